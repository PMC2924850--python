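"""Diastolic indices: closed forms, recovery, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinefill import (
    InfeasibleParametersError,
    NoFillingError,
    VolumeCurve,
    compute_indices,
    diastolic_volume_recovery,
    find_fiducials,
    generate_volume_curve,
    infarct_size,
    lv_mass,
    make_truth,
    normalized_pfr,
    peak_filling_rate,
    sample_patient,
    time_to_pfr,
)
from cinefill.curve import Fiducials


def linear_filling_curve(n=30, rr=1000.0, ts=500.0, edv=150.0, esv=70.0):
    """Piecewise-linear fall then rise: constant diastolic filling rate."""
    t = np.arange(n) * rr / n
    v = np.where(t < ts, edv - (edv - esv) * t / ts, esv + (edv - esv) * (t - ts) / (rr - ts))
    return VolumeCurve(phase_times=t, volumes=v, rr_ms=rr, provenance="analytic")


def fiducials_for(curve, es_time, edv, esv):
    sv = edv - esv
    return Fiducials(
        ed_index=0, ed_time=0.0,
        es_index=int(np.argmin(np.abs(curve.phase_times - es_time))),
        es_time=es_time, edv=edv, esv=esv, sv=sv, ef=sv / edv * 100,
        rr_ms=curve.rr_ms, diastole_duration=curve.rr_ms - es_time,
    )


def test_linear_filling_constant_rate():
    """80 ml over 500 ms of diastole is a 160 ml/s plateau."""
    curve = linear_filling_curve()
    fid = fiducials_for(curve, 500.0, 150.0, 70.0)
    t = np.linspace(0, 1000, 4001, endpoint=False)
    rates = np.where(t >= 500, 160.0, -160.0)
    pfr, _ = peak_filling_rate(t, rates, fid)
    assert pfr == pytest.approx(160.0)


def test_raised_cosine_peak_through_production_chain():
    """Single 80 ml / 400 ms lobe: production PFR = 400 ml/s at midpoint."""
    truth = make_truth(
        "normal", edv=150, esv=70, rr_ms=1000, ts_ms=400,
        e_fraction=1.0, e_onset_ms=0.0, e_width_ms=400.0,
    )
    curve = generate_volume_curve(truth, 48, 0.0)
    idx = compute_indices(curve)
    assert idx.pfr == pytest.approx(400.0, rel=0.005)
    assert idx.tpfr_ms == pytest.approx(200.0, abs=6.0)


def test_no_filling_raises():
    curve = linear_filling_curve()
    fid = fiducials_for(curve, 500.0, 150.0, 70.0)
    t = np.linspace(0, 1000, 401, endpoint=False)
    with pytest.raises(NoFillingError):
        peak_filling_rate(t, np.full_like(t, -5.0), fid)


def test_normalized_pfr_values():
    assert normalized_pfr(266.0, 85.0) == pytest.approx(3.13, abs=0.005)
    assert normalized_pfr(85.0, 85.0) == pytest.approx(1.0)
    # consistency of the published operating points: 344 ml/s at the mean
    # stroke volume corresponds to the printed 4.02 /s cutoff
    assert round(normalized_pfr(344.0, 85.6), 2) == pytest.approx(4.02)
    with pytest.raises(InfeasibleParametersError):
        normalized_pfr(100.0, 0.0)


def test_time_to_pfr_arithmetic():
    curve = linear_filling_curve()
    fid = fiducials_for(curve, 350.0, 150.0, 70.0)
    assert time_to_pfr(550.0, fid) == pytest.approx(200.0)
    with pytest.raises(InfeasibleParametersError):
        time_to_pfr(300.0, fid)


def test_lobe_peak_at_half_width():
    """A lobe starting at end-systole peaks at half its width."""
    truth = make_truth(
        "normal", edv=150, esv=70, rr_ms=1000, ts_ms=400,
        e_fraction=1.0, e_onset_ms=0.0, e_width_ms=500.0,
    )
    assert truth.analytic_tpfr == pytest.approx(250.0)


def test_dvr_linear_filling_is_exactly_80():
    curve = linear_filling_curve(n=240)
    fid = fiducials_for(curve, 500.0, 150.0, 70.0)
    assert diastolic_volume_recovery(curve, fid, 0.8) == pytest.approx(80.0, abs=1e-6)


def test_dvr_early_filling_bound():
    """All filling within the first interval keeps DVR near the interval."""
    rr, ts = 1000.0, 500.0
    t = np.arange(30) * rr / 30
    v = np.where(t < ts, 150 - 80 * t / ts, np.where(t < ts + 40, 70 + 80 * (t - ts) / 40, 150.0))
    curve = VolumeCurve(phase_times=t, volumes=v, rr_ms=rr)
    fid = fiducials_for(curve, ts, 150.0, 70.0)
    dvr = diastolic_volume_recovery(curve, fid, 0.8)
    assert dvr <= 100.0 * 40 / (rr - ts) + 1e-9


def test_dvr_symmetric_lobe_matches_dense_oracle():
    """Full-diastole raised-cosine lobe: crossing from a dense root-find."""
    truth = make_truth(
        "normal", edv=150, esv=70, rr_ms=1000, ts_ms=400,
        e_fraction=1.0, e_onset_ms=0.0, e_width_ms=600.0,
    )
    idx = compute_indices(generate_volume_curve(truth, 48, 0.0))
    # oracle: 10,000-point scan of the continuous model
    t = np.linspace(400.0, 1000.0, 10_000)
    v = truth.model().volume(t)
    target = 70 + 0.8 * 80
    t_star = t[int(np.argmax(v >= target))]
    expected = 100.0 * (t_star - 400.0) / 600.0
    assert idx.dvr == pytest.approx(expected, abs=0.2)


@given(st.lists(st.sampled_from([0.5, 0.6, 0.7, 0.8, 0.9]), min_size=2, max_size=4))
@settings(deadline=None, max_examples=20)
def test_dvr_monotone_in_fraction(fractions):
    truth = make_truth(
        "normal", edv=150, esv=70, rr_ms=1000, ts_ms=400,
        e_fraction=0.6, e_onset_ms=0.0, e_width_ms=300.0,
        a_onset_ms=320.0, a_width_ms=260.0,
    )
    curve = generate_volume_curve(truth, 48, 0.0)
    fid = find_fiducials(curve)
    values = [diastolic_volume_recovery(curve, fid, f) for f in sorted(fractions)]
    assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))


def test_ea_two_equal_lobes():
    truth = make_truth(
        "normal", edv=150, esv=70, rr_ms=1000, ts_ms=300,
        e_fraction=0.5, e_onset_ms=0.0, e_width_ms=280.0,
        a_onset_ms=380.0, a_width_ms=280.0,
    )
    idx = compute_indices(generate_volume_curve(truth, 48, 0.0))
    assert idx.ea_discernable
    assert idx.ea_ratio == pytest.approx(1.0, abs=0.02)


def test_single_lobe_not_discernable():
    truth = make_truth(
        "normal", edv=150, esv=70, rr_ms=1000, ts_ms=400,
        e_fraction=1.0, e_onset_ms=0.0, e_width_ms=500.0,
    )
    idx = compute_indices(generate_volume_curve(truth, 48, 0.0))
    assert not idx.ea_discernable
    assert idx.ea_ratio is None


def test_grade1_scale_ratio_recovered_under_noise():
    """A mild-dysfunction-scale peak ratio of 1.1 recovers within 10%."""
    truth = make_truth(
        "grade1", edv=141, esv=63, rr_ms=1000, ts_ms=380,
        e_fraction=0.52, e_onset_ms=0.0, e_width_ms=290.0,
        a_onset_ms=310.0, a_width_ms=294.5,
    )
    assert truth.analytic_ea == pytest.approx(1.1, abs=0.02)
    ratios = []
    for i in range(50):
        rng = np.random.default_rng(40_000 + i)
        curve = generate_volume_curve(truth, 30, 2.0, rng)
        idx = compute_indices(curve)
        if idx.ea_discernable:
            ratios.append(idx.ea_ratio)
    assert len(ratios) >= 40
    assert np.mean(ratios) == pytest.approx(truth.analytic_ea, rel=0.10)


def test_lv_mass():
    assert lv_mass(200.0, 120.0) == pytest.approx(84.0)
    assert lv_mass(120.0, 120.0) == 0.0
    assert lv_mass(215.0, 151.0) == pytest.approx(67.2)
    with pytest.raises(InfeasibleParametersError):
        lv_mass(100.0, 120.0)


def test_infarct_size():
    assert infarct_size([0] * 17) == 0.0
    assert infarct_size([4] * 17) == pytest.approx(88.0)
    assert infarct_size([4] + [0] * 16) == pytest.approx(88 / 17, abs=0.005)
    with pytest.raises(InfeasibleParametersError):
        infarct_size([0] * 16)
    with pytest.raises(InfeasibleParametersError):
        infarct_size([5] + [0] * 16)


def test_scale_equivariance():
    """Scaling volumes by c scales PFR/SV by c, leaves ratios unchanged."""
    truth = sample_patient("grade2", np.random.default_rng(6))
    curve = generate_volume_curve(truth, 30, 0.0)
    scaled = VolumeCurve(
        phase_times=curve.phase_times,
        volumes=2.5 * curve.volumes,
        rr_ms=curve.rr_ms,
    )
    a = compute_indices(curve)
    b = compute_indices(scaled)
    assert b.pfr == pytest.approx(2.5 * a.pfr, rel=1e-6)
    assert b.sv == pytest.approx(2.5 * a.sv, rel=1e-6)
    assert b.npfr == pytest.approx(a.npfr, rel=1e-6)
    assert b.dvr == pytest.approx(a.dvr, abs=1e-6)
    assert b.ef == pytest.approx(a.ef, abs=1e-6)


def test_pfr_exceeds_mean_filling_rate():
    """PFR is bounded below by stroke volume over diastolic duration."""
    for seed in range(5):
        truth = sample_patient("normal", np.random.default_rng(60_000 + seed))
        idx = compute_indices(generate_volume_curve(truth, 30, 0.0))
        mean_rate = 1000.0 * idx.sv / (truth.rr_ms - truth.ts_ms)
        assert idx.pfr > mean_rate


def test_raw_difference_mode():
    """The unfiltered successive-difference convention stays close for clean data."""
    truth = sample_patient("grade3", np.random.default_rng(9))
    curve = generate_volume_curve(truth, 30, 0.0)
    raw = compute_indices(curve, pfr_mode="raw")
    filt = compute_indices(curve, pfr_mode="filtered")
    assert raw.pfr == pytest.approx(filt.pfr, rel=0.15)
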