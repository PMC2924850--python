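"""Echo grading, thresholds, calibration and diagnostic arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinefill import (
    CalibrationError,
    ConfusionMatrix,
    EchoPanel,
    InfeasibleParametersError,
    Thresholds,
    aggregate_criterion,
    calibrate_threshold,
    classify_cmr,
    diagnostic_performance,
    grade_echo,
    render_performance_table,
    sample_echo_panel,
)
from cinefill.classify import performance_from_matrix, round_half_up
from cinefill.cohort import GRADES
from cinefill.indices import DiastolicIndices


def make_indices(dvr=65.0, tpfr=174.0, pfr=266.0, sv=85.0):
    return DiastolicIndices(
        edv=150.0, esv=65.0, sv=sv, ef=56.0, pfr=pfr, npfr=pfr / sv,
        tpfr_ms=tpfr, dvr=dvr, e_peak=None, a_peak=None, ea_ratio=None,
        ea_discernable=False, n_harmonics=10,
    )


# -- echo grading -----------------------------------------------------------


@pytest.mark.parametrize(
    "panel,expected",
    [
        (EchoPanel(0.7, 6, 8, 260), "grade1"),
        (EchoPanel(2.5, 5, 7, 120), "grade3"),
        (EchoPanel(1.0, 9, 11, 180), "normal"),
        (EchoPanel(1.2, 6, 8, 180), "grade2"),
        (EchoPanel(1.2, 6, 8, 300), "indeterminate"),  # no rule matches
    ],
)
def test_grade_echo_rules(panel, expected):
    assert grade_echo(panel) == expected


def test_equivocal_tissue_doppler_adjudication():
    """Abnormal lateral with normal septal e' resolves via e'/a' reversal."""
    base = dict(e_over_a=1.2, septal_e_prime=9.0, lateral_e_prime=8.0, dt_ms=180.0)
    assert grade_echo(EchoPanel(**base)) == "indeterminate"
    reversed_panel = EchoPanel(**base, eprime_over_aprime_lateral=0.8)
    assert grade_echo(reversed_panel) == "grade2"


def test_grading_closure_all_grades():
    """Every sampled echo panel maps back to its generating grade."""
    rng = np.random.default_rng(11)
    for grade in GRADES:
        assert all(
            grade_echo(sample_echo_panel(grade, rng)) == grade for _ in range(250)
        )


# -- CMR flags --------------------------------------------------------------


def test_classify_cmr_flags():
    th = Thresholds()
    assert "prolonged_dvr" in classify_cmr(make_indices(dvr=81.0), th)
    assert "high_npfr" in classify_cmr(make_indices(pfr=4.1 * 85.0), th)
    assert classify_cmr(make_indices(dvr=65, tpfr=174, pfr=266), th) == frozenset()


def test_strict_inequality_at_cutoffs():
    th = Thresholds()
    assert "prolonged_dvr" not in classify_cmr(make_indices(dvr=77.0), th)
    assert "prolonged_dvr" in classify_cmr(make_indices(dvr=77.0001), th)


def test_aggregate_criterion():
    assert aggregate_criterion({"prolonged_dvr"})
    assert aggregate_criterion({"high_pfr"})
    assert not aggregate_criterion(set())
    assert not aggregate_criterion({"long_tpfr"})


# -- calibration ------------------------------------------------------------


def test_calibration_on_distinct_values():
    """40 distinct values, 82.5% target: exactly 7 of 40 exceed the cutoff."""
    values = np.arange(1.0, 41.0)
    cutoff = calibrate_threshold(values, "above", 0.825)
    above = int(np.sum(values > cutoff))
    assert above == 7
    assert np.mean(values <= cutoff) >= 0.825


def test_calibration_degenerate_identical_values():
    cutoff = calibrate_threshold([5.0] * 10, "above", 0.99)
    assert cutoff > 5.0
    assert np.mean(np.array([5.0] * 10) <= cutoff) == 1.0


def brute_force_cutoff(values, direction, target):
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    margin = (distinct[-1] - distinct[0]) * 0.5 or 1.0
    candidates = np.concatenate(
        [[distinct[0] - margin], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + margin]]
    )
    feasible = []
    for c in candidates:
        spec = np.mean(values <= c) if direction == "above" else np.mean(values >= c)
        if spec >= target:
            feasible.append(c)
    return min(feasible) if direction == "above" else max(feasible)


@given(
    st.integers(min_value=0, max_value=10_000),
    st.sampled_from(["above", "below"]),
    st.sampled_from([0.5, 0.7, 0.825, 0.9, 0.95]),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_calibration_matches_exhaustive_scan(seed, direction, target):
    rng = np.random.default_rng(seed)
    values = rng.normal(65, 16, size=200)
    cutoff = calibrate_threshold(values, direction, target)
    expected = brute_force_cutoff(values, direction, target)
    assert cutoff == pytest.approx(expected)


def test_calibration_input_validation():
    with pytest.raises(CalibrationError):
        calibrate_threshold([1, 2, 3], "above", 0.8)
    with pytest.raises(CalibrationError):
        calibrate_threshold(np.arange(10.0), "above", 1.5)
    with pytest.raises(CalibrationError):
        calibrate_threshold(np.arange(10.0), "sideways", 0.8)


def test_looser_specificity_never_less_sensitive():
    """Monotone trade-off on a paired normal/abnormal evaluation set."""
    rng = np.random.default_rng(3)
    normals = rng.normal(65, 10, 60)
    abnormals = rng.normal(80, 10, 40)
    last_sens = -1.0
    for target in (0.95, 0.9, 0.8, 0.7, 0.6):
        cutoff = calibrate_threshold(normals, "above", target)
        sens = float(np.mean(abnormals > cutoff))
        assert sens >= last_sens
        last_sens = sens


# -- diagnostic performance -------------------------------------------------


def test_confusion_matrix_worked_example():
    """15/21 sensitivity with 33/40 specificity prints as 71%/83%/79%/68%/85%."""
    perf = performance_from_matrix(ConfusionMatrix(tp=15, fn=6, fp=7, tn=33))
    pct = perf.as_percent()
    assert pct == {
        "sensitivity": 71,
        "specificity": 83,
        "accuracy": 79,
        "ppv": 68,
        "npv": 85,
    }


def test_degenerate_denominator_reported_absent():
    perf = performance_from_matrix(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
    pct = perf.as_percent()
    assert pct["specificity"] == 100
    assert pct["sensitivity"] is None


def test_diagnostic_performance_from_labels():
    predicted = [True] * 15 + [False] * 6 + [True] * 7 + [False] * 33
    truth = [True] * 21 + [False] * 40
    perf = diagnostic_performance(predicted, truth)
    assert perf.matrix == ConfusionMatrix(tp=15, fn=6, fp=7, tn=33)
    with pytest.raises(InfeasibleParametersError):
        diagnostic_performance([True], [True, False])


def test_round_half_up():
    assert round_half_up(82.5) == 83
    assert round_half_up(71.43) == 71
    assert round_half_up(91.67) == 92  # 33/36: half-up rounding gives 92


# -- rendering --------------------------------------------------------------


def test_render_cells():
    from cinefill.report import cells_for_metrics, format_cell

    perf = performance_from_matrix(ConfusionMatrix(tp=15, fn=6, fp=7, tn=33))
    cells = cells_for_metrics(perf)
    assert cells["Sensitivity"] == "71% (15/21)"
    perf0 = performance_from_matrix(ConfusionMatrix(tp=0, fn=9, fp=7, tn=33))
    assert cells_for_metrics(perf0)["Sensitivity"] == "0% (0/9)"
    assert format_cell(0, 0) == "-"


def test_render_empty_report_header_only():
    import pandas as pd

    from cinefill.classify import DiagnosticReport

    table = render_performance_table(DiagnosticReport(entries=pd.DataFrame()))
    assert table.splitlines()[0].startswith("Index")
    assert len(table.splitlines()) == 1
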