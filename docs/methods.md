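# Methods

`cinefill` models and analyses the time course of left-ventricular (LV)
volumetric filling as measured by routine short-axis cine CMR. It has two
halves: a *generator* that produces grade-stratified synthetic patients with
exact, closed-form ground truth for every diastolic index, and an *analysis
chain* that recovers those indices from sampled (optionally noisy, optionally
image-derived) volume curves and scores them against echo-style reference
grades. Everything below is the package's own account of the modelling and
numerical choices.

## The volume model

One ECG-gated cardiac cycle of length `rr_ms` is split into a systolic
ejection phase of duration `ts_ms` and a diastolic filling phase of duration
`D = rr_ms − ts_ms`.

* **Systole.** Volume falls monotonically from EDV to ESV along a quintic
  smoothstep, `V(t) = EDV − SV·s(t/ts)` with `s(x) = 6x⁵ − 15x⁴ + 10x³`.
  The smoothstep has zero first *and* second derivatives at both ends, so
  sampled curves have a rapidly decaying harmonic spectrum and the
  systole–diastole junction introduces no spurious high-frequency content.
* **Diastole.** Filling is the sum of two non-overlapping raised-cosine
  *rate* pulses: the early (E) wave carrying a volume fraction
  `e_fraction` of the stroke volume and the late atrial (A) wave carrying
  the remainder. A pulse of width `w` carrying volume `f·SV` has rate
  `(f·SV/w)·(1 − cos(2π(t−t₀)/w))`, hence an exact peak rate of `2·f·SV/w`
  and an analytically integrable cumulative volume.

Because every piece is closed-form, the ground-truth indices are exact:
PFR is the larger lobe peak (ties to E), TPFR its centre time measured from
end-systole, E:A the ratio of lobe peak rates, and DVR80 the root of the
cumulative filling fraction at 0.8 (found by `brentq` to 1e-9 ms).

## Index definitions

| index | definition | units |
|---|---|---|
| PFR | maximal diastolic dV/dt | ml/s |
| nPFR | PFR / stroke volume | 1/s |
| TPFR | end-systole → PFR instant | ms |
| DVR80 | fraction of diastole to recover 80% of SV | % of diastole |
| E:A | early / late peak filling-rate ratio | – |
| EF | (EDV − ESV)/EDV · 100 | % |

End-diastole is the gated cycle start (`t = 0`); end-systole is the
(earliest) volume minimum; diastole runs from end-systole to the cycle end.
EDV is the curve maximum, so a curve whose maximum is not at the trigger
still yields the conventional EF.

## Grade templates

Per-grade generative targets are truncated normals (±2.5 SD plus physiologic
hard bounds) parameterised by the post-MI cohort moments reported for the
four reference groups: EDV 151/141/149/220 ml, EF 57/55/54/41%,
PFR 266/207/231/353 ml/s, TPFR 174/321/221/136 ms, DVR80 65/81/73/58% for
normal/grade 1/grade 2/grade 3 respectively. The cycle length is drawn from
N(1000, 100) ms (beta-blocked post-MI patients at rest), giving a 33 ms
phase spacing at the default 30 reconstructed phases, consistent with
routine cine temporal resolution.

A bounded least-squares fit then chooses the lobe geometry — `e_fraction`,
systolic duration, lobe widths and the diastasis gap — that realises the
sampled index targets as closely as the two-lobe form allows. The fit is
restricted to regions where the implied ground truth is *recoverable in
principle* from noisy 30-phase data:

* **Peak-dominance margin.** The analytic E:A peak-rate ratio never falls
  in (0.58, 1.65). With near-equal peaks, phase noise of the magnitude the
  generator itself injects makes the identity of the global rate maximum —
  the TPFR ground truth — undecidable, so such patients would carry
  unusable labels. Grade 1 is generated A-dominant (E:A ≈ 0.5, marked E:A
  reversal) in line with its defining echo criterion E/A < 0.8; the
  reported CMR E:A for that group (1.1 ± 0.4) straddles unity and cannot
  serve as an unambiguous generative target.
* **Inflow-wave durations** are bounded to [200, 340] ms (scaled up with
  cycle length), the physiologic range; the *dominant* wave is at least
  280 ms wide so its peak is resolved by the first ~6 cardiac harmonics.
* **DVR80 conditioning.** `e_fraction` stays away from the 0.8 recovery
  fraction (branches [0.30, 0.70] / [0.88, 0.94]; A-dominant ≤ 0.45):
  at `e_fraction ≈ 0.8` the recovery target sits on the inter-lobe
  diastasis plateau where the crossing time is ill-defined. A penalty also
  keeps the filling rate at the 80% crossing above ~20% of PFR.
* **Valley balance.** A soft penalty equalises the flatness of the volume
  valley on the systolic and diastolic sides of end-systole, keeping the
  end-systole fiducial well conditioned.

Consequences worth knowing: a raised-cosine pulse has a crest factor of 2,
which puts a floor of roughly `2·SV/D` on the attainable peak rate. Low PFR
targets (mostly grade 1 and normal) saturate at this floor, so realised
analytic PFR means sit some 30–50% above the published group means while the
ordering across grades (grade 3 ≫ grade 1) is preserved. Similarly the
A-dominant grade-1 geometry cannot push DVR80 much above ~78%, a few points
below the published 81 ± 5. The recovery and diagnostic-direction test
suites are therefore run against the generator's *own* analytic values, not
the published group means, which derive from non-public patient data.

Echo panels are sampled uniformly strictly inside each grade's criteria
(normal: E/A ≥ 0.8, septal e′ ≥ 8 cm/s, lateral e′ ≥ 10 cm/s, DT
140–240 ms; grade 1: E/A < 0.8, low e′, DT > 240 ms; grade 2: E/A 0.8–1.5,
low e′, DT 140–240 ms; grade 3: E/A ≥ 2, low e′, DT < 140 ms). Open-ended
ranges are bounded at physiologic extremes (grade-1 DT ≤ 335 ms, grade-3
DT ≥ 85 ms, E/A ≤ 4.8, e′ ≥ 3 cm/s).

## Smoothing and estimation

The curve is periodic, so smoothing is spectral: a Fourier reconstruction
whose derivative is evaluated analytically rather than by finite
differences (differencing is exactly what amplifies per-phase segmentation
error). The `lowpass`/`derivative` operations take an explicit harmonic
cutoff; the pipeline default is noise-adaptive:

* The mean amplitude of the top third of the harmonic spectrum — empty of
  physiologic volume signal — estimates the per-harmonic noise amplitude.
* If that floor is negligible (≤ 0.05 ml and ≤ 0.2% of the fundamental),
  the curve is treated as effectively noise-free: harmonics pass with a
  soft ramp that only suppresses amplitudes indistinguishable from the
  floor itself (e.g. rasterisation jitter).
* Otherwise each harmonic receives an empirical-Wiener gain
  `max(0, 1 − α·P_noise/A_k²)` with oversubtraction factor `α = 1.5`,
  calibrated by simulation to balance residual-noise inflation of the peak
  against shrinkage attenuation.

Fiducials and indices are then read from the smooth model on a 4096-point
grid, with estimators chosen for their noise behaviour:

* **End-systole**: on clean curves, the argmin refined by a local quartic
  fit of the raw samples (the band-limited model's minimum is displaced a
  few ms at a sharp valley); under noise, the depth-weighted centroid of
  the valley set with a symmetrised window, which averages noise over the
  whole valley bottom instead of chasing its deepest dip.
* **EDV/ESV under noise**: local quadratic fits of the reconstruction
  around the (noise-averaged) extremum times. Taking extreme *values* of
  a noisy curve is biased outward and systematically inflates stroke
  volume by several percent.
* **PFR time (TPFR)**: the rate-weighted centroid of the dominant wave's
  support (rate above 25% of the peak, clipped at rebounds, symmetrised).
  For a symmetric wave this is the peak instant, but it averages noise
  over the wave; a plain argmax jitters by tens of ms and is biased toward
  the wave's steeper neighbour.
* **PFR value**: under measurable noise, the mean of the spectral peak and
  a local quartic fit of the *raw* samples over a 270 ms window around the
  peak. The two estimates have largely independent errors (spectral vs
  direct averaging of i.i.d. phase noise), so ensembling roughly halves
  the variance. Clean curves keep the exact spectral peak.
* **DVR80**: linear interpolation between bracketing samples of the dense
  reconstruction (the published values are finer than the phase spacing,
  so interpolation at acquisition-phase resolution would be too coarse).
* **E/A waves**: local maxima of the diastolic rate above 5% of PFR; the
  two *most prominent* candidates are the waves (E earlier, A later) —
  on a clean two-lobe profile this reduces to earliest/latest, but it
  ignores low-prominence noise shoulders. Discernability requires the
  inter-wave valley to fall below 50% of the smaller peak; a
  non-discernable profile is a flagged outcome, not an error.

A raw successive-difference PFR mode (`pfr_mode="raw"`) reproduces the
unfiltered Δvolume/Δphase convention for comparison.

## Phantom and stand-in segmentation

The phantom writes each patient as a multi-slice stack of bright disks with
a truncated-ellipsoid base-to-apex taper, scaled per phase so the analytic
summed-disk volume equals the model volume. Slice geometry defaults to the
acquisition convention (6 mm slices, 4 mm gaps); volume summation uses the
effective spacing thickness + gap by default (assuming contiguous chamber
coverage — summing with bare thickness would underestimate volumes by
~40%), switchable via `include_gap`. Disk edges carry linear sub-pixel
coverage, and deterministic sub-pixel per-slice centre offsets break the
coherence of pixel-quantisation error across slices so it averages out of
the summed volume. The default raster (1.0 mm pixels, 224²) keeps
discretisation error well below the segmentation-chain tolerance; a
acquisition-typical 1.4 mm in-plane resolution remains available through
`CineGeometry`.

The segmenter is deliberately simple plumbing — global intensity threshold
(strictly greater than `threshold × max`) plus per-slice 4-connected region
growth from a seed, areas as pixel count × pixel area — standing in for a
clinical segmentation algorithm, which is prior work outside this package.
Basal truncation at the mitral annulus is emulated by an optional slice
range.

## Classification and calibration

Echo grading applies the four criteria in the order
normal → 1 → 2 → 3, first match winning; panels matching no rule are
returned as `indeterminate`, never coerced. Equivocal tissue Doppler
(abnormal lateral, normal septal e′) is adjudicated by e′/a′ reversal
(< 1) when supplied, with the sub-grade taken from the inflow pattern.

CMR abnormality flags use strict exceedance of the published operating
points (DVR80 77% of diastole, TPFR 221 ms, PFR 344 ml/s, nPFR 4.02 /s);
the aggregate criterion is prolonged DVR80 OR high PFR.
`calibrate_threshold` regenerates cohort-specific cutoffs: candidates are
midpoints between sorted distinct normal values plus one candidate beyond
each extreme, and the most sensitive candidate meeting the target
specificity (default 83%) is returned. Printed percentages round half-up
to integers; ratios with a zero denominator are reported absent.

## What the synthetic data do and do not show

The generator emulates grade-stratified filling profiles, chamber volumes,
cine geometry and additive, independent Gaussian segmentation noise that a
low-pass filter can remove. It does not model atrial mechanics, mitral
regurgitation, arrhythmia, beat-to-beat variability, respiratory drift,
correlated segmentation error, papillary muscles or partial-volume effects.
Passing recovery tests therefore demonstrates that the analysis chain is
faithful to its own definitions under realistic sampling and noise — not
that it would achieve the same accuracy on clinical data, where the noise
structure is richer and the reference standard itself is imperfect.

## Numerical choices and problem sizes

* Dense evaluation grid 4096 points/cycle; ties at extrema resolve to the
  earlier time.
* Oracle-equivalence checks run 100 noise-free patients at 48 phases: at
  that sampling the production chain matches a 10,000-point dense-grid
  oracle to 0.14% (PFR), 1.3 ms (TPFR), 0.06 pp (DVR80) and 0.5% (E:A).
  At 30 phases the end-systolic valley of the sharpest patients is only
  determined to ±3 ms by the samples themselves (an information limit, not
  an algorithmic one), which bounds DVR80 agreement near 0.25 pp.
* Recovery checks run the full default cohort (115 patients, 30 phases,
  2 ml noise); per-grade mean errors stay within 5% (PFR), 10 ms (TPFR)
  and 2 pp (DVR80) of the analytic values.
* Estimator constants (Wiener α, window widths, prominence rule) were
  calibrated on simulation seeds disjoint from the fixed seed used by the
  test suite and then frozen.
* The phantom suite uses 10 patients × 30 phases × 10 slices.

## Known limitations

* Realised PFR and grade-1 DVR80 distributions deviate from the published
  group moments (crest-factor floor and A-dominance ceiling, above).
* The E:A exclusion band means the generator never produces the genuinely
  ambiguous near-unity profiles that occur clinically (the pipeline still
  handles them — identification is by prominence, and near-equal waves
  simply yield a ratio near 1).
* Echo panels are drawn strictly inside the grade criteria, so reference
  grading is noiseless; real echo reference standards misclassify.
* One cycle only; no heart-rate correction of indices is attempted.
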