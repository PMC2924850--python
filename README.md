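# cinefill

Left-ventricular diastolic filling analysis from routine cine-CMR volume
curves — for imaging researchers who want a tested, fully synthetic sandbox
for LV filling indices and their diagnostic behaviour across diastolic
dysfunction (DD) grades.

Cine CMR images the whole cardiac cycle, so the segmented short-axis stack
yields a volume–time curve V(t) over one gated beat. From the filtered
curve and its derivative dV/dt the package computes the standard global
filling indices:

* **PFR** — peak filling rate, max diastolic dV/dt (ml/s), and
  **nPFR** = PFR/SV (1/s);
* **TPFR** — time from end-systole to the PFR instant (ms);
* **DVR80** — fraction of diastole needed to recover 80% of stroke volume
  (%), with SV = EDV − ESV and EF = SV/EDV · 100;
* **E:A** — ratio of the early (passive) to late (atrial) peak filling
  rates of the diastolic rate profile, when both waves are discernable.

Impaired relaxation (grade 1 DD) prolongs the filling interval (high
DVR80, long TPFR, E:A reversal); restrictive physiology (grade 3) does the
opposite (high PFR/nPFR, short recovery). The package generates synthetic
cohorts with exact closed-form ground truth for all of these, optionally
renders them as segmentable short-axis cine stacks, recovers the indices
from noisy curves, grades patients by the standard echo criteria
(E/A, septal/lateral e′, deceleration time), calibrates index cutoffs at a
matched specificity on the normal group, and emits per-grade diagnostic
performance tables.

## Worked example

```python
import numpy as np
from cinefill import sample_patient, generate_volume_curve, compute_indices

rng = np.random.default_rng(7)
truth = sample_patient("grade3", rng)                      # restrictive filling
curve = generate_volume_curve(truth, n_phases=30, noise_sd=2.0, rng=rng)
idx = compute_indices(curve)
print(f"PFR {idx.pfr:.0f} ml/s (truth {truth.analytic_pfr:.0f})")
print(f"DVR80 {idx.dvr:.1f} %  (truth {truth.analytic_dvr80:.1f})")
```

prints

```
PFR 473 ml/s (truth 465)
DVR80 40.7 %  (truth 39.9)
```

a high peak filling rate with early volume recovery — the restrictive
signature — recovered from a 30-phase curve with 2 ml per-phase
segmentation noise. The `examples/` directory has one short script per
capability: cohort generation, index recovery, the phantom
rasterise-segment-index chain, and diagnostic table construction. A thin
CLI wraps the same pipeline:

```bash
cinefill all --seed 7 --out runs/demo
```

writes the cohort, index table, diagnostic report and a manifest that
reproduces the run bit for bit.

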