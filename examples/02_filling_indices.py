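"""Compute diastolic filling indices for one noisy cine volume curve.

Samples a severe-dysfunction (restrictive) patient at 30 cine phases with
2 ml of per-phase segmentation noise, runs the index pipeline, and compares
the recovered indices against the generator's exact values.
"""

import numpy as np

from cinefill import compute_indices, generate_volume_curve, sample_patient

rng = np.random.default_rng(7)
truth = sample_patient("grade3", rng)
curve = generate_volume_curve(truth, n_phases=30, noise_sd=2.0, rng=rng)
idx = compute_indices(curve)

print(f"patient grade: {truth.grade}, RR {truth.rr_ms:.0f} ms")
print(f"{'index':>10} {'recovered':>10} {'truth':>10}")
print(f"{'PFR ml/s':>10} {idx.pfr:10.0f} {truth.analytic_pfr:10.0f}")
print(f"{'nPFR /s':>10} {idx.npfr:10.2f} {truth.analytic_pfr / truth.sv:10.2f}")
print(f"{'TPFR ms':>10} {idx.tpfr_ms:10.0f} {truth.analytic_tpfr:10.0f}")
print(f"{'DVR80 %':>10} {idx.dvr:10.1f} {truth.analytic_dvr80:10.1f}")
if idx.ea_discernable:
    print(f"{'E:A':>10} {idx.ea_ratio:10.2f} {truth.analytic_ea:10.2f}")
print(
    "\nhigh PFR with a short recovery time is the restrictive-filling "
    "signature; small differences from truth reflect the 2 ml noise."
)
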