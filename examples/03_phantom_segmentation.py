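"""Exercise the full image chain: rasterise, segment, and re-index.

A synthetic patient is rendered as a multi-slice short-axis cine stack
(6 mm slices, 4 mm gaps), segmented by threshold + region growth, and the
summed-disk volume curve is pushed through the same index pipeline as the
directly sampled curve.  The two PFR/DVR80 values agree to within the
rasterisation error of the phantom.
"""

import numpy as np

from cinefill import (
    compute_indices,
    generate_volume_curve,
    rasterize_stack,
    sample_patient,
    segment_stack,
)

truth = sample_patient("normal", np.random.default_rng(3))
stack = rasterize_stack(truth, n_phases=30)
seg = segment_stack(stack)

clean = generate_volume_curve(truth, n_phases=30, noise_sd=0.0)
idx_img = compute_indices(seg.to_curve())
idx_ref = compute_indices(clean)

vol_err = 100 * np.max(np.abs(seg.volumes_ml / stack.analytic_volumes - 1))
print(f"stack: {stack.n_phases} phases x {stack.n_slices} slices")
print(f"max segmented-volume error vs analytic: {vol_err:.2f}%")
print(f"PFR   image chain {idx_img.pfr:6.0f} ml/s | direct {idx_ref.pfr:6.0f} ml/s")
print(f"DVR80 image chain {idx_img.dvr:6.1f} %    | direct {idx_ref.dvr:6.1f} %")
print("\nsub-percent volume error keeps the index chain faithful end to end.")
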