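"""Simulate a polarization-resolved acquisition and reconstruct the Mueller matrix.

Builds a small birefringent phantom (retardance 0.8 rad, 10% diattenuation,
mild depolarization), images it through the default 24 state-pair scheme
with 2% shot-like noise, and reconstructs the per-pixel 4x4 Mueller matrix
by least squares.
"""

import numpy as np

import muellermap as mm
from muellermap.synth import PhantomSpec, make_sample

spec = PhantomSpec.generate(
    height=64, width=64, delta0=0.8, d0=0.10, depol=(0.95, 0.95, 0.90), seed=0
)
truth, stack = make_sample(spec, noise_sigma=0.02, rng=np.random.default_rng(0))
print(f"acquired {len(stack.states)} images of {stack.shape[0]}x{stack.shape[1]} px")

rec = mm.reconstruct_mueller(stack)  # least squares over all state pairs
mask = mm.compute_mask(stack.images.sum(axis=0))
err = np.abs(rec.normalize().elements - truth.normalize().elements)[mask.mask]
print(f"tissue pixels: {mask.n_pixels}  (threshold {mask.threshold_used:.3g})")
print(f"median per-element reconstruction error: {np.median(err):.4f}")
print(f"99th percentile error:                   {np.percentile(err, 99):.4f}")
# Errors of a few 1e-2 at 2% intensity noise: the overdetermined 24-pair
# design averages noise down relative to the minimal 16-pair scheme.

# System calibration: image empty air (identity matrix) with the same noise
# and compare the mean reconstructed matrix against the theoretical identity.
air = np.broadcast_to(np.eye(4), (32, 32, 4, 4)).copy()
air_stack = mm.simulate_stack(air, noise_sigma=0.02, rng=np.random.default_rng(1))
report = mm.calibrate(mm.reconstruct_mueller(air_stack), np.eye(4), "air")
print(f"air-calibration max element error: {report.max_error:.2f}%")
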