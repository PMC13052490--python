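"""Extract the 24 polarimetric parameters from a reconstructed Mueller image.

The four frameworks (polar decomposition, matrix transformation, rotation
invariants, linear identities) turn the 16 raw matrix elements into named
scalar maps: retardance delta tracks fiber birefringence, PL the linear
polarizance of aligned fibers, Delta the depolarization from structural
heterogeneity.
"""

import numpy as np

import muellermap as mm
from muellermap.synth import PhantomSpec, make_sample

# aligned-fiber phantom: high orientation concentration, moderate retardance
spec = PhantomSpec.generate(
    height=64, width=64, delta0=0.9, d0=0.12, kappa=8.0, micro_kappa=8.0, seed=1
)
truth, stack = make_sample(spec, noise_sigma=0.02, rng=np.random.default_rng(1))
rec = mm.reconstruct_mueller(stack)
mask = mm.compute_mask(stack.images.sum(axis=0))
maps = mm.extract_all(rec, mask)

print(f"{len(maps.names)} parameter maps on a {maps.mask.shape} grid\n")
print(f"{'parameter':<10}{'median':>10}{'iqr':>10}")
for name in ("delta", "R", "D", "PL", "rL", "Delta", "b", "beta", "psi"):
    vals = maps[name][maps.mask]
    iqr = np.subtract(*np.percentile(vals, [75, 25]))
    print(f"{mm.PARAMETER_SYMBOLS[name]:<10}{np.median(vals):>10.4f}{iqr:>10.4f}")

# delta ~ 0.9 rad recovers the injected retardance; PL ~ d0 * alignment
# resultant; Delta > 0 reflects the sub-resolution fiber dispersion.
summary = mm.summarize_sample(maps, mask, "phantom-01", "healthy")
print(f"\nper-sample median PL = {summary.median['PL']:.4f} "
      f"over {summary.n_pixels} tissue pixels")
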