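# Methods

## Forward model and reconstruction

A transmission polarimeter is modeled as generator → sample → analyzer. The
six canonical fully polarized states are H = (1,1,0,0), V = (1,−1,0,0),
P = (1,0,1,0), B = (1,0,−1,0), R = (1,0,0,1), L = (1,0,0,−1); the detected
intensity for generator state *s* and analyzer state *a* through a sample
with Mueller matrix *M* is *I = ½ aᵀ M s* (ideal-polarizer analyzer; the ½
fixes the absolute scale and cancels after m₁₁ normalization). The default
acquisition scheme is the full 6-generator × 4-analyzer (H, V, P, R) cross:
24 images, overdetermined for the 16 unknowns; a minimal well-conditioned
16-pair scheme (4×4) is provided for comparison. Which state pairs an
instrument acquires is a design choice; both schemes and arbitrary
user-supplied schemes are supported, and reconstruction accepts either
route:

* **stokes** (default): per generator, the output Stokes vector is
  synthesized from that generator's analyzer intensities (exactly, for
  analyzer sets spanning all four components), then *S_out = M S_in* is
  solved by least squares over generators;
* **pairs**: one least-squares fit of all pair intensities to vec(*M*).

Both agree exactly on noiseless data; with exactly 16 well-conditioned
pairs the fit equals algebraic inversion. Matrices are normalized per
pixel by m₁₁ before parameter extraction — the printed parameter bounds
(e.g. D ≤ 1) presume it.

Calibration compares a measured (mean, normalized) matrix against a known
reference (air, or a retarder of known retardance/orientation), reporting
per-element relative errors in percent; elements whose true value is zero
fall back to absolute error and are flagged.

Registration is translation-only, via phase cross-correlation against the
first image, with integer or subpixel (upsampled) modes. Inter-image drift
in this kind of instrument is small and translation-dominant; a rotation or
affine model is deliberately out of scope. Masking thresholds the total
transmitted intensity at 5% of its 99th percentile by default (background =
bare slide transmits negligibly in this configuration); an Otsu bimodal
split is available.

## Parameter extraction

The Lu–Chipman polar decomposition factors *M = M_Δ M_R M_D*: the
diattenuator is built from the first row, the depolarizer block is the
principal square root of m′m′ᵀ (m′ the 3×3 block of M M_D⁻¹) with its
overall sign tied to sign(det m′), and the retarder is M_Δ⁻¹M′. Degenerate
inputs (diattenuation within 10⁻⁶ of 1, or a singular depolarizer block)
take a pseudo-inverse path, project the retarder block onto the nearest
rotation, and are flagged per pixel. All arccos arguments are clipped to
[−1, 1]; ψ uses atan2, never a bare ratio.

Two printed-formula ambiguities are resolved by forward construction and
exposed behind a `paper_literal` switch:

* the linear/circular retardance split defaults to
  δ = arccos(√[(r₂₂+r₃₃)² + (r₃₂−r₂₃)²] − 1),
  ψ = ½ atan2(r₃₂−r₂₃, r₂₂+r₃₃) — the only sign placement under which a
  pure linear retarder returns (δ₀, 0) and a pure rotator returns (0, ±ψ₀);
  the literal variant uses (r₃₂+r₂₃) inside δ and (r₂₂−r₃₃) in ψ's
  denominator;
* P6 defaults to (m₁₃−m₃₁)/2, the symmetric partner of P5; the literal
  variant divides by 3.

Flattened typeset exponents in the source formulas (e.g. PL printed as
(m21)2+(m31)2) are restored to √(Σ squares) — the stated [0, 1] bounds
force this reading.

The catalogue order and names are fixed in `PARAMETER_NAMES`; kC = m₄₄ is
computed and carried as an auxiliary map but is not one of the 24 reported
parameters. Extraction is fully vectorized ((…, 4, 4) arrays throughout);
the batched path is tested identical (1e−12) to the per-matrix path and
against an independent scalar re-implementation.

**Range-bound caveat.** The b ∈ [0, 1] bound (and through it A) is not a
theorem for arbitrary realizable matrices: a near-half-wave retarder
composed with an off-axis diattenuator yields m₂₂+m₃₃ < 0. The bound holds
in the weakly retarding thin-section regime, so the property ensembles
sample δ ∈ [0, π/2] and |ψ| ≤ 0.2 rad; Δ ≤ 1 and PL ≤ 1 hold on the
unrestricted ensemble and are asserted there.

## Statistics

One value per sample and parameter: the median over masked, finite pixels
(mean and SD carried but untested). Two comparisons per parameter: pooled
EDS vs healthy, and cEDS vs hEDS — 48 tests. The Shapiro–Wilk gate is
applied per group (the conservative reading of "as appropriate"); Welch's
t-test is used only when both groups pass at α_norm = 0.05, otherwise
Mann–Whitney U — exact null distribution when both n ≤ 12 with no ties,
tie- and continuity-corrected normal approximation otherwise. Identical
constant groups short-circuit to p = 1 (degenerate-variance guard), and
groups whose spread is floating-point dust around a structurally zero
parameter are routed past the normality test to the rank test. Two-tailed,
α = 0.05, no outlier removal, no multiple-testing correction — matching
the analysis conventions of the originating study design; both conventions
are recorded in the report header.

## Synthetic phantoms

Per-pixel ground truth composes
M_depol(a,b,c) · M_rot(ψ₀) · M_ret(δ₀,θ) · M_diat(d₀,θ) — exactly the
factor order the polar decomposition inverts, so the noiseless round trip
is exact and provides a sharp oracle. Fiber orientation is axial: the
doubled angle is von Mises with concentration κ, smoothed (Gaussian, σ =
correlation length in pixels) on the doubled-angle unit vectors to add
spatial correlation without breaking the marginal symmetry.

Heterogeneity enters through **sub-resolution fiber-domain averaging**:
each pixel's retarder⊗diattenuator is the average of `n_domains` (default
12) domain matrices whose axes scatter around the local orientation with
concentration `micro_kappa`. A convex combination of realizable matrices
is realizable, genuinely depolarizing, and shrinks linear polarizance to
PL ≈ d₀ · resultant(κ) — monotone in κ — which grounds the qualitative
ordering the cohort is built to show (aligned healthy tissue: high PL;
disordered EDS tissue: low PL) in a physical mechanism rather than a
parameter dial.

Noise is signal-proportional Gaussian (shot-like), default σ = 2%, the
scale at which the simulated air calibration lands inside the 1–5% error
band typical of this instrument class. Background (bare slide) pixels
carry a neutral matrix at 1% transmission so masking is exercised. Drift
is per-image (dy, dx) translation, integer or subpixel.

Cohort defaults (`COHORT_DEFAULTS`; all invented, chosen once for
testability, not fitted to any dataset):

| group   | n  | κ | d₀ (mean ± sd) | δ₀ (rad)      | depolarizer |
|---------|----|---|----------------|---------------|-------------|
| healthy | 3  | 8 | 0.14 ± 0.02    | 0.70 ± 0.10   | 0.95 ± 0.02 |
| cEDS    | 5  | 2 | 0.07 ± 0.02    | 0.50 ± 0.08   | 0.86 ± 0.03 |
| hEDS    | 11 | 3 | 0.08 ± 0.02    | 0.80 ± 0.15   | 0.88 ± 0.03 |

hEDS carries higher, more dispersed retardance than cEDS so the
circular↔linear conversion magnitude rL separates the subtypes. All
randomness flows from one integer seed through `numpy.random.SeedSequence`
spawning; identical config + seed gives bit-identical cohorts.

**What the phantoms do not emulate:** multiple scattering and photon
transport, wavelength dependence (one 630 nm band is assumed), nanoscale
fibril structure, instrument-specific aberrations, and the absolute
pixel-value distributions of real biopsies. Passing tests therefore
demonstrate that the algorithms are correct and that effects of the
modeled kind are detectable at study-scale sample sizes — not that any
particular clinical effect size is reproduced.

## Problem sizes and numerical choices

Validation runs at sizes chosen to keep the suite quick while leaving the
conclusions unchanged: structural checks on 64×64 phantoms, the noiseless
round trip on a 128×128 phantom (1e−6 tolerance; observed error ~1e−15),
bound properties on 10⁴ random realizable matrices, rotation invariance at
1e−9 (observed ~1e−14), Mann–Whitney vs exhaustive enumeration at group
sizes (5, 11) (4368 assignments), type-I error over 1000 median-level null
replicates (expected within [0.03, 0.07]), and detection power over 200
cohort replicates at 24×24 pixels with the acquisition stage skipped
(ground-truth matrices decomposed directly — the acquisition stage is
validated separately and adds only unbiased noise).

Degenerate inputs: empty masks raise; all-zero images mask to empty with a
warning; non-finite pixels inside the mask are excluded and counted;
rank-deficient acquisition schemes raise an ill-conditioned-design error.

## Known limitations

* The Lu–Chipman factor order is an assumption; media whose true factor
  order differs will show order-dependent parameter bias (inherent to the
  method, not this implementation).
* ψ from atan2 can leave [−π/4, π/4] when m₂₂+m₃₃ < 0 (strong combined
  retardance); within the thin-section regime it stays inside.
* The registration model is translation-only; rotational drift beyond a
  fraction of a pixel at the field edge is not corrected.
* Exact Mann–Whitney p-values require tie-free data; tied medians fall
  back to the corrected normal approximation even at small n.
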