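# muellermap

Label-free Mueller-matrix polarimetry analysis for thin tissue sections,
built around the use case of characterizing dermal collagen organization in
connective-tissue disease (Ehlers–Danlos syndromes) from polarized-light
microscopy of unstained skin-biopsy sections.

The package covers the complete computational chain:

1. **Acquisition model** — a polarization state generator prepares one of
   the six canonical Stokes states (H, V, P, B, R, L), the sample acts as a
   per-pixel 4×4 Mueller matrix *M*, and an analyzer records
   *I(g, a) = ½ aᵀ M s*. The default scheme crosses all 6 generator states
   with 4 analyzer states — 24 images, an overdetermined design for the 16
   unknown elements.
2. **Reconstruction** — per pixel, output Stokes vectors
   *S* = (H+V, H−V, P−B, R−L) are assembled per generator state and
   *S_out = M S_in* is solved by least squares (an equivalent direct
   pair-wise fit is available). Includes calibration against known
   references, translation-only co-registration, and intensity-based
   tissue masking.
3. **Parameter extraction** — 24 polarimetric parameters from four
   frameworks:
   * polar decomposition *M = M_Δ M_R M_D* (Lu–Chipman):
     Δ = 1 − |tr M_Δ − 1|/3, R = arccos(tr M_R/2 − 1),
     D = √(m₁₂² + m₁₃² + m₁₄²), with the linear/circular split δ, ψ of R;
   * matrix transformation: t1, b, β, A from the central 3×3 block;
   * rotation invariants: PL, DL, PC, DC, qL, rL (plus auxiliary kC = m₄₄);
   * linear identities: P1…P8 and Ptms = √(P1² + P2²), departures from
     ideal pure linear retarders/diattenuators and from mirror-transverse
     symmetry.
4. **Statistics** — per-sample medians over masked pixels, then two
   comparisons per parameter (pooled EDS vs healthy; cEDS vs hEDS) with a
   Shapiro–Wilk normality gate choosing Welch's t-test or the Mann–Whitney
   U test; two-tailed p-values at α = 0.05, no outlier removal, no
   multiple-testing correction.
5. **Synthetic phantoms** — since no raw biopsy data are available, every
   stage is validated on phantoms with known ground truth: per-pixel
   matrices composed of depolarizer · rotator · retarder · diattenuator
   factors (the exact order the polar decomposition inverts), spatially
   correlated fiber-orientation fields, sub-resolution fiber-domain
   dispersion (which physically produces depolarization and lowers linear
   polarizance), shot-like noise, stage drift, and study-shaped cohorts
   (3 healthy / 5 cEDS / 11 hEDS).

## Worked example

`examples/02_parameter_maps.py` builds an aligned-fiber phantom (retardance
0.9 rad, 12% diattenuation, orientation concentration κ = 8), simulates the
24-image acquisition at 2% noise, reconstructs, and extracts all parameter
maps:

```
24 parameter maps on a (64, 64) grid

parameter     median       iqr
δ             0.8541    0.0334
R             0.8543    0.0335
D             0.1138    0.0189
PL            0.1080    0.0096
rL            0.6955    0.0386
Δ             0.0925    0.0201
b             0.7683    0.0149
β             0.0075    0.0097
ψ            -0.0000    0.0074

per-sample median PL = 0.1080 over 2608 tissue pixels
```

The recovered linear retardance δ sits at the injected 0.9 rad minus the
averaging loss from sub-resolution fiber dispersion; R ≈ δ because no
optical rotation was injected (ψ ≈ 0); PL ≈ d₀ × alignment resultant; the
nonzero Δ is genuine depolarization created by averaging dispersed
fiber-domain matrices within each pixel.

`examples/03_cohort_comparison.py` runs the full statistical stage on a
simulated 19-sample cohort and prints the significant parameters per
comparison — with the default effect sizes, alignment- and
polarizance-related parameters (PL, Δ, t1, qL, rL, …) separate EDS from
healthy, and retardance-related parameters separate the EDS subtypes.

A thin CLI mirrors the library:
`muellermap simulate | reconstruct | decompose | summarize | compare | run-all`.

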