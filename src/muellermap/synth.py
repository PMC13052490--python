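"""Synthetic optical phantoms and simulated cohorts with known ground truth.

No raw biopsy data ship with this package, so every pipeline stage is
validated on phantoms: per-pixel Mueller matrices composed (in the
depolarizer @ rotator @ retarder @ diattenuator order that the polar
decomposition inverts) from spatially varying optical-property fields,
imaged through the simulated 24-pair acquisition, and grouped into cohorts
mimicking the study structure (3 healthy, 5 cEDS, 11 hEDS).

The mechanism linking fiber organization to the polarimetric contrast is
sub-resolution domain averaging: each pixel's matrix is the average of
``n_domains`` fiber-domain matrices whose axes scatter around the local
orientation with axial von Mises concentration ``micro_kappa``.  Averaging
dispersed retarder/diattenuator matrices produces genuine depolarization and
shrinks the linear polarizance to ``PL ~ d0 * resultant(micro_kappa)``, so
aligned (healthy-like) tissue has higher PL than disordered (EDS-like)
tissue, and median PL rises monotonically with the concentration.

All defaults are study-shaped but invented (the source study publishes no
raw values); they are collected in ``COHORT_DEFAULTS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from .acquisition import DEFAULT_SCHEME, IntensityStack, MuellerImage, simulate_stack
from .elements import (
    diagonal_depolarizer,
    linear_diattenuator,
    linear_retarder,
    realizability_check,
    rotator,
)

__all__ = [
    "COHORT_DEFAULTS",
    "PhantomSpec",
    "GroupConfig",
    "CohortConfig",
    "CohortSample",
    "orientation_field",
    "compose_pixel",
    "compose_field",
    "make_sample",
    "make_cohort",
    "realizability_check",
]


def orientation_field(
    height: int,
    width: int,
    kappa: float,
    mean_direction: float = 0.0,
    correlation_length: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Spatially smooth axial fiber-orientation map on [0, pi).

    Orientations are axial (a fiber at ``theta`` equals one at
    ``theta + pi``), so the doubled angle ``2 theta`` is drawn from a von
    Mises distribution with concentration ``kappa`` (``kappa = 0``: uniform;
    ``kappa -> inf``: perfectly aligned at ``mean_direction``).  A Gaussian
    smoothing of the doubled-angle unit vectors with sigma
    ``correlation_length`` (pixels) introduces spatial correlation without
    breaking the marginal symmetry.
    """
    if kappa < 0:
        raise ValueError("concentration kappa must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    two_theta = rng.vonmises(2.0 * mean_direction, kappa, size=(height, width))
    if correlation_length > 0:
        c = ndi.gaussian_filter(np.cos(two_theta), correlation_length, mode="wrap")
        s = ndi.gaussian_filter(np.sin(two_theta), correlation_length, mode="wrap")
        two_theta = np.arctan2(s, c)
    return (two_theta / 2.0) % np.pi


def compose_pixel(
    delta0=0.0, theta=0.0, psi0=0.0, d0=0.0, d_axis=None, depol=(1.0, 1.0, 1.0)
) -> np.ndarray:
    """Compose the per-pixel matrix ``M_depol @ M_rot(psi0) @ M_ret(delta0, theta) @ M_diat(d0, d_axis)``.

    Exactly the factor order the polar decomposition inverts, so the
    noiseless round trip recovers every factor.  Broadcasts over array
    arguments; ``d_axis`` defaults to the retarder axis ``theta`` (fibers
    both retard and diattenuate along their own axis).
    """
    if d_axis is None:
        d_axis = theta
    a, b, c = (np.asarray(x, dtype=float) for x in depol)
    M = (
        diagonal_depolarizer(a, b, c)
        @ rotator(psi0)
        @ linear_retarder(delta0, theta)
        @ linear_diattenuator(d0, d_axis)
    )
    ok, diag = realizability_check(M.reshape(-1, 4, 4)[0])
    if not ok:  # broadcast sanity check on the first element only (cheap)
        raise ValueError(f"composed matrix is not physically realizable: {diag['failure']}")
    return M


def compose_field(
    delta0,
    theta,
    psi0,
    d0,
    d_axis=None,
    depol=(1.0, 1.0, 1.0),
    micro_kappa: float | None = None,
    n_domains: int = 12,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-pixel matrices for whole maps, optionally with sub-pixel fiber dispersion.

    With ``micro_kappa`` set, each pixel's retarder/diattenuator pair is
    averaged over ``n_domains`` domain axes drawn (axially) around the local
    orientation; the average is a convex combination of realizable matrices,
    hence realizable, and is genuinely depolarizing.
    """
    delta0 = np.asarray(delta0, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if d_axis is None:
        d_axis = theta
    if micro_kappa is None or np.isinf(micro_kappa):
        return compose_pixel(delta0, theta, psi0, d0, d_axis, depol)
    if rng is None:
        rng = np.random.default_rng()
    shape = np.broadcast_shapes(delta0.shape, theta.shape)
    offsets = rng.vonmises(0.0, micro_kappa, size=shape + (n_domains,)) / 2.0
    th = theta[..., None] + offsets
    ax = np.asarray(d_axis, dtype=float)[..., None] + offsets
    core = linear_retarder(delta0[..., None], th) @ linear_diattenuator(
        np.asarray(d0, dtype=float)[..., None]
        if np.ndim(d0)
        else np.full(shape + (1,), float(d0)),
        ax,
    )
    avg = core.mean(axis=-3)
    a, b, c = (np.asarray(x, dtype=float) for x in depol)
    return diagonal_depolarizer(a, b, c) @ rotator(psi0) @ avg


@dataclass
class PhantomSpec:
    """Ground-truth optical-property fields of one synthetic sample.

    Per-pixel maps (all ``(height, width)``, broadcastable scalars allowed
    at construction through :meth:`generate`): linear retardance ``delta0``
    (rad), fiber orientation ``theta`` (rad, axial), optical rotation
    ``psi0`` (rad), diattenuation ``d0`` with axis ``d_axis``, depolarizer
    diagonal ``depol`` (a, b, c).  ``foreground`` flags tissue pixels;
    background models the bare slide (negligible transmission).
    """

    height: int
    width: int
    delta0: np.ndarray
    theta: np.ndarray
    psi0: np.ndarray
    d0: np.ndarray
    d_axis: np.ndarray
    depol: tuple
    foreground: np.ndarray
    micro_kappa: float | None = None
    n_domains: int = 12
    seed: int = 0

    @classmethod
    def generate(
        cls,
        height: int = 64,
        width: int = 64,
        delta0: float = 0.6,
        kappa: float = 5.0,
        mean_direction: float = 0.0,
        correlation_length: float = 3.0,
        psi0: float = 0.0,
        d0: float = 0.10,
        depol: tuple = (0.95, 0.95, 0.90),
        foreground: str | np.ndarray = "ellipse",
        micro_kappa: float | None = None,
        n_domains: int = 12,
        seed: int = 0,
    ) -> "PhantomSpec":
        """Build a spec with a smooth orientation field and an elliptical tissue region."""
        rng = np.random.default_rng(seed)
        theta = orientation_field(
            height, width, kappa, mean_direction, correlation_length, seed=rng
        )
        if isinstance(foreground, str):
            if foreground == "ellipse":
                yy, xx = np.mgrid[:height, :width]
                cy, cx = (height - 1) / 2, (width - 1) / 2
                fg = ((yy - cy) / (0.45 * height)) ** 2 + ((xx - cx) / (0.45 * width)) ** 2 <= 1
            elif foreground == "full":
                fg = np.ones((height, width), dtype=bool)
            else:
                raise ValueError(f"unknown foreground shape {foreground!r}")
        else:
            fg = np.asarray(foreground, dtype=bool)
        return cls(
            height=height,
            width=width,
            delta0=np.full((height, width), float(delta0)),
            theta=theta,
            psi0=np.full((height, width), float(psi0)),
            d0=np.full((height, width), float(d0)),
            d_axis=theta,
            depol=tuple(float(x) for x in depol),
            foreground=fg,
            micro_kappa=micro_kappa,
            n_domains=n_domains,
            seed=seed,
        )


def make_sample(
    spec: PhantomSpec,
    scheme=DEFAULT_SCHEME,
    noise_sigma: float = 0.0,
    drift: np.ndarray | None = None,
    gain: float = 1.0,
    background_transmission: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[MuellerImage, IntensityStack]:
    """Compose the ground-truth Mueller image and simulate its acquisition.

    Background pixels carry a neutral matrix scaled to
    ``background_transmission`` so they produce near-zero intensity and
    exercise the masking stage.  Returns ``(truth, stack)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    M = compose_field(
        spec.delta0,
        spec.theta,
        spec.psi0,
        spec.d0,
        spec.d_axis,
        spec.depol,
        micro_kappa=spec.micro_kappa,
        n_domains=spec.n_domains,
        rng=rng,
    )
    M = np.where(
        spec.foreground[..., None, None],
        M,
        background_transmission * np.eye(4),
    )
    truth = MuellerImage(M, normalized=False)
    stack = simulate_stack(
        truth, scheme=scheme, gain=gain, noise_sigma=noise_sigma, drift=drift, rng=rng
    )
    return truth, stack


@dataclass
class GroupConfig:
    """Sampling distributions of per-sample phantom parameters for one group."""

    n: int
    kappa: float
    d0_mean: float
    d0_sd: float
    delta0_mean: float
    delta0_sd: float
    depol_mean: float
    depol_sd: float
    psi0_mean: float = 0.0
    psi0_sd: float = 0.01


#: Study-shaped cohort defaults (invented; see module docstring).  Healthy
#: tissue: aligned fibers (high kappa), stronger diattenuation, weaker
#: depolarization.  EDS groups: disordered fibers, lower diattenuation;
#: hEDS carries higher and more dispersed retardance than cEDS (rL contrast).
COHORT_DEFAULTS: dict[str, GroupConfig] = {
    "healthy": GroupConfig(
        n=3, kappa=8.0, d0_mean=0.14, d0_sd=0.02,
        delta0_mean=0.70, delta0_sd=0.10, depol_mean=0.95, depol_sd=0.02,
    ),
    "cEDS": GroupConfig(
        n=5, kappa=2.0, d0_mean=0.07, d0_sd=0.02,
        delta0_mean=0.50, delta0_sd=0.08, depol_mean=0.86, depol_sd=0.03,
        psi0_sd=0.02,
    ),
    "hEDS": GroupConfig(
        n=11, kappa=3.0, d0_mean=0.08, d0_sd=0.02,
        delta0_mean=0.80, delta0_sd=0.15, depol_mean=0.88, depol_sd=0.03,
        psi0_sd=0.02,
    ),
}


@dataclass
class CohortConfig:
    """A simulated multi-sample cohort: group distributions plus imaging settings."""

    groups: dict[str, GroupConfig] = field(
        default_factory=lambda: {k: replace(v) for k, v in COHORT_DEFAULTS.items()}
    )
    height: int = 64
    width: int = 64
    correlation_length: float = 3.0
    n_domains: int = 12
    noise_sigma: float = 0.02
    background_transmission: float = 0.01
    simulate_acquisition: bool = True
    seed: int = 0

    @classmethod
    def null(cls, **kwargs) -> "CohortConfig":
        """All three groups share one distribution (no true effect)."""
        ref = COHORT_DEFAULTS["hEDS"]
        groups = {
            name: replace(ref, n=COHORT_DEFAULTS[name].n) for name in COHORT_DEFAULTS
        }
        return cls(groups=groups, **kwargs)


@dataclass
class CohortSample:
    """One simulated sample: ground truth, optional acquisition, and drawn parameters."""

    sample_id: str
    group: str
    truth: MuellerImage
    stack: IntensityStack | None
    truth_params: dict[str, float]
    foreground: np.ndarray


def make_cohort(config: CohortConfig) -> list[CohortSample]:
    """Draw a full cohort, deterministic per ``config.seed``.

    Per sample: group-level distributions give scalar optical parameters;
    an orientation field with the group's concentration plus sub-pixel
    domain dispersion (``micro_kappa`` = group ``kappa``) gives the spatial
    structure; the acquisition is simulated unless
    ``config.simulate_acquisition`` is off (ground truth only, the fast
    path for large replicate studies).
    """
    for name, g in config.groups.items():
        if g.n < 3:
            raise ValueError(f"group {name!r} has n={g.n} < 3 (statistics precondition)")
    ss = np.random.SeedSequence(config.seed)
    samples: list[CohortSample] = []
    idx = 0
    for name, g in config.groups.items():
        child_seeds = ss.spawn(g.n)
        for k in range(g.n):
            rng = np.random.default_rng(child_seeds[k])
            d0 = float(np.clip(rng.normal(g.d0_mean, g.d0_sd), 0.005, 0.9))
            delta0 = float(np.clip(rng.normal(g.delta0_mean, g.delta0_sd), 0.05, 3.0))
            depol = float(np.clip(rng.normal(g.depol_mean, g.depol_sd), 0.3, 1.0))
            psi0 = float(rng.normal(g.psi0_mean, g.psi0_sd))
            mean_dir = float(rng.uniform(0, np.pi))
            spec = PhantomSpec.generate(
                height=config.height,
                width=config.width,
                delta0=delta0,
                kappa=g.kappa,
                mean_direction=mean_dir,
                correlation_length=config.correlation_length,
                psi0=psi0,
                d0=d0,
                depol=(depol, depol, max(0.0, depol - 0.05)),
                micro_kappa=g.kappa,
                n_domains=config.n_domains,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            truth, stack = (None, None)
            if config.simulate_acquisition:
                truth, stack = make_sample(
                    spec,
                    noise_sigma=config.noise_sigma,
                    background_transmission=config.background_transmission,
                    rng=np.random.default_rng(child_seeds[k].spawn(1)[0]),
                )
            else:
                M = compose_field(
                    spec.delta0, spec.theta, spec.psi0, spec.d0, spec.d_axis,
                    spec.depol, micro_kappa=spec.micro_kappa,
                    n_domains=spec.n_domains,
                    rng=np.random.default_rng(child_seeds[k].spawn(1)[0]),
                )
                M = np.where(
                    spec.foreground[..., None, None], M,
                    config.background_transmission * np.eye(4),
                )
                truth = MuellerImage(M, normalized=False)
            samples.append(
                CohortSample(
                    sample_id=f"{name}-{k + 1:02d}",
                    group=name,
                    truth=truth,
                    stack=stack,
                    truth_params={
                        "kappa": g.kappa, "d0": d0, "delta0": delta0,
                        "depol": depol, "psi0": psi0, "mean_direction": mean_dir,
                    },
                    foreground=spec.foreground,
                )
            )
            idx += 1
    return samples
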