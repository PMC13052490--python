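"""Forward model and per-pixel Mueller-matrix reconstruction.

The transmission polarimeter prepares a generator state ``s`` (PSG), passes
the beam through the sample (Mueller matrix ``M``), and analyzes it with an
ideal-polarizer analyzer state ``a`` (PSA).  The detected intensity is

    I(g, a) = 1/2 * a . (M s)

(the 1/2 is the ideal-analyzer transmission convention; its absolute scale
cancels once matrices are normalized by m11).  A measurement scheme is an
ordered list of (generator, analyzer) label pairs; the default scheme uses
all six generator states crossed with the four analyzers H, V, P, R — 24
images, an overdetermined design for the 16 unknown matrix elements.

Reconstruction solves the linear system per pixel, either by assembling an
output Stokes vector per generator state from its analyzer intensities and
solving ``S_out = M S_in`` in the least-squares sense (``via="stokes"``), or
by a direct least-squares fit of all state-pair intensities to the 16
elements (``via="pairs"``).  The two routes agree exactly on noiseless data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .polarization import state_to_stokes

__all__ = [
    "DEFAULT_SCHEME",
    "SIXTEEN_PAIR_SCHEME",
    "IntensityStack",
    "MuellerImage",
    "TissueMask",
    "CalibrationReport",
    "simulate_intensity",
    "simulate_stack",
    "measure_output_stokes",
    "reconstruct_mueller",
    "calibrate",
    "register_stack",
    "compute_mask",
]

#: Default 24-pair acquisition scheme: 6 generators x 4 analyzers.
DEFAULT_SCHEME: tuple[tuple[str, str], ...] = tuple(
    (g, a) for g in "HVPBRL" for a in "HVPR"
)

#: Minimal well-conditioned scheme: 4 independent generators x 4 analyzers.
SIXTEEN_PAIR_SCHEME: tuple[tuple[str, str], ...] = tuple(
    (g, a) for g in "HVPR" for a in "HVPR"
)


class IncompleteMeasurementError(ValueError):
    """A required analyzer intensity is missing."""


class IllConditionedDesignError(ValueError):
    """The acquisition scheme cannot determine all 16 matrix elements."""


@dataclass
class IntensityStack:
    """Polarization-resolved intensity images, one per (generator, analyzer) pair."""

    images: np.ndarray  # (n_pairs, H, W), non-negative
    states: tuple[tuple[str, str], ...]
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.states = tuple((g, a) for g, a in self.states)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_pairs, H, W) array")
        if len(self.states) != self.images.shape[0]:
            raise ValueError(
                f"{self.images.shape[0]} images but {len(self.states)} state pairs"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class MuellerImage:
    """Per-pixel 4x4 Mueller matrix field over an image grid."""

    elements: np.ndarray  # (H, W, 4, 4)
    normalized: bool = False
    pixel_size: float = 1.0

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.shape[-2:] != (4, 4):
            raise ValueError("elements must have trailing shape (4, 4)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elements.shape[:2]

    def normalize(self) -> "MuellerImage":
        """Divide every pixel matrix by its m11; pixels with m11 <= 0 become NaN."""
        if self.normalized:
            return self
        m11 = self.elements[..., 0:1, 0:1]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(m11 > 0, self.elements / m11, np.nan)
        return MuellerImage(out, normalized=True, pixel_size=self.pixel_size)


@dataclass
class TissueMask:
    """Boolean foreground mask with the intensity threshold that produced it."""

    mask: np.ndarray
    threshold_used: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CalibrationReport:
    """Per-element agreement of a measured matrix with a reference truth."""

    reference_name: str
    per_element_error: np.ndarray  # (4, 4), percent
    max_error: float  # percent
    absolute_fallback: np.ndarray = field(default=None)  # (4,4) bool: abs error used

    def __post_init__(self):
        self.per_element_error = np.asarray(self.per_element_error, dtype=float)
        if self.absolute_fallback is None:
            self.absolute_fallback = np.zeros((4, 4), dtype=bool)


def simulate_intensity(M: np.ndarray, generator: str, analyzer: str) -> np.ndarray:
    """Detected intensity ``1/2 a . (M s)`` for one state pair (broadcasts over pixels)."""
    s = state_to_stokes(generator)
    a = state_to_stokes(analyzer)
    M = np.asarray(M, dtype=float)
    return 0.5 * np.einsum("i,...ij,j->...", a, M, s)


def _design_matrix(states) -> np.ndarray:
    """Rows 0.5 * kron(a, s): intensity = row . vec(M) with row-major vec."""
    return np.array(
        [0.5 * np.kron(state_to_stokes(a), state_to_stokes(g)) for g, a in states]
    )


def simulate_stack(
    M_img: "MuellerImage | np.ndarray",
    scheme=DEFAULT_SCHEME,
    gain: float = 1.0,
    noise_sigma: float = 0.0,
    drift: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    pixel_size: float = 1.0,
) -> IntensityStack:
    """Simulate a polarization-resolved acquisition of a Mueller-matrix field.

    Parameters
    ----------
    M_img
        Mueller image (or raw ``(H, W, 4, 4)`` array) of the sample.
    scheme
        Ordered (generator, analyzer) label pairs.
    gain
        Overall intensity scale (source x detector).
    noise_sigma
        Relative standard deviation of signal-proportional (shot-like)
        Gaussian noise: ``I -> I (1 + sigma N(0,1))``, clipped at zero.
    drift
        Optional ``(n_pairs, 2)`` per-image ``(dy, dx)`` translations in
        pixels (image 0 should be ``(0, 0)``); emulates inter-image stage drift.
    """
    if isinstance(M_img, MuellerImage):
        E = M_img.elements
        pixel_size = M_img.pixel_size
    else:
        E = np.asarray(M_img, dtype=float)
    A = _design_matrix(scheme)  # (n_pairs, 16)
    vec = E.reshape(E.shape[:-2] + (16,))  # (H, W, 16)
    intensities = gain * np.einsum("pk,hwk->phw", A, vec)
    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        shifted = np.empty_like(intensities)
        for p in range(intensities.shape[0]):
            dy, dx = drift[p]
            if dy == 0 and dx == 0:
                shifted[p] = intensities[p]
            elif float(dy).is_integer() and float(dx).is_integer():
                shifted[p] = np.roll(intensities[p], (int(dy), int(dx)), axis=(0, 1))
            else:
                shifted[p] = ndi.shift(intensities[p], (dy, dx), order=3, mode="wrap")
        intensities = shifted
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        intensities = intensities * (1.0 + noise_sigma * rng.standard_normal(intensities.shape))
    intensities = np.clip(intensities, 0.0, None)
    return IntensityStack(intensities, tuple(scheme), pixel_size=pixel_size)


def measure_output_stokes(intensities: dict[str, np.ndarray]) -> np.ndarray:
    """Assemble an output Stokes vector from the six analyzer intensities.

    ``S = (H + V, H - V, P - B, R - L)``; each value may be a scalar or an
    image, and the result stacks on the last axis.
    """
    missing = [k for k in "HVPBRL" if k not in intensities]
    if missing:
        raise IncompleteMeasurementError(f"missing analyzer intensities: {missing}")
    H, V, P, B, R, L = (np.asarray(intensities[k], dtype=float) for k in "HVPBRL")
    return np.stack([H + V, H - V, P - B, R - L], axis=-1)


def _stokes_synthesis_matrix(analyzers: tuple[str, ...]) -> np.ndarray:
    """Linear map from analyzer intensities to the output Stokes vector.

    With the 1/2 ideal-analyzer convention, ``I(a) = 1/2 (S_out . a)``; the
    four Stokes components are recovered by least squares from the available
    analyzer projections (exact for {H,V,P,B,R,L} or {H,V,P,R}).
    """
    A = 0.5 * np.array([state_to_stokes(a) for a in analyzers])  # (n_a, 4)
    if np.linalg.matrix_rank(A) < 4:
        raise IllConditionedDesignError(
            f"analyzer set {analyzers} does not span all Stokes components"
        )
    return np.linalg.pinv(A)  # (4, n_a)


def reconstruct_mueller(stack: IntensityStack, via: str = "stokes") -> MuellerImage:
    """Reconstruct the per-pixel Mueller matrix from a polarization-resolved stack.

    Parameters
    ----------
    stack
        At least 16 state pairs whose generators span 4 independent Stokes
        vectors; the default 24-pair scheme is overdetermined.
    via
        ``"stokes"`` — per generator state, synthesize the output Stokes
        vector from that generator's analyzer intensities, then solve
        ``S_out = M S_in`` by least squares over generators.
        ``"pairs"`` — single least-squares fit of all pair intensities to
        the 16 elements.  Identical on noiseless data.

    Returns
    -------
    MuellerImage
        Unnormalized per-pixel matrices; call ``.normalize()`` before
        parameter extraction.
    """
    if len(stack.states) < 16:
        raise IllConditionedDesignError(
            f"{len(stack.states)} state pairs given; >= 16 required"
        )
    n, h, w = stack.images.shape
    if via == "pairs":
        A = _design_matrix(stack.states)  # (n, 16)
        if np.linalg.matrix_rank(A) < 16:
            raise IllConditionedDesignError("state pairs do not determine all 16 elements")
        sol = np.linalg.pinv(A) @ stack.images.reshape(n, h * w)
        return MuellerImage(sol.T.reshape(h, w, 4, 4), pixel_size=stack.pixel_size)
    if via != "stokes":
        raise ValueError(f"unknown reconstruction mode {via!r}")

    generators = []
    for g, _ in stack.states:
        if g not in generators:
            generators.append(g)
    S_in = np.array([state_to_stokes(g) for g in generators]).T  # (4, n_g)
    if np.linalg.matrix_rank(S_in) < 4:
        raise IllConditionedDesignError(
            f"generator set {generators} spans fewer than 4 Stokes dimensions"
        )
    # Synthesize S_out per generator from that generator's analyzers.
    S_out = np.empty((4, len(generators), h, w))
    for i, g in enumerate(generators):
        idx = [k for k, (gg, _) in enumerate(stack.states) if gg == g]
        analyzers = tuple(stack.states[k][1] for k in idx)
        T = _stokes_synthesis_matrix(analyzers)  # (4, n_a)
        S_out[:, i] = np.einsum("ca,ahw->chw", T, stack.images[idx])
    # Solve M S_in = S_out  =>  M = S_out pinv(S_in), per pixel.
    P = np.linalg.pinv(S_in)  # (n_g, 4)
    M = np.einsum("cghw,gj->hwcj", S_out, P)
    return MuellerImage(M, pixel_size=stack.pixel_size)


def calibrate(
    measured: "MuellerImage | np.ndarray",
    reference_truth: np.ndarray,
    reference_name: str = "reference",
    zero_tol: float = 1e-6,
) -> CalibrationReport:
    """Compare a measured (mean, normalized) matrix with a known reference.

    Per-element relative error in percent; elements whose true value is
    (numerically) zero fall back to absolute error, expressed in percent of
    m11 = 1 and flagged in the report.
    """
    if isinstance(measured, MuellerImage):
        E = measured.normalize().elements
        M = np.nanmean(E.reshape(-1, 4, 4), axis=0)
    else:
        M = np.asarray(measured, dtype=float)
        M = M / M[0, 0]
    T = np.asarray(reference_truth, dtype=float)
    T = T / T[0, 0]
    zero = np.abs(T) < zero_tol
    err = np.empty((4, 4))
    err[~zero] = 100.0 * np.abs((M[~zero] - T[~zero]) / T[~zero])
    err[zero] = 100.0 * np.abs(M[zero] - T[zero])
    return CalibrationReport(
        reference_name=reference_name,
        per_element_error=err,
        max_error=float(err.max()),
        absolute_fallback=zero,
    )


def register_stack(
    stack: IntensityStack, subpixel: bool = True, upsample_factor: int = 20
) -> tuple[IntensityStack, np.ndarray]:
    """Translation-align every image to the first by phase cross-correlation.

    Returns the registered stack and the ``(n_pairs, 2)`` array of recovered
    ``(dy, dx)`` shifts (the translation that was removed from each image).
    Constant (featureless) images are left in place with a warning.
    """
    ref = stack.images[0]
    out = stack.images.copy()
    shifts = np.zeros((len(stack.states), 2))
    for p in range(1, out.shape[0]):
        img = stack.images[p]
        if np.ptp(img) == 0 or np.ptp(ref) == 0:
            warnings.warn(f"image {p} (or reference) is featureless; registration skipped")
            continue
        shift, _, _ = phase_cross_correlation(
            ref, img, upsample_factor=upsample_factor if subpixel else 1,
            normalization=None,
        )
        shifts[p] = -shift  # drift that had been applied to the image
        if subpixel and not np.allclose(shift, np.round(shift)):
            out[p] = ndi.shift(img, shift, order=3, mode="wrap")
        else:
            out[p] = np.roll(img, tuple(int(s) for s in np.round(shift)), axis=(0, 1))
    return replace(stack, images=out), shifts


def compute_mask(
    total_intensity: np.ndarray,
    method: str = "fraction",
    fraction: float = 0.05,
    percentile: float = 99.0,
) -> TissueMask:
    """Threshold the total-intensity image into tissue foreground vs background.

    ``method="fraction"`` (default): threshold at ``fraction`` of the robust
    maximum (the given intensity percentile) — excludes pixels of negligible
    transmitted light.  ``method="otsu"``: automatic bimodal split.
    """
    I = np.asarray(total_intensity, dtype=float)
    if np.any(I < 0):
        raise ValueError("intensity image must be non-negative")
    if np.ptp(I) == 0 and I.flat[0] == 0:
        warnings.warn("all-zero intensity image: mask is empty")
        return TissueMask(np.zeros_like(I, dtype=bool), threshold_used=0.0)
    if method == "fraction":
        thr = fraction * np.percentile(I, percentile)
    elif method == "otsu":
        thr = float(threshold_otsu(I))
    else:
        raise ValueError(f"unknown mask method {method!r}")
    mask = I > thr
    if not mask.any():
        warnings.warn("mask is empty: no pixel exceeds the threshold")
    return TissueMask(mask, threshold_used=float(thr))
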