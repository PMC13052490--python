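"""Polarimetric parameter extraction from normalized Mueller matrices.

Four complementary frameworks turn the 16 raw matrix elements into 24
interpretable parameters:

* **Polar decomposition** (Lu-Chipman): ``M = M_Delta M_R M_D`` — a
  depolarizer, a retarder, and a diattenuator — yielding depolarization
  power ``Delta``, total retardance ``R`` with linear/circular split
  ``delta``/``psi``, and diattenuation ``D``.
* **Matrix transformation**: ``t1``, ``b``, ``beta``, ``A`` from the central
  3x3 block, measures of anisotropy, depolarization and optical rotation.
* **Rotation invariants**: corner/edge magnitudes ``PL``, ``DL``, ``PC``,
  ``DC``, ``qL``, ``rL`` (and auxiliary ``kC = m44``) that are insensitive
  to in-plane sample orientation.
* **Linear identities**: ``P1..P8`` and ``Ptms``, departures from ideal
  pure linear retarders / diattenuators and from mirror-transverse symmetry.

All functions are vectorized over leading axes: a single 4x4 matrix and a
whole ``(H, W, 4, 4)`` image go through the same code path.  Matrices are
assumed m11-normalized (the parameter bounds presume it); ``extract_all``
normalizes if needed.

Element indices in docstrings are 1-based (``m11`` is the top-left element).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARAMETER_NAMES",
    "PARAMETER_SYMBOLS",
    "PolarDecomposition",
    "ParameterMaps",
    "lu_chipman",
    "depolarization_power",
    "retardance",
    "diattenuation",
    "linear_circular_retardance",
    "mmt_params",
    "mmri_params",
    "mmli_params",
    "extract_all",
]

#: The 24 reported parameters, in catalogue order.
PARAMETER_NAMES: tuple[str, ...] = (
    "Delta", "b", "PL", "PC", "D", "DC", "DL", "t1", "A",
    "P5", "P6", "P7", "P8",
    "R", "delta", "qL", "rL", "P1", "P2", "P3", "P4", "Ptms",
    "psi", "beta",
)

#: Display symbols (Greek where conventional) for reports and figures.
PARAMETER_SYMBOLS: dict[str, str] = {
    "Delta": "Δ", "delta": "δ", "psi": "ψ", "beta": "β",
    **{n: n for n in PARAMETER_NAMES if n not in {"Delta", "delta", "psi", "beta"}},
}

#: Theoretical range of each parameter (used for report sanity checks).
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "Delta": (0, 1), "b": (0, 1), "PL": (0, 1), "PC": (-1, 1), "D": (0, 1),
    "DC": (-1, 1), "DL": (0, 1), "t1": (0, 1), "A": (0, 1),
    "P5": (-1, 1), "P6": (-1, 1), "P7": (0, 1), "P8": (-1, 1),
    "R": (0, np.pi), "delta": (0, np.pi), "qL": (0, 1), "rL": (0, 1),
    "P1": (-1, 1), "P2": (-1, 1), "P3": (0, 1), "P4": (-1, 1),
    "Ptms": (0, np.sqrt(2)), "psi": (-np.pi / 4, np.pi / 4), "beta": (0, 1),
    "kC": (-1, 1),
}


@dataclass
class PolarDecomposition:
    """Lu-Chipman factors ``M = M_delta @ M_R @ M_D`` (batched over leading axes)."""

    M_delta: np.ndarray
    M_R: np.ndarray
    M_D: np.ndarray
    residual: np.ndarray  # max |M_delta M_R M_D - M| per matrix
    degenerate: np.ndarray  # bool: pseudo-inverse fallback used


@dataclass
class ParameterMaps:
    """The 24 named parameter maps (plus auxiliary kC) on one image grid."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    n_invalid: int = 0  # masked pixels where a parameter was non-finite
    kC: np.ndarray = field(default=None)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def names(self) -> tuple[str, ...]:
        return PARAMETER_NAMES


def _as_batch(M: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    M = np.asarray(M, dtype=float)
    if M.shape[-2:] != (4, 4):
        raise ValueError("expected trailing shape (4, 4)")
    lead = M.shape[:-2]
    return M.reshape(-1, 4, 4), lead


def lu_chipman(M: np.ndarray, degeneracy_tol: float = 1e-6) -> PolarDecomposition:
    """Polar-decompose normalized Mueller matrices into depolarizer, retarder, diattenuator.

    The diattenuator is built from the first row of ``M``; the depolarizer
    block is the principal square root of ``m' m'^T`` (``m'`` the 3x3 block
    of ``M' = M M_D^{-1}``) with overall sign matched to ``sign(det m')``;
    the retarder is ``M_delta^{-1} M'``, projected onto the nearest rotation
    only when the depolarizer block is singular (flagged as degenerate).

    Near-unit diattenuation (``D >= 1 - degeneracy_tol``) takes a
    pseudo-inverse fallback path, also flagged.
    """
    Mb, lead = _as_batch(M)
    if not np.all(np.isfinite(Mb)):
        raise ValueError("non-finite Mueller matrix")
    n = Mb.shape[0]

    Dvec = Mb[:, 0, 1:]  # diattenuation vector (m12, m13, m14)
    D = np.linalg.norm(Dvec, axis=1)
    degenerate = D >= 1.0 - degeneracy_tol
    Dsafe = np.where(degenerate, 0.0, D)

    # M_D = [[1, D^T], [D, sqrt(1-D^2) I + (1 - sqrt(1-D^2)) Dhat Dhat^T]]
    s = np.sqrt(np.clip(1.0 - Dsafe**2, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        Dhat = np.where(D[:, None] > 0, Dvec / np.where(D[:, None] > 0, D[:, None], 1.0), 0.0)
    MD = np.zeros((n, 4, 4))
    MD[:, 0, 0] = 1.0
    MD[:, 0, 1:] = Dvec
    MD[:, 1:, 0] = Dvec
    MD[:, 1:, 1:] = s[:, None, None] * np.eye(3) + (1 - s)[:, None, None] * (
        Dhat[:, :, None] * Dhat[:, None, :]
    )
    MD_inv = np.empty_like(MD)
    ok = ~degenerate
    if np.any(ok):
        MD_inv[ok] = np.linalg.inv(MD[ok])
    if np.any(degenerate):
        full = MD.copy()
        full[degenerate, 1:, 1:] += degeneracy_tol * np.eye(3)
        MD_inv[degenerate] = np.linalg.pinv(full[degenerate])

    Mp = Mb @ MD_inv
    mp = Mp[:, 1:, 1:]

    # Depolarizer block: principal square root of mp mp^T, sign tied to det(mp).
    G = mp @ np.transpose(mp, (0, 2, 1))
    w, V = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    m_delta = np.einsum("nik,nk,njk->nij", V, np.sqrt(w), V)
    det_mp = np.linalg.det(mp)
    m_delta = np.where((det_mp < 0)[:, None, None], -m_delta, m_delta)

    M_delta = np.zeros((n, 4, 4))
    M_delta[:, 0, 0] = 1.0
    M_delta[:, 1:, 0] = Mp[:, 1:, 0]
    M_delta[:, 1:, 1:] = m_delta

    # Retarder: m_R = m_delta^{-1} m'; pinv when the depolarizer is singular.
    singular = np.abs(np.linalg.det(m_delta)) < 1e-12
    m_R = np.empty_like(mp)
    if np.any(~singular):
        m_R[~singular] = np.linalg.solve(m_delta[~singular], mp[~singular])
    if np.any(singular):
        m_R[singular] = np.linalg.pinv(m_delta[singular]) @ mp[singular]
        # Project onto the nearest rotation so M_R stays a pure retarder.
        U, _, Vt = np.linalg.svd(m_R[singular])
        proj = U @ Vt
        neg = np.linalg.det(proj) < 0
        if np.any(neg):
            U[neg, :, -1] *= -1
            proj = U @ Vt
        m_R[singular] = proj
        degenerate = degenerate | singular

    M_R = np.zeros((n, 4, 4))
    M_R[:, 0, 0] = 1.0
    M_R[:, 1:, 1:] = m_R

    recomposed = M_delta @ M_R @ MD
    residual = np.max(np.abs(recomposed - Mb), axis=(1, 2))

    rs = lead + (4, 4)
    return PolarDecomposition(
        M_delta=M_delta.reshape(rs),
        M_R=M_R.reshape(rs),
        M_D=MD.reshape(rs),
        residual=residual.reshape(lead),
        degenerate=degenerate.reshape(lead),
    )


def depolarization_power(dec: PolarDecomposition) -> np.ndarray:
    """``Delta = 1 - |tr(M_delta) - 1| / 3``, clipped to [0, 1]."""
    tr = np.trace(dec.M_delta, axis1=-2, axis2=-1)
    return np.clip(1.0 - np.abs(tr - 1.0) / 3.0, 0.0, 1.0)


def retardance(dec: PolarDecomposition) -> np.ndarray:
    """Total retardance ``R = arccos(tr(M_R)/2 - 1)`` in [0, pi]."""
    tr = np.trace(dec.M_R, axis1=-2, axis2=-1)
    return np.arccos(np.clip(tr / 2.0 - 1.0, -1.0, 1.0))


def diattenuation(M: np.ndarray) -> np.ndarray:
    """``D = sqrt(m12^2 + m13^2 + m14^2)`` of a normalized matrix, clipped to [0, 1]."""
    M = np.asarray(M, dtype=float)
    return np.clip(np.linalg.norm(M[..., 0, 1:], axis=-1), 0.0, 1.0)


def linear_circular_retardance(
    dec: PolarDecomposition, paper_literal: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Split total retardance into linear ``delta`` and circular ``psi`` parts.

    Default convention (validated on forward-constructed pure retarders and
    rotators)::

        delta = arccos( sqrt[(r22 + r33)^2 + (r32 - r23)^2] - 1 )
        psi   = 1/2 atan2(r32 - r23, r22 + r33)

    with ``rij`` the 1-based elements of the retarder factor.  With
    ``paper_literal=True`` the printed sign variant is used instead
    (``r32 + r23`` inside delta's root; ``r22 - r33`` in psi's denominator).
    """
    MR = dec.M_R
    r22, r33 = MR[..., 1, 1], MR[..., 2, 2]
    r23, r32 = MR[..., 1, 2], MR[..., 2, 1]
    if paper_literal:
        root = np.sqrt((r22 + r33) ** 2 + (r32 + r23) ** 2)
        psi = 0.5 * np.arctan2(r32 - r23, r22 - r33)
    else:
        root = np.sqrt((r22 + r33) ** 2 + (r32 - r23) ** 2)
        psi = 0.5 * np.arctan2(r32 - r23, r22 + r33)
    delta = np.arccos(np.clip(root - 1.0, -1.0, 1.0))
    return delta, psi


def mmt_params(M: np.ndarray) -> dict[str, np.ndarray]:
    """Matrix-transformation parameters ``t1``, ``b``, ``beta``, ``A``.

    ``t1 = sqrt[(m22 - m33)^2 + (m23 + m32)^2] / 2`` (anisotropy degree),
    ``b = (m22 + m33)/2`` (depolarization), ``beta = |m23 - m32| / 2``
    (optical rotation), ``A = 2 b t1 / (b^2 + t1^2)`` (normalized
    anisotropy, 0 where ``b = t1 = 0``).
    """
    M = np.asarray(M, dtype=float)
    m22, m33 = M[..., 1, 1], M[..., 2, 2]
    m23, m32 = M[..., 1, 2], M[..., 2, 1]
    t1 = 0.5 * np.sqrt((m22 - m33) ** 2 + (m23 + m32) ** 2)
    b = 0.5 * (m22 + m33)
    beta = 0.5 * np.abs(m23 - m32)
    denom = b**2 + t1**2
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(denom > 0, 2.0 * b * t1 / np.where(denom > 0, denom, 1.0), 0.0)
    return {"t1": t1, "b": b, "beta": beta, "A": A}


def mmri_params(M: np.ndarray) -> dict[str, np.ndarray]:
    """Rotation-invariant corner/edge parameters of a normalized matrix.

    ``PL``/``PC``: linear/circular polarizance (first column);
    ``DL``/``DC``: linear/circular diattenuation (first row);
    ``qL``/``rL``: linear-to-circular and circular-to-linear conversion
    magnitudes (last row/column edges); auxiliary ``kC = m44``.
    """
    M = np.asarray(M, dtype=float)
    return {
        "PL": np.hypot(M[..., 1, 0], M[..., 2, 0]),
        "DL": np.hypot(M[..., 0, 1], M[..., 0, 2]),
        "PC": M[..., 3, 0],
        "DC": M[..., 0, 3],
        "qL": np.hypot(M[..., 3, 1], M[..., 3, 2]),
        "rL": np.hypot(M[..., 1, 3], M[..., 2, 3]),
        "kC": M[..., 3, 3],
    }


def mmli_params(
    M: np.ndarray, mmri: dict[str, np.ndarray] | None = None, paper_literal: bool = False
) -> dict[str, np.ndarray]:
    """Linear-identity parameters ``P1..P8`` and ``Ptms``.

    ``P1..P4`` measure departure from a pure linear retarder (for which
    ``m43 = -m34``, ``m42 = -m24`` and ``qL = rL``); ``P5..P8`` departure
    from a pure linear diattenuator (``m12 = m21``, ``m13 = m31``,
    ``DL = PL``); ``Ptms = sqrt(P1^2 + P2^2)`` is the deviation from
    mirror-transverse symmetry.  ``paper_literal=True`` divides P6 by 3 as
    printed instead of the symmetric default 2.
    """
    M = np.asarray(M, dtype=float)
    if mmri is None:
        mmri = mmri_params(M)
    m12, m13 = M[..., 0, 1], M[..., 0, 2]
    m21, m31 = M[..., 1, 0], M[..., 2, 0]
    m24, m34 = M[..., 1, 3], M[..., 2, 3]
    m42, m43 = M[..., 3, 1], M[..., 3, 2]
    p6_denom = 3.0 if paper_literal else 2.0
    P1 = 0.5 * (m43 + m34)
    P2 = 0.5 * (m42 + m24)
    return {
        "P1": P1,
        "P2": P2,
        "P3": np.abs(mmri["qL"] - mmri["rL"]),
        "P4": 0.5 * (m34 * m24 - m42 * m43),
        "P5": 0.5 * (m12 - m21),
        "P6": (m13 - m31) / p6_denom,
        "P7": np.abs(mmri["DL"] - mmri["PL"]),
        "P8": 0.5 * (m12 * m13 - m21 * m31),
        "Ptms": np.hypot(P1, P2),
    }


def extract_all(
    M_img, mask=None, paper_literal: bool = False
) -> ParameterMaps:
    """Compute all 24 parameter maps (plus auxiliary kC) over the masked pixels.

    Parameters
    ----------
    M_img
        ``MuellerImage`` or raw ``(H, W, 4, 4)`` array; normalized if needed.
    mask
        ``TissueMask`` or boolean array; unmasked pixels are NaN in every map.

    Raises
    ------
    ValueError
        If the mask is empty.  Masked pixels where any parameter is
        non-finite are excluded and counted in ``n_invalid``.
    """
    from .acquisition import MuellerImage, TissueMask  # local: avoid import cycle

    if isinstance(M_img, MuellerImage):
        M_img = M_img.normalize()
        E = M_img.elements
    else:
        E = np.asarray(M_img, dtype=float)
        m11 = E[..., 0:1, 0:1]
        with np.errstate(divide="ignore", invalid="ignore"):
            E = np.where(m11 > 0, E / m11, np.nan)
    h, w = E.shape[:2]
    if mask is None:
        mask_arr = np.ones((h, w), dtype=bool)
    elif isinstance(mask, TissueMask):
        mask_arr = mask.mask
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    if mask_arr.shape != (h, w):
        raise ValueError("mask grid does not match the Mueller image")
    if not mask_arr.any():
        raise ValueError("empty tissue mask: no pixels to extract")

    Mv = E[mask_arr]  # (n_valid, 4, 4)
    finite = np.all(np.isfinite(Mv), axis=(1, 2))
    Mv = Mv[finite]
    if Mv.shape[0] == 0:
        raise ValueError("no finite Mueller matrices inside the mask")

    dec = lu_chipman(Mv)
    delta, psi = linear_circular_retardance(dec, paper_literal=paper_literal)
    mmri = mmri_params(Mv)
    values: dict[str, np.ndarray] = {
        "Delta": depolarization_power(dec),
        "R": retardance(dec),
        "D": diattenuation(Mv),
        "delta": delta,
        "psi": psi,
        **mmt_params(Mv),
        **{k: v for k, v in mmri.items() if k != "kC"},
        **mmli_params(Mv, mmri, paper_literal=paper_literal),
    }

    all_finite = np.all([np.isfinite(v) for v in values.values()], axis=0)
    n_invalid = int(mask_arr.sum() - finite.sum() + (~all_finite).sum())
    if n_invalid:
        warnings.warn(f"{n_invalid} masked pixels had non-finite parameters; excluded")

    def to_map(vals: np.ndarray) -> np.ndarray:
        out = np.full((h, w), np.nan)
        flat = np.full(finite.shape[0], np.nan)
        flat[np.flatnonzero(finite)[all_finite]] = vals[all_finite]
        out[mask_arr] = flat
        return out

    maps = {name: to_map(values[name]) for name in PARAMETER_NAMES}
    kC_map = to_map(mmri["kC"])
    final_mask = mask_arr & np.isfinite(maps["Delta"])
    return ParameterMaps(maps=maps, mask=final_mask, n_invalid=n_invalid, kC=kC_map)
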