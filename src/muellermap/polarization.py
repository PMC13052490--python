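"""Stokes vectors and canonical polarization states.

A Stokes vector ``S = (I, Q, U, V)`` describes a light beam: ``I`` is total
intensity, ``Q = H - V`` and ``U = P - B`` the linear-polarization intensity
differences (horizontal/vertical and +-45 degrees), and ``V = R - L`` the
circular difference.  The six canonical states used by the polarization state
generator (PSG) and analyzer (PSA) are H, V, P, B, R and L, each a fully
polarized unit-intensity beam.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "POL_STATE_LABELS",
    "state_to_stokes",
    "degree_of_polarization",
    "is_physical_stokes",
]

#: Canonical PSG/PSA states: label -> unit-intensity Stokes vector.
_STATE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "H": (1.0, 1.0, 0.0, 0.0),
    "V": (1.0, -1.0, 0.0, 0.0),
    "P": (1.0, 0.0, 1.0, 0.0),
    "B": (1.0, 0.0, -1.0, 0.0),
    "R": (1.0, 0.0, 0.0, 1.0),
    "L": (1.0, 0.0, 0.0, -1.0),
}

POL_STATE_LABELS = tuple(_STATE_TABLE)


class InvalidStateError(ValueError):
    """Raised for a polarization-state label outside {H, V, P, B, R, L}."""


def state_to_stokes(label: str) -> np.ndarray:
    """Return the unit-intensity Stokes vector of a canonical state.

    Parameters
    ----------
    label
        One of ``"H"``, ``"V"``, ``"P"``, ``"B"``, ``"R"``, ``"L"``.

    Returns
    -------
    numpy.ndarray
        Shape ``(4,)`` float vector ``(I, Q, U, V)`` with ``I = 1``.
    """
    try:
        return np.array(_STATE_TABLE[label], dtype=float)
    except KeyError:
        raise InvalidStateError(
            f"unknown polarization state {label!r}; expected one of {POL_STATE_LABELS}"
        ) from None


def degree_of_polarization(S: np.ndarray) -> np.ndarray:
    """Degree of polarization ``sqrt(Q^2 + U^2 + V^2) / I`` (elementwise on last axis)."""
    S = np.asarray(S, dtype=float)
    pol = np.sqrt(np.sum(S[..., 1:] ** 2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(S[..., 0] > 0, pol / S[..., 0], np.inf)


def is_physical_stokes(S: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """True where ``I >= 0`` and the polarized part does not exceed ``I`` (within tol)."""
    S = np.asarray(S, dtype=float)
    I = S[..., 0]
    pol = np.sqrt(np.sum(S[..., 1:] ** 2, axis=-1))
    return (I >= -tol) & (pol <= I * (1.0 + tol) + tol)
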