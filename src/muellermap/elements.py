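"""Normalized Mueller matrices of elementary optical elements.

All constructors return 4x4 matrices with ``m11 = 1`` (broadcasting over
array-valued parameters, so a map of retardances yields a ``(..., 4, 4)``
stack).  Conventions:

* ``linear_retarder(delta, theta)`` — linear retardance ``delta`` (rad),
  fast axis at ``theta`` (rad, axial, pi-periodic).  At ``theta = 0``::

      [[1, 0,        0,         0        ],
       [0, 1,        0,         0        ],
       [0, 0,  cos(delta),  sin(delta)  ],
       [0, 0, -sin(delta),  cos(delta)  ]]

* ``rotator(psi)`` — optical rotation (circular retardance) by ``psi`` (rad);
  ``m22 = m33 = cos(2 psi)``, ``m23 = sin(2 psi) = -m32`` (handedness fixed
  by this sign choice).

* ``linear_diattenuator(d, theta)`` — diattenuation magnitude
  ``d = (q - r)/(q + r)`` for axis transmittances ``q >= r``, axis at
  ``theta``.  At ``theta = 0``::

      [[1, d, 0, 0],
       [d, 1, 0, 0],
       [0, 0, s, 0],
       [0, 0, 0, s]]        with  s = sqrt(1 - d^2)

* ``diagonal_depolarizer(a, b, c)`` — ``diag(1, a, b, c)``; the diagonal
  entries are the polarization-maintaining fractions for Q, U and V.

``rotate_sample(M, theta)`` applies an in-plane rotation of the sample frame,
``Rot(theta) @ M @ Rot(-theta)``, the transformation under which the
rotation-invariant parameter sets must not change.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "linear_retarder",
    "rotator",
    "linear_diattenuator",
    "diagonal_depolarizer",
    "rotation_mueller",
    "rotate_sample",
    "realizability_check",
]


def _embed(block: np.ndarray) -> np.ndarray:
    """Embed a (..., 3, 3) block into (..., 4, 4) with (1, 0...) first row/col."""
    shape = block.shape[:-2] + (4, 4)
    M = np.zeros(shape, dtype=float)
    M[..., 0, 0] = 1.0
    M[..., 1:, 1:] = block
    return M


def rotation_mueller(theta):
    """Mueller matrix of a frame rotation by ``theta`` (rad) about the beam axis."""
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    block = np.zeros(theta.shape + (3, 3))
    block[..., 0, 0] = c
    block[..., 0, 1] = -s
    block[..., 1, 0] = s
    block[..., 1, 1] = c
    block[..., 2, 2] = 1.0
    return _embed(block)


def rotate_sample(M: np.ndarray, theta: float) -> np.ndarray:
    """Return ``Rot(theta) @ M @ Rot(-theta)``: the same sample rotated in-plane."""
    R = rotation_mueller(theta)
    Rinv = rotation_mueller(-theta)
    return R @ np.asarray(M, dtype=float) @ Rinv


def linear_retarder(delta, theta=0.0) -> np.ndarray:
    """Linear retarder of retardance ``delta`` (rad) with fast axis at ``theta`` (rad)."""
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    delta, theta = np.broadcast_arrays(delta, theta)
    cd, sd = np.cos(delta), np.sin(delta)
    c2, s2 = np.cos(2 * theta), np.sin(2 * theta)
    block = np.empty(delta.shape + (3, 3))
    block[..., 0, 0] = c2**2 + s2**2 * cd
    block[..., 0, 1] = c2 * s2 * (1 - cd)
    block[..., 0, 2] = -s2 * sd
    block[..., 1, 0] = c2 * s2 * (1 - cd)
    block[..., 1, 1] = s2**2 + c2**2 * cd
    block[..., 1, 2] = c2 * sd
    block[..., 2, 0] = s2 * sd
    block[..., 2, 1] = -c2 * sd
    block[..., 2, 2] = cd
    return _embed(block)


def rotator(psi) -> np.ndarray:
    """Optical rotator (circular retarder) rotating the polarization plane by ``psi`` (rad)."""
    psi = np.asarray(psi, dtype=float)
    c, s = np.cos(2 * psi), np.sin(2 * psi)
    block = np.zeros(psi.shape + (3, 3))
    block[..., 0, 0] = c
    block[..., 0, 1] = s
    block[..., 1, 0] = -s
    block[..., 1, 1] = c
    block[..., 2, 2] = 1.0
    return _embed(block)


def linear_diattenuator(d, theta=0.0) -> np.ndarray:
    """Normalized linear diattenuator of magnitude ``d`` in [0, 1), axis at ``theta``."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(d < 0) or np.any(d >= 1):
        raise ValueError("diattenuation magnitude must satisfy 0 <= d < 1")
    d, theta = np.broadcast_arrays(d, theta)
    s = np.sqrt(1 - d**2)
    c2, t2 = np.cos(2 * theta), np.sin(2 * theta)
    M = np.zeros(d.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 0, 1] = d * c2
    M[..., 0, 2] = d * t2
    M[..., 1, 0] = d * c2
    M[..., 2, 0] = d * t2
    M[..., 1, 1] = s + (1 - s) * c2**2
    M[..., 1, 2] = (1 - s) * c2 * t2
    M[..., 2, 1] = (1 - s) * c2 * t2
    M[..., 2, 2] = s + (1 - s) * t2**2
    M[..., 3, 3] = s
    return M


def diagonal_depolarizer(a, b, c) -> np.ndarray:
    """Diagonal depolarizer ``diag(1, a, b, c)`` with each factor in (-1, 1]."""
    a, b, c = np.broadcast_arrays(
        np.asarray(a, dtype=float), np.asarray(b, dtype=float), np.asarray(c, dtype=float)
    )
    for name, v in (("a", a), ("b", b), ("c", c)):
        if np.any(np.abs(v) > 1):
            raise ValueError(f"depolarizer factor {name} must lie in [-1, 1]")
    M = np.zeros(a.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = a
    M[..., 2, 2] = b
    M[..., 3, 3] = c
    return M


# Probe states for the realizability check: the 6 canonical fully polarized
# states, unpolarized light, and a deterministic grid on the Poincare sphere.
def _probe_states(n_grid: int = 12) -> np.ndarray:
    probes = [
        (1, 0, 0, 0),
        (1, 1, 0, 0),
        (1, -1, 0, 0),
        (1, 0, 1, 0),
        (1, 0, -1, 0),
        (1, 0, 0, 1),
        (1, 0, 0, -1),
    ]
    golden = np.pi * (3 - np.sqrt(5))
    for k in range(n_grid):
        z = 1 - 2 * (k + 0.5) / n_grid
        r = np.sqrt(1 - z * z)
        phi = golden * k
        probes.append((1, r * np.cos(phi), r * np.sin(phi), z))
    return np.array(probes, dtype=float)


_PROBES = _probe_states()


def realizability_check(M: np.ndarray, tol: float = 1e-9) -> tuple[bool, dict]:
    """Check that ``M`` maps physical light to physical light on a probe grid.

    Passes iff ``m11 > 0``, all ``|mij| <= m11 (1 + tol)``, and every probe
    Stokes state (canonical states, unpolarized, and a Poincare-sphere grid)
    is mapped to a beam with non-negative intensity and degree of
    polarization at most ``1 + tol``.

    Returns
    -------
    (ok, diagnostics)
        ``diagnostics`` names the first failed check and the offending probe.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        return False, {"failure": "non-finite elements"}
    m11 = M[0, 0]
    if m11 <= 0:
        return False, {"failure": "m11 <= 0", "m11": float(m11)}
    if np.any(np.abs(M) > m11 * (1 + tol)):
        i, j = np.unravel_index(np.argmax(np.abs(M)), M.shape)
        return False, {
            "failure": "element bound |mij| <= m11",
            "element": (int(i) + 1, int(j) + 1),
            "value": float(M[i, j] / m11),
        }
    S_out = _PROBES @ M.T
    I = S_out[:, 0]
    if np.any(I < -tol * m11):
        k = int(np.argmin(I))
        return False, {"failure": "negative output intensity", "probe": _PROBES[k].tolist()}
    pol = np.sqrt(np.sum(S_out[:, 1:] ** 2, axis=1))
    bad = pol > I * (1 + tol) + tol * m11
    if np.any(bad):
        k = int(np.argmax(pol - I))
        return False, {
            "failure": "output degree of polarization > 1",
            "probe": _PROBES[k].tolist(),
            "dop": float(pol[k] / I[k]) if I[k] > 0 else np.inf,
        }
    return True, {"failure": None}
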