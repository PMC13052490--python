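"""Polar decomposition and the four parameter frameworks.

Every formula is cross-checked against a literal scalar re-implementation
(`_oracle_*` below) that works element-by-element with scipy's matrix square
root — a fully independent code path from the vectorized implementation.
"""

import numpy as np
import pytest
import scipy.linalg

import muellermap as mm
from muellermap.decompose import (
    PARAMETER_NAMES,
    PARAMETER_RANGES,
    depolarization_power,
    diattenuation,
    extract_all,
    linear_circular_retardance,
    lu_chipman,
    mmli_params,
    mmri_params,
    mmt_params,
    retardance,
)
from muellermap.synth import PhantomSpec, make_sample

# ---------------------------------------------------------------------------
# Independent literal oracle (scalar, scipy-based)


def _oracle_lu_chipman(M):
    M = np.asarray(M, dtype=float)
    Dv = M[0, 1:]
    D = np.linalg.norm(Dv)
    s = np.sqrt(1 - D**2)
    mD = s * np.eye(3)
    if D > 0:
        mD += (1 - s) * np.outer(Dv / D, Dv / D)
    MD = np.block([[np.ones((1, 1)), Dv[None, :]], [Dv[:, None], mD]])
    Mp = M @ np.linalg.inv(MD)
    mp = Mp[1:, 1:]
    mdelta = scipy.linalg.sqrtm(mp @ mp.T).real
    if np.linalg.det(mp) < 0:
        mdelta = -mdelta
    Mdelta = np.eye(4)
    Mdelta[1:, 0] = Mp[1:, 0]
    Mdelta[1:, 1:] = mdelta
    MR = np.eye(4)
    MR[1:, 1:] = np.linalg.solve(mdelta, mp)
    return Mdelta, MR, MD


def _oracle_params(M):
    """All 24 parameters by direct element arithmetic (1-based indices in names)."""
    Mdelta, MR, _ = _oracle_lu_chipman(M)
    m = lambda i, j: M[i - 1, j - 1]
    r = lambda i, j: MR[i - 1, j - 1]
    out = {}
    out["Delta"] = 1 - abs(np.trace(Mdelta) - 1) / 3
    out["R"] = np.arccos(np.clip(np.trace(MR) / 2 - 1, -1, 1))
    out["D"] = np.sqrt(m(1, 2) ** 2 + m(1, 3) ** 2 + m(1, 4) ** 2)
    out["delta"] = np.arccos(
        np.clip(np.sqrt((r(2, 2) + r(3, 3)) ** 2 + (r(3, 2) - r(2, 3)) ** 2) - 1, -1, 1)
    )
    out["psi"] = 0.5 * np.arctan2(r(3, 2) - r(2, 3), r(2, 2) + r(3, 3))
    out["t1"] = np.sqrt((m(2, 2) - m(3, 3)) ** 2 + (m(2, 3) + m(3, 2)) ** 2) / 2
    out["b"] = (m(2, 2) + m(3, 3)) / 2
    out["beta"] = abs(m(2, 3) - m(3, 2)) / 2
    out["A"] = (
        2 * out["b"] * out["t1"] / (out["b"] ** 2 + out["t1"] ** 2)
        if out["b"] ** 2 + out["t1"] ** 2 > 0
        else 0.0
    )
    out["PL"] = np.sqrt(m(2, 1) ** 2 + m(3, 1) ** 2)
    out["DL"] = np.sqrt(m(1, 2) ** 2 + m(1, 3) ** 2)
    out["PC"] = m(4, 1)
    out["DC"] = m(1, 4)
    out["qL"] = np.sqrt(m(4, 2) ** 2 + m(4, 3) ** 2)
    out["rL"] = np.sqrt(m(2, 4) ** 2 + m(3, 4) ** 2)
    out["P1"] = (m(4, 3) + m(3, 4)) / 2
    out["P2"] = (m(4, 2) + m(2, 4)) / 2
    out["P3"] = abs(out["qL"] - out["rL"])
    out["P4"] = (m(3, 4) * m(2, 4) - m(4, 2) * m(4, 3)) / 2
    out["P5"] = (m(1, 2) - m(2, 1)) / 2
    out["P6"] = (m(1, 3) - m(3, 1)) / 2
    out["P7"] = abs(out["DL"] - out["PL"])
    out["P8"] = (m(1, 2) * m(1, 3) - m(2, 1) * m(3, 1)) / 2
    out["Ptms"] = np.sqrt(out["P1"] ** 2 + out["P2"] ** 2)
    return out


def _all_params(M):
    dec = lu_chipman(M)
    delta, psi = linear_circular_retardance(dec)
    mmri = mmri_params(M)
    return {
        "Delta": depolarization_power(dec),
        "R": retardance(dec),
        "D": diattenuation(M),
        "delta": delta,
        "psi": psi,
        **mmt_params(M),
        **{k: v for k, v in mmri.items() if k != "kC"},
        **mmli_params(M, mmri),
    }


# ---------------------------------------------------------------------------
# Lu-Chipman decomposition


def test_identity_decomposes_to_identities():
    dec = lu_chipman(np.eye(4))
    for F in (dec.M_delta, dec.M_R, dec.M_D):
        np.testing.assert_allclose(F, np.eye(4), atol=1e-12)


def test_construct_then_decompose_recovers_factors():
    Mdep = np.diag([1.0, 0.8, 0.8, 0.7])
    MR = mm.linear_retarder(1.0, np.deg2rad(30))
    MD = mm.linear_diattenuator(0.2, np.deg2rad(30))
    dec = lu_chipman(Mdep @ MR @ MD)
    np.testing.assert_allclose(dec.M_delta, Mdep, atol=1e-8)
    np.testing.assert_allclose(dec.M_R, MR, atol=1e-8)
    np.testing.assert_allclose(dec.M_D, MD, atol=1e-8)


def test_pure_retarder_decomposes_trivially():
    M = mm.linear_retarder(np.pi / 2, 0.0)
    dec = lu_chipman(M)
    np.testing.assert_allclose(dec.M_D, np.eye(4), atol=1e-12)
    np.testing.assert_allclose(dec.M_delta, np.eye(4), atol=1e-12)
    np.testing.assert_allclose(dec.M_R, M, atol=1e-12)


def test_retarder_factor_is_rotation(rng, realizable_batch):
    M = realizable_batch(200, rng)
    dec = lu_chipman(M)
    blocks = dec.M_R[:, 1:, 1:]
    gram = blocks @ np.transpose(blocks, (0, 2, 1))
    np.testing.assert_allclose(gram, np.broadcast_to(np.eye(3), gram.shape), atol=1e-8)
    np.testing.assert_allclose(dec.M_R[:, 0, :], [[1, 0, 0, 0]] * 200, atol=1e-12)


def test_factorization_residual_small(rng, realizable_batch):
    M = realizable_batch(500, rng, tissue_like=False)
    dec = lu_chipman(M)
    assert dec.residual.max() < 1e-8


def test_degenerate_diattenuator_flagged():
    M = np.zeros((4, 4))  # ideal horizontal polarizer, normalized
    M[0, 0] = M[0, 1] = M[1, 0] = M[1, 1] = 1.0
    M *= 0.5
    M = M / M[0, 0]
    dec = lu_chipman(M)
    assert dec.degenerate.all()


def test_nonfinite_input_rejected():
    M = np.eye(4)
    M[2, 2] = np.nan
    with pytest.raises(ValueError):
        lu_chipman(M)


# ---------------------------------------------------------------------------
# Scalar parameter formulas


def test_depolarization_power_examples():
    dec = lu_chipman(np.eye(4))
    assert depolarization_power(dec) == pytest.approx(0.0)
    dec_ideal = lu_chipman(np.diag([1.0, 0, 0, 0]))
    assert depolarization_power(dec_ideal) == pytest.approx(1.0)
    dec_d = lu_chipman(np.diag([1.0, 0.8, 0.8, 0.7]))
    assert depolarization_power(dec_d) == pytest.approx(1 - (0.8 + 0.8 + 0.7) / 3)


@pytest.mark.parametrize(
    "delta0, expected",
    [(0.0, 0.0), (np.pi / 2, np.pi / 2), (np.pi, np.pi)],
)
def test_retardance_of_pure_retarders(delta0, expected):
    dec = lu_chipman(mm.linear_retarder(delta0, 0.7))
    assert retardance(dec) == pytest.approx(expected)


def test_diattenuation_examples():
    assert diattenuation(np.eye(4)) == pytest.approx(0.0)
    pol = np.zeros((4, 4))
    pol[0, 0] = pol[0, 1] = pol[1, 0] = pol[1, 1] = 1.0
    assert diattenuation(pol) == pytest.approx(1.0)
    assert diattenuation(mm.linear_diattenuator(1 / 3, 0.2)) == pytest.approx(1 / 3)


def test_linear_circular_split():
    dec_id = lu_chipman(np.eye(4))
    d, p = linear_circular_retardance(dec_id)
    assert (d, p) == (pytest.approx(0.0), pytest.approx(0.0))
    dec_lin = lu_chipman(mm.linear_retarder(1.2, 0.5))
    d, p = linear_circular_retardance(dec_lin)
    assert d == pytest.approx(1.2)
    assert p == pytest.approx(0.0, abs=1e-12)
    dec_rot = lu_chipman(mm.rotator(0.2))
    d, p = linear_circular_retardance(dec_rot)
    assert d == pytest.approx(0.0, abs=1e-12)
    assert abs(p) == pytest.approx(0.2)


def test_paper_literal_split_differs_on_rotator():
    dec_rot = lu_chipman(mm.rotator(0.2))
    d_default, _ = linear_circular_retardance(dec_rot)
    d_literal, _ = linear_circular_retardance(dec_rot, paper_literal=True)
    assert d_default == pytest.approx(0.0, abs=1e-12)
    assert d_literal != pytest.approx(0.0, abs=1e-6)


def test_total_retardance_equals_linear_when_no_rotation(rng):
    """For psi = 0 constructions the total retardance is purely linear."""
    for delta0 in rng.uniform(0.05, 3.0, 20):
        theta = rng.uniform(0, np.pi)
        dec = lu_chipman(mm.linear_retarder(delta0, theta))
        d, p = linear_circular_retardance(dec)
        assert retardance(dec) == pytest.approx(d, abs=1e-8)
        assert p == pytest.approx(0.0, abs=1e-8)


def test_mmt_examples():
    p = mmt_params(np.eye(4))
    assert (p["t1"], p["b"], p["beta"], p["A"]) == (0.0, 1.0, 0.0, 0.0)
    p = mmt_params(mm.rotator(0.3))
    assert p["beta"] == pytest.approx(abs(np.sin(0.6)))
    p = mmt_params(mm.linear_retarder(np.pi / 2, 0.0))
    assert p["t1"] == pytest.approx(0.5)
    assert p["b"] == pytest.approx(0.5)
    assert p["A"] == pytest.approx(1.0)


def test_mmri_examples():
    p = mmri_params(np.eye(4))
    assert p["kC"] == 1.0
    for k in ("PL", "DL", "PC", "DC", "qL", "rL"):
        assert p[k] == 0.0
    p = mmri_params(mm.linear_retarder(1.1, 0.77))
    assert p["qL"] == pytest.approx(abs(np.sin(1.1)))
    assert p["rL"] == pytest.approx(abs(np.sin(1.1)))
    assert p["PL"] == pytest.approx(0.0)
    pol = np.zeros((4, 4))
    pol[0, 0] = pol[0, 1] = pol[1, 0] = pol[1, 1] = 1.0
    p = mmri_params(pol)
    assert p["PL"] == p["DL"] == 1.0
    assert p["kC"] == 0.0


def test_mmli_examples(rng):
    p = mmli_params(np.eye(4))
    assert all(v == 0.0 for v in p.values())
    # pure linear retarder: m43 = -m34, m42 = -m24, qL = rL
    p = mmli_params(mm.linear_retarder(rng.uniform(0.1, 3), rng.uniform(0, np.pi)))
    for k in ("P1", "P2", "P3", "Ptms"):
        assert p[k] == pytest.approx(0.0, abs=1e-12)
    # pure diattenuator: transpose-symmetric, so P5..P8 vanish
    p = mmli_params(mm.linear_diattenuator(0.4, rng.uniform(0, np.pi)))
    for k in ("P5", "P6", "P7", "P8"):
        assert p[k] == pytest.approx(0.0, abs=1e-12)


def test_mmli_paper_literal_p6_denominator():
    M = mm.rotate_sample(mm.linear_diattenuator(0.4, 0.3), 0.2) @ mm.rotator(0.1)
    default = mmli_params(M)["P6"]
    literal = mmli_params(M, paper_literal=True)["P6"]
    assert literal == pytest.approx(default * 2 / 3)


# ---------------------------------------------------------------------------
# Oracle equivalence, bounds, rotation invariance, vectorization


def test_every_formula_matches_literal_oracle(rng, realizable_batch):
    M = realizable_batch(100, rng)
    got = _all_params(M)
    for i in range(100):
        expected = _oracle_params(M[i])
        for name in PARAMETER_NAMES:
            assert got[name][i] == pytest.approx(expected[name], abs=1e-9), name


def test_all_parameter_bounds_on_realizable_ensemble(rng, realizable_batch):
    M = realizable_batch(10_000, rng)
    vals = _all_params(M)
    vals["kC"] = mmri_params(M)["kC"]
    for name, v in vals.items():
        lo, hi = PARAMETER_RANGES[name]
        assert v.min() >= lo - 1e-9, name
        assert v.max() <= hi + 1e-9, name


ROTATION_INVARIANT = [
    "Delta", "R", "D", "t1", "b", "beta", "A",
    "PL", "DL", "PC", "DC", "qL", "rL", "P3", "P7", "Ptms",
]


@pytest.mark.parametrize("theta", [0.3, 1.1, -0.7])
def test_rotation_invariance(theta, rng, realizable_batch):
    M = realizable_batch(200, rng)
    v1 = _all_params(M)
    v2 = _all_params(mm.rotate_sample(M, theta))
    for name in ROTATION_INVARIANT:
        np.testing.assert_allclose(v1[name], v2[name], atol=1e-9, err_msg=name)
    k1 = mmri_params(M)["kC"]
    k2 = mmri_params(mm.rotate_sample(M, theta))["kC"]
    np.testing.assert_allclose(k1, k2, atol=1e-12)


def test_vectorized_equals_per_pixel_path(rng, realizable_batch):
    M = realizable_batch(50, rng)
    batched = _all_params(M)
    for i in range(0, 50, 7):
        single = _all_params(M[i])
        for name in PARAMETER_NAMES:
            assert batched[name][i] == pytest.approx(single[name], abs=1e-12), name


# ---------------------------------------------------------------------------
# Whole-image extraction


def test_extract_all_identity_image():
    img = np.broadcast_to(np.eye(4), (5, 5, 4, 4)).copy()
    maps = extract_all(img)
    assert len(maps.names) == 24
    np.testing.assert_allclose(maps["Delta"], 0.0, atol=1e-12)
    np.testing.assert_allclose(maps.kC, 1.0, atol=1e-12)
    np.testing.assert_allclose(maps["b"], 1.0, atol=1e-12)  # (m22 + m33)/2 of identity
    for name in PARAMETER_NAMES:
        if name not in ("Delta", "b"):
            np.testing.assert_allclose(maps[name], 0.0, atol=1e-12, err_msg=name)


def test_extract_all_recovers_phantom_retardance():
    spec = PhantomSpec.generate(24, 24, delta0=0.9, d0=0.1, seed=8)
    truth, stack = make_sample(spec)
    rec = mm.reconstruct_mueller(stack)
    mask = mm.compute_mask(stack.images.sum(axis=0))
    maps = extract_all(rec, mask)
    inside = mask.mask & spec.foreground
    np.testing.assert_allclose(maps["delta"][inside], 0.9, atol=1e-6)
    np.testing.assert_allclose(maps["D"][inside], 0.1, atol=1e-6)


def test_extract_all_empty_mask_rejected():
    img = np.broadcast_to(np.eye(4), (4, 4, 4, 4)).copy()
    with pytest.raises(ValueError):
        extract_all(img, np.zeros((4, 4), dtype=bool))


def test_extract_all_flags_invalid_pixels():
    img = np.broadcast_to(np.eye(4), (4, 4, 4, 4)).copy()
    img[1, 1] = np.nan
    with pytest.warns(UserWarning, match="non-finite"):
        maps = extract_all(img)
    assert maps.n_invalid == 1
    assert np.isnan(maps["Delta"][1, 1])
    assert not maps.mask[1, 1]
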