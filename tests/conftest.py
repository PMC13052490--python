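import numpy as np
import pytest

from muellermap import (
    diagonal_depolarizer,
    linear_diattenuator,
    linear_retarder,
    rotator,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_realizable(n, rng, tissue_like=True):
    """Random products depolarizer @ rotator @ retarder @ diattenuator.

    With ``tissue_like`` the parameters stay in the thin-section regime
    (retardance below a quarter wave, small optical rotation), the regime in
    which the printed parameter range bounds hold; without it, the full
    retardance range [0, pi] is sampled.
    """
    delta = rng.uniform(0, np.pi / 2 if tissue_like else np.pi, n)
    theta = rng.uniform(0, np.pi, n)
    psi = rng.uniform(-0.2, 0.2, n) if tissue_like else rng.uniform(-np.pi / 4, np.pi / 4, n)
    d = rng.uniform(0, 0.9, n)
    d_axis = rng.uniform(0, np.pi, n)
    a = rng.uniform(0.2, 1, n)
    b = rng.uniform(0.2, 1, n)
    c = rng.uniform(0.2, 1, n)
    return (
        diagonal_depolarizer(a, b, c)
        @ rotator(psi)
        @ linear_retarder(delta, theta)
        @ linear_diattenuator(d, d_axis)
    )


@pytest.fixture
def realizable_batch():
    return random_realizable
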