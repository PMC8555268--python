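import numpy as np
import pytest

from pottsdca.fixtures import random_potts, synthetic_msa
from pottsdca.msa_io import PROTEIN, RNA


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protein():
    return PROTEIN


@pytest.fixture
def rna():
    return RNA


@pytest.fixture
def tiny_planted():
    """A small coupled model (L=4, q=3) with every pair active."""
    return random_potts(4, 3, density=1.0, coupling_scale=0.5, seed=7)


@pytest.fixture
def tiny_msa(tiny_planted):
    """2000 exact draws from the tiny planted model."""
    return synthetic_msa(tiny_planted.model, 2000, seed=11)


def transfer_matrix_marginals(model):
    """Independent oracle: exact single-site marginals of a chain-topology
    Potts model via the transfer-matrix method.

    Requires couplings only between consecutive sites.  Returns (logZ, p1).
    """
    L, q = model.L, model.q
    for i in range(L):
        for j in range(i + 2, L):
            assert np.all(model.J[i, j] == 0), "chain topology required"
    # forward messages F[i][a]: sum over s_0..s_{i-1} of exp(energy up to i)
    F = [np.exp(model.h[0])]
    for i in range(1, L):
        T = np.exp(model.J[i - 1, i])  # (q, q): [a_prev, a]
        F.append(np.exp(model.h[i]) * (F[-1] @ T))
    # backward messages B[i][a]
    B = [np.ones(q) for _ in range(L)]
    for i in range(L - 2, -1, -1):
        T = np.exp(model.J[i, i + 1])
        B[i] = T @ (np.exp(model.h[i + 1]) * B[i + 1])
    Z = float(F[-1] @ B[-1])
    p1 = np.array([F[i] * B[i] / Z for i in range(L)])
    return np.log(Z), p1
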