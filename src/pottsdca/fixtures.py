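"""Planted Potts models and synthetic alignments for end-to-end testing.

The generator draws a sparse pairwise model (each site pair carries a full
q x q Gaussian coupling block with probability ``density``) and samples
alignments from it either exactly — by enumerating the q^L state space and
inverting the cumulative distribution, feasible at desk scale and free of
any MCMC circularity — or with a long thinned Markov chain.  Synthetic
alignments carry unit weights: the generator makes i.i.d. draws and does not
imitate the phylogenetic redundancy of real families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .msa_io import MSA, Alphabet
from .mcmc_sampler import run_sweeps
from .potts_core import PottsModel, enumerate_states, exact_marginals

__all__ = ["PlantedModel", "random_potts", "synthetic_msa", "write_planted_json"]

_STATE_SYMBOLS = "-ABCDEFGHIJKLMNOPQRST"  # gap + up to 20 letters


def state_alphabet(q: int) -> Alphabet:
    """A q-letter alphabet (gap first) for synthetic sequences."""
    if not 2 <= q <= len(_STATE_SYMBOLS):
        raise ValueError(f"q must lie in [2, {len(_STATE_SYMBOLS)}]")
    return Alphabet.custom(_STATE_SYMBOLS[:q], name=f"state{q}")


@dataclass
class PlantedModel:
    """A ground-truth model plus the list of pairs carrying real couplings."""

    model: PottsModel
    contact_set: list[tuple[int, int]]


def random_potts(
    L: int,
    q: int,
    density: float,
    coupling_scale: float = 1.0,
    field_scale: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> PlantedModel:
    """Sparse random model: pairs are active i.i.d. with probability
    ``density``; active blocks and all fields are i.i.d. Gaussian."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    model = PottsModel.zeros(L, q)
    model.h = rng.normal(0.0, field_scale, size=(L, q))
    contacts: list[tuple[int, int]] = []
    for i in range(L):
        for j in range(i + 1, L):
            if rng.random() < density:
                block = rng.normal(0.0, coupling_scale, size=(q, q))
                model.set_coupling(i, j, block)
                contacts.append((i, j))
    return PlantedModel(model=model, contact_set=contacts)


def synthetic_msa(
    model: PottsModel,
    M: int,
    seed: int | np.random.Generator = 0,
    method: str = "exact",
    cap: int = 2**20,
    burn_in: int = 1000,
    stride: int = 10,
) -> MSA:
    """Sample M sequences from the model's Boltzmann distribution.

    ``exact`` enumerates the state space (requires q^L <= cap) and draws
    i.i.d. configurations by cumulative-probability inversion; ``mcmc`` runs
    one long Metropolis chain, discarding ``burn_in`` sweeps and keeping
    every ``stride``-th sweep thereafter.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    L, q = model.L, model.q
    if method == "exact":
        summary = exact_marginals(model, cap=cap)
        states = enumerate_states(L, q)
        # recompute the full distribution from the enumeration oracle
        energies = np.zeros(states.shape[0])
        for i in range(L):
            energies += model.h[i, states[:, i]]
        for i in range(L):
            for j in range(i + 1, L):
                energies += model.J[i, j][states[:, i], states[:, j]]
        P = np.exp(energies - summary.logZ)
        cdf = np.cumsum(P)
        cdf[-1] = 1.0
        idx = np.searchsorted(cdf, rng.random(M), side="right")
        data = states[idx]
    elif method == "mcmc":
        config = rng.integers(0, q, size=(1, L), dtype=np.int8)
        run_sweeps(model, config, burn_in, rng)
        data = np.empty((M, L), dtype=np.int8)
        for m in range(M):
            run_sweeps(model, config, stride, rng)
            data[m] = config[0]
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    names = [f"sample{m}" for m in range(M)]
    return MSA(names, data, state_alphabet(q), weights=np.ones(M))


def write_planted_json(planted: PlantedModel, seed: int, path) -> None:
    """Record the planted truth (dimensions, seed, contact list) as JSON."""
    payload = {
        "L": planted.model.L,
        "q": planted.model.q,
        "seed": seed,
        "contacts": [list(p) for p in planted.contact_set],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
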