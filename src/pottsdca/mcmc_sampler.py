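"""Metropolis and Gibbs sampling of the Potts measure with adaptive timing.

Chains evolve by elementary single-site moves; one *sweep* is L elementary
steps.  A sampling epoch runs ``N_s`` chains for ``T_eq`` sweeps, records a
configuration, then records one more every ``T_wait`` sweeps until ``N_c``
samples per chain are collected.  Chains are either *transient*
(re-initialised every epoch; the default) or *persistent* (carried across
epochs, contrastive-divergence style).

Whether T_eq and T_wait are long enough is diagnosed from three overlap
families: Q^ext between different chains at equal sampling time, Q^int1
between consecutive samples of one chain, Q^int2 between samples two steps
apart.  At stationarity with de-correlated samples all three share the same
mean; T_wait is doubled when |mu_ext - mu_int2| exceeds five combined
standard errors, and relaxed towards its pre-doubling value when
|mu_ext - mu_int1| falls below five combined standard errors.  After every
update T_eq = 2 T_wait.

All kernels are vectorised across chains; the Python-level loop is over
elementary steps only.  Metropolis picks sites uniformly at random with
replacement and proposes one of the q-1 other states; Gibbs performs a
systematic site scan, resampling each site from its exact conditional.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .msa_io import MSA
from .potts_core import PottsModel
from .preprocessing import SiteStatistics, frequencies_from_codes

__all__ = [
    "ChainEnsemble",
    "SampleBlock",
    "OverlapStats",
    "MCTimes",
    "metropolis_sweep",
    "gibbs_sweep",
    "run_sweeps",
    "init_chains",
    "sample_epoch",
    "estimate_marginals",
    "overlap",
    "overlap_statistics",
    "update_mc_times",
    "mean_pairwise_overlap",
]


@dataclass
class MCTimes:
    """Equilibration and waiting times in sweeps; t_prev remembers the
    T_wait value before the last doubling (used when relaxing)."""

    t_wait: int
    t_eq: int
    t_prev: int

    def __post_init__(self) -> None:
        if self.t_wait < 1 or self.t_eq < 0 or self.t_prev < 1:
            raise ValueError("MC times must be positive")

    @classmethod
    def initial(cls, t_wait: int = 10, t_eq: int | None = None) -> "MCTimes":
        return cls(t_wait=t_wait, t_eq=2 * t_wait if t_eq is None else t_eq,
                   t_prev=t_wait)


@dataclass
class ChainEnsemble:
    """Current state of N_s Markov chains plus their (re-)initialisation rule."""

    configs: np.ndarray            # (N_s, L) int8
    q: int
    rng: np.random.Generator
    persistent: bool = False
    init_mode: str = "uniform_random"
    msa: MSA | None = None         # needed for msa_weighted re-initialisation
    skip_equilibration: bool = False

    @property
    def n_chains(self) -> int:
        return self.configs.shape[0]

    @property
    def L(self) -> int:
        return self.configs.shape[1]

    def reinitialise(self) -> None:
        self.configs = _draw_initial(
            self.init_mode, self.n_chains, self.L, self.q, self.msa, self.rng
        )


def _draw_initial(mode, n_chains, L, q, msa, rng) -> np.ndarray:
    if mode == "uniform_random":
        return rng.integers(0, q, size=(n_chains, L), dtype=np.int8)
    if mode == "msa_weighted":
        if msa is None:
            raise ValueError("msa_weighted initialisation requires an MSA")
        w = msa.weights if msa.weights is not None else np.ones(msa.n_sequences)
        p = np.asarray(w, dtype=float)
        p = p / p.sum()
        idx = rng.choice(msa.n_sequences, size=n_chains, p=p)
        return msa.data[idx].copy()
    raise ValueError(f"unknown chain initialisation mode {mode!r}")


def init_chains(
    mode: str,
    n_chains: int,
    *,
    L: int | None = None,
    q: int | None = None,
    msa: MSA | None = None,
    rng: np.random.Generator | None = None,
    persistent: bool = False,
    skip_equilibration: bool = False,
) -> ChainEnsemble:
    """Create an ensemble; uniform start needs (L, q), msa_weighted needs an MSA."""
    if rng is None:
        rng = np.random.default_rng()
    if msa is not None:
        L, q = msa.length, msa.alphabet.q
    if L is None or q is None:
        raise ValueError("L and q (or an MSA) are required")
    configs = _draw_initial(mode, n_chains, L, q, msa, rng)
    return ChainEnsemble(
        configs=configs, q=q, rng=rng, persistent=persistent,
        init_mode=mode, msa=msa, skip_equilibration=skip_equilibration,
    )


def _metropolis_sweeps(
    model: PottsModel, configs: np.ndarray, n_sweeps: int, rng: np.random.Generator
) -> None:
    """In-place Metropolis evolution of all chains for ``n_sweeps`` sweeps."""
    N, L = configs.shape
    q = model.q
    h, J = model.h, model.J
    rows = np.arange(N)
    cols = np.arange(L)
    for _ in range(n_sweeps * L):
        sites = rng.integers(0, L, size=N)
        cur = configs[rows, sites].astype(np.int64)
        prop = rng.integers(0, q - 1, size=N)
        prop += prop >= cur  # uniform over the q-1 other states
        d_h = h[sites, prop] - h[sites, cur]
        Jb = J[sites[:, None], cols[None, :], prop[:, None], configs]
        Ja = J[sites[:, None], cols[None, :], cur[:, None], configs]
        d_e = d_h + (Jb - Ja).sum(axis=1)
        accept = np.log(rng.random(N)) < d_e
        configs[rows[accept], sites[accept]] = prop[accept].astype(np.int8)


def _gibbs_sweeps(
    model: PottsModel, configs: np.ndarray, n_sweeps: int, rng: np.random.Generator
) -> None:
    """In-place Gibbs evolution: systematic scan over sites 0..L-1 per sweep."""
    N, L = configs.shape
    cols = np.arange(L)
    for _ in range(n_sweeps):
        for i in range(L):
            logits = _conditional_logits(model, configs, i, cols)
            g = rng.gumbel(size=logits.shape)
            configs[:, i] = np.argmax(logits + g, axis=1).astype(np.int8)


def _conditional_logits(model, configs, site, cols=None):
    if cols is None:
        cols = np.arange(configs.shape[1])
    T = model.J[site].transpose(0, 2, 1)  # (L, q_b, q_a): T[j, b, a] = J[i,j,a,b]
    contrib = T[cols[None, :], configs, :]  # (N, L, q)
    return model.h[site][None, :] + contrib.sum(axis=1)


def conditional_probs(model: PottsModel, config: np.ndarray, site: int) -> np.ndarray:
    """Exact conditional distribution of one site given the rest (one chain)."""
    logits = _conditional_logits(model, np.asarray(config)[None, :], site)[0]
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


_KERNELS = {"metropolis": _metropolis_sweeps, "gibbs": _gibbs_sweeps}


def run_sweeps(
    model: PottsModel,
    configs: np.ndarray,
    n_sweeps: int,
    rng: np.random.Generator,
    sampler: str = "metropolis",
) -> None:
    """Evolve a (N, L) block of chains in place."""
    if sampler not in _KERNELS:
        raise ValueError(f"unknown sampler {sampler!r}")
    if n_sweeps > 0:
        _KERNELS[sampler](model, configs, n_sweeps, rng)


def metropolis_sweep(
    model: PottsModel, config: np.ndarray, rng: np.random.Generator,
    n_sweeps: int = 1,
) -> np.ndarray:
    """Metropolis evolution of a single configuration; returns the new state."""
    block = np.asarray(config, dtype=np.int8).copy()[None, :]
    _metropolis_sweeps(model, block, n_sweeps, rng)
    return block[0]


def gibbs_sweep(
    model: PottsModel, config: np.ndarray, rng: np.random.Generator,
    n_sweeps: int = 1,
) -> np.ndarray:
    """Gibbs evolution of a single configuration; returns the new state."""
    block = np.asarray(config, dtype=np.int8).copy()[None, :]
    _gibbs_sweeps(model, block, n_sweeps, rng)
    return block[0]


@dataclass
class SampleBlock:
    """Samples indexed (chain, time); sample n of chain i was taken after
    T_eq + n T_wait sweeps of that chain within the epoch."""

    samples: np.ndarray  # (N_s, N_c, L)
    q: int
    t_eq_used: int
    t_wait_used: int

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_per_chain(self) -> int:
        return self.samples.shape[1]

    def flat(self) -> np.ndarray:
        return self.samples.reshape(-1, self.samples.shape[2])


def sample_epoch(
    model: PottsModel,
    ensemble: ChainEnsemble,
    times: MCTimes,
    n_per_chain: int,
    sampler: str = "metropolis",
) -> SampleBlock:
    """One sampling epoch: equilibrate, then collect ``n_per_chain`` samples
    per chain spaced by T_wait sweeps.  Transient ensembles are re-initialised
    first; persistent ensembles continue from their previous state (and still
    run T_eq sweeps unless ``skip_equilibration`` is set)."""
    if n_per_chain < 1:
        raise ValueError("need at least one sample per chain")
    if not ensemble.persistent:
        ensemble.reinitialise()
    t_eq = 0 if (ensemble.persistent and ensemble.skip_equilibration) else times.t_eq
    configs = ensemble.configs
    run_sweeps(model, configs, t_eq, ensemble.rng, sampler)
    samples = np.empty((ensemble.n_chains, n_per_chain, ensemble.L), dtype=np.int8)
    samples[:, 0] = configs
    for n in range(1, n_per_chain):
        run_sweeps(model, configs, times.t_wait, ensemble.rng, sampler)
        samples[:, n] = configs
    ensemble.configs = configs
    return SampleBlock(
        samples=samples, q=model.q, t_eq_used=t_eq, t_wait_used=times.t_wait
    )


def estimate_marginals(block: SampleBlock) -> SiteStatistics:
    """Unweighted empirical frequencies over all N_s * N_c samples."""
    f1, f2 = frequencies_from_codes(block.flat(), block.q)
    return SiteStatistics(f1=f1, f2=f2, alpha=0.0, kind="model")


def overlap(s: np.ndarray, t: np.ndarray) -> int:
    """Number of positions at which two sequences agree."""
    s, t = np.asarray(s), np.asarray(t)
    if s.shape != t.shape:
        raise ValueError("sequences must have equal length")
    return int((s == t).sum())


@dataclass
class OverlapStats:
    """Means and standard errors of the three overlap families."""

    mu_ext: float
    mu_int1: float
    mu_int2: float
    se_ext: float
    se_int1: float
    se_int2: float
    reference_overlap: float | None = None


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float).ravel()
    mu = float(values.mean())
    if values.size < 2:
        return mu, 0.0
    return mu, float(values.std(ddof=1) / np.sqrt(values.size))


def overlap_statistics(
    block: SampleBlock,
    rng: np.random.Generator | None = None,
    reference_overlap: float | None = None,
) -> OverlapStats:
    """Overlap diagnostics of one epoch's samples.

    int1 averages O(s_n, s_{n+1}) and int2 O(s_n, s_{n+2}) within chains;
    ext pairs up chains in a random disjoint pairing at each sampling time.
    Requires N_c >= 3 and N_s >= 2.
    """
    S = block.samples
    n_s, n_c, _ = S.shape
    if n_c < 3 or n_s < 2:
        raise ValueError("overlap diagnostics need N_c >= 3 and N_s >= 2")
    if rng is None:
        rng = np.random.default_rng()
    int1 = (S[:, :-1] == S[:, 1:]).sum(axis=2)
    int2 = (S[:, :-2] == S[:, 2:]).sum(axis=2)
    ext = []
    half = n_s // 2
    for n in range(n_c):
        perm = rng.permutation(n_s)
        a, b = perm[:half], perm[half : 2 * half]
        ext.append((S[a, n] == S[b, n]).sum(axis=1))
    mu_ext, se_ext = _mean_se(np.concatenate(ext))
    mu_int1, se_int1 = _mean_se(int1)
    mu_int2, se_int2 = _mean_se(int2)
    return OverlapStats(
        mu_ext=mu_ext, mu_int1=mu_int1, mu_int2=mu_int2,
        se_ext=se_ext, se_int1=se_int1, se_int2=se_int2,
        reference_overlap=reference_overlap,
    )


def update_mc_times(
    stats: OverlapStats, times: MCTimes, max_t_wait: int = 10**5
) -> MCTimes:
    """Adapt T_wait from the overlap diagnostics (increase has priority):

    - not de-correlated (|mu_ext - mu_int2| > 5 combined SE): double T_wait;
    - well de-correlated (|mu_ext - mu_int1| < 5 combined SE): relax T_wait to
      ceil((T_wait + T_prev)/2) where T_prev predates the last doubling;
    - otherwise leave T_wait alone.  Always reset T_eq = 2 T_wait.
    """
    t_wait, t_prev = times.t_wait, times.t_prev
    inc = abs(stats.mu_ext - stats.mu_int2) > 5.0 * np.hypot(stats.se_ext, stats.se_int2)
    dec = abs(stats.mu_ext - stats.mu_int1) < 5.0 * np.hypot(stats.se_ext, stats.se_int1)
    if inc:
        t_prev = t_wait
        t_wait = min(2 * t_wait, max_t_wait)
    elif dec:
        t_wait = max(1, ceil((t_wait + t_prev) / 2))
    return MCTimes(t_wait=t_wait, t_eq=2 * t_wait, t_prev=t_prev)


def mean_pairwise_overlap(
    data: np.ndarray,
    rng: np.random.Generator | None = None,
    max_pairs: int = 2000,
) -> float:
    """Mean overlap over (a random subset of) distinct sequence pairs (q_MSA)."""
    data = np.asarray(data)
    M = data.shape[0]
    if M < 2:
        raise ValueError("need at least two sequences")
    if rng is None:
        rng = np.random.default_rng()
    n_all = M * (M - 1) // 2
    if n_all <= max_pairs:
        iu, ju = np.triu_indices(M, k=1)
    else:
        iu = rng.integers(0, M, size=max_pairs)
        ju = rng.integers(0, M - 1, size=max_pairs)
        ju += ju >= iu
    return float((data[iu] == data[ju]).sum(axis=1).mean())
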