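"""Sequence reweighting, gap filtering and regularised empirical statistics.

Phylogenetic redundancy is corrected by the standard similarity reweighting:
each sequence mu gets weight w^mu = 1/k where k is the number of sequences
(including mu itself) sharing at least a fraction ``identity_threshold`` of
identical residues with it.  M_eff = sum_mu w^mu is the effective sample size.

One- and two-site frequencies are the weighted counts

    f_i(a)    = (1/M_eff) sum_mu w^mu [s_i^mu == a]
    f_ij(a,b) = (1/M_eff) sum_mu w^mu [s_i^mu == a][s_j^mu == b]

optionally mixed with the uniform distribution through a pseudocount alpha:

    f_i    -> (1-alpha) f_i + alpha/q
    f_ij   -> (1-alpha) f_ij + alpha/q^2

which preserves the marginalisation identity sum_b f_ij(a,b) = f_i(a) for
every alpha and guarantees strictly positive frequencies when alpha > 0.
The default alpha used by the trainer is 1/M_eff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import MSA

__all__ = [
    "WeightVector",
    "SiteStatistics",
    "compute_weights",
    "filter_gap_runs",
    "empirical_frequencies",
    "frequencies_from_codes",
    "apply_pseudocount",
    "connected_correlations",
]


@dataclass
class WeightVector:
    """Per-sequence weights w^mu in (0, 1] and their sum M_eff."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or np.any(self.w <= 0) or np.any(self.w > 1):
            raise ValueError("weights must be a vector with entries in (0, 1]")

    @property
    def m_eff(self) -> float:
        return float(self.w.sum())


@dataclass
class SiteStatistics:
    """One- and two-site frequencies (or model marginals).

    ``f1`` is L x q; ``f2`` is the full L x L x q x q tensor with
    f2[i, j, a, b] the joint frequency of (s_i=a, s_j=b) for i != j and
    f2[i, i, a, b] = delta_ab * f1[i, a] on the diagonal.  ``kind`` records
    provenance: raw data counts, pseudocounted counts, or MCMC model
    marginals.
    """

    f1: np.ndarray
    f2: np.ndarray
    alpha: float = 0.0
    kind: str = "empirical"

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]


def compute_weights(
    msa: MSA,
    identity_threshold: float = 0.8,
    match_gaps: bool = True,
    chunk_size: int = 512,
) -> WeightVector:
    """Similarity-based reweighting (inclusive threshold).

    ``match_gaps=True`` counts shared gap positions as identities (the common
    DCA convention); set it to False to require matching residues only.
    The pairwise scan is O(M^2 L), chunked to bound memory.
    """
    data = msa.data
    M, L = data.shape
    if match_gaps:
        q = msa.alphabet.q
        X = np.zeros((M, L * q), dtype=np.float32)
        flat = data.astype(np.int64) + q * np.arange(L)
        np.put_along_axis(X, flat, 1.0, axis=1)
        needed = identity_threshold * L
        counts = np.zeros(M, dtype=np.int64)
        for start in range(0, M, chunk_size):
            block = X[start : start + chunk_size] @ X.T  # pairwise overlap counts
            counts[start : start + chunk_size] = (block >= needed - 1e-9).sum(axis=1)
    else:
        needed = identity_threshold * L
        counts = np.zeros(M, dtype=np.int64)
        gap_free = data != 0
        for start in range(0, M, chunk_size):
            A = data[start : start + chunk_size]
            # matches at non-gap positions of both sequences
            eq = (A[:, None, :] == data[None, :, :]) & gap_free[start : start + chunk_size][:, None, :] & gap_free[None, :, :]
            similar = eq.sum(axis=2) >= needed - 1e-9
            # a sequence always counts itself, even when its non-gap
            # self-overlap falls below the threshold
            for r in range(similar.shape[0]):
                similar[r, start + r] = True
            counts[start : start + chunk_size] = similar.sum(axis=1)
    return WeightVector(1.0 / counts)


def filter_gap_runs(msa: MSA, max_run: int = 6) -> MSA:
    """Drop sequences containing a run of more than ``max_run`` consecutive gaps."""
    gaps = msa.data == 0
    run = np.zeros(msa.n_sequences, dtype=np.int64)
    worst = np.zeros(msa.n_sequences, dtype=np.int64)
    for col in range(msa.length):
        run = np.where(gaps[:, col], run + 1, 0)
        worst = np.maximum(worst, run)
    keep = worst <= max_run
    if not keep.any():
        raise ValueError("gap-run filter removed every sequence")
    return MSA(
        [n for n, k in zip(msa.names, keep) if k],
        msa.data[keep],
        msa.alphabet,
        None if msa.weights is None else msa.weights[keep],
    )


def frequencies_from_codes(
    data: np.ndarray, q: int, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted one- and two-site frequencies of an M x L code matrix."""
    data = np.asarray(data)
    M, L = data.shape
    if weights is None:
        weights = np.ones(M)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (M,):
        raise ValueError("weights must have one entry per sequence")
    norm = weights.sum()
    X = np.zeros((M, L, q))
    np.put_along_axis(X, data[:, :, None].astype(np.int64), 1.0, axis=2)
    Xf = X.reshape(M, L * q)
    f1 = (weights @ Xf).reshape(L, q) / norm
    f2 = (Xf.T * weights) @ Xf / norm
    f2 = f2.reshape(L, q, L, q).transpose(0, 2, 1, 3)
    _set_diagonal_blocks(f2, f1)
    return f1, f2


def _set_diagonal_blocks(f2: np.ndarray, f1: np.ndarray) -> None:
    L, q = f1.shape
    for i in range(L):
        f2[i, i] = np.diag(f1[i])


def empirical_frequencies(msa: MSA, weights: WeightVector | None = None) -> SiteStatistics:
    if weights is None:
        w = msa.weights if msa.weights is not None else np.ones(msa.n_sequences)
    else:
        w = weights.w
    f1, f2 = frequencies_from_codes(msa.data, msa.alphabet.q, w)
    return SiteStatistics(f1=f1, f2=f2, alpha=0.0, kind="empirical")


def apply_pseudocount(stats: SiteStatistics, alpha: float) -> SiteStatistics:
    """Mix frequencies with the uniform distribution; exact marginalisation kept."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("pseudocount alpha must lie in [0, 1]")
    q = stats.q
    f1 = (1 - alpha) * stats.f1 + alpha / q
    f2 = (1 - alpha) * stats.f2 + alpha / q**2
    _set_diagonal_blocks(f2, f1)
    return SiteStatistics(f1=f1, f2=f2, alpha=alpha, kind="pseudocounted")


def connected_correlations(stats: SiteStatistics) -> np.ndarray:
    """c_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b), full L x L x q x q tensor."""
    outer = stats.f1[:, None, :, None] * stats.f1[None, :, None, :]
    return stats.f2 - outer
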