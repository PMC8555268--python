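"""Potts model representation, exact oracle, gauge fixing and contact scores.

The model assigns every aligned sequence s = (s_1..s_L), s_i in [0, q), the
Boltzmann probability

    P(s) = exp( sum_i h_i(s_i) + sum_{i<j} J_ij(s_i, s_j) ) / Z .

Couplings are kept as a full L x L x q x q tensor with the symmetry
J[j, i, b, a] = J[i, j, a, b] and zero diagonal blocks, which makes the
single-site energy differences needed by the samplers a plain gather.  A
boolean ``mask`` of the same shape marks active entries; inactive entries are
pinned to exactly zero (used by topology files and decimation).

The parametrisation is redundant: any gauge transformation

    J_ij(a, b) -> J_ij(a, b) + K[i,j](a) + K[j,i](b)
    h_i(a)     -> h_i(a) + g_i - sum_{j != i} K[i,j](a)

leaves P(s) unchanged.  The zero-sum gauge (all row and column sums of every
coupling block vanish) is the member of the orbit with minimal Frobenius
norms and is applied before computing contact scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import SiteStatistics, connected_correlations

__all__ = [
    "PottsModel",
    "GaugeTransform",
    "ExactSummary",
    "ContactScores",
    "log_score",
    "exact_marginals",
    "enumerate_states",
    "profile_init",
    "zero_sum_gauge",
    "weakest_correlation_mask",
    "frobenius_apc_scores",
    "write_scores",
]


def _default_mask(L: int, q: int) -> np.ndarray:
    mask = np.ones((L, L, q, q), dtype=bool)
    mask[np.arange(L), np.arange(L)] = False
    return mask


@dataclass
class PottsModel:
    """Fields ``h`` (L x q) and couplings ``J`` (L x L x q x q, symmetric)."""

    h: np.ndarray
    J: np.ndarray
    mask: np.ndarray | None = None
    gauge_tag: str = "none"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must have shape (L, L, q, q)")
        if self.mask is None:
            self.mask = _default_mask(L, q)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.J.shape:
            raise ValueError("mask must have the same shape as J")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def n_active(self) -> int:
        """Active coupling entries, counted once per unordered pair."""
        iu = np.triu_indices(self.L, k=1)
        return int(self.mask[iu].sum())

    @property
    def n_parameters(self) -> int:
        """N_p for the fully active model: L(L-1)/2 q^2 + L q."""
        L, q = self.L, self.q
        return L * (L - 1) // 2 * q**2 + L * q

    @classmethod
    def zeros(cls, L: int, q: int) -> "PottsModel":
        return cls(h=np.zeros((L, q)), J=np.zeros((L, L, q, q)))

    def set_coupling(self, i: int, j: int, block: np.ndarray) -> None:
        """Set J_ij (and its transpose image) for one pair i != j."""
        if i == j:
            raise ValueError("no self couplings")
        block = np.asarray(block, dtype=float)
        self.J[i, j] = block
        self.J[j, i] = block.T

    def copy(self) -> "PottsModel":
        return PottsModel(
            h=self.h.copy(), J=self.J.copy(), mask=self.mask.copy(),
            gauge_tag=self.gauge_tag,
        )

    def validate(self, atol: float = 1e-10) -> None:
        if not np.isfinite(self.h).all() or not np.isfinite(self.J).all():
            raise ValueError("parameters must be finite")
        if not np.allclose(self.J, self.J.transpose(1, 0, 3, 2), atol=atol):
            raise ValueError("J must satisfy J[i,j,a,b] == J[j,i,b,a]")
        if np.any(self.J[~self.mask] != 0.0):
            raise ValueError("inactive coupling entries must be exactly zero")


def log_score(model: PottsModel, seq: np.ndarray) -> float:
    """log of the unnormalised probability of one sequence."""
    seq = np.asarray(seq)
    L = model.L
    if seq.shape != (L,):
        raise ValueError(f"sequence length {seq.shape} does not match L={L}")
    if seq.min() < 0 or seq.max() >= model.q:
        raise ValueError("sequence codes out of range")
    e = model.h[np.arange(L), seq].sum()
    iu, ju = np.triu_indices(L, k=1)
    e += model.J[iu, ju, seq[iu], seq[ju]].sum()
    return float(e)


def enumerate_states(L: int, q: int) -> np.ndarray:
    """All q^L configurations, one per row, in lexicographic order."""
    n = q**L
    idx = np.unravel_index(np.arange(n), (q,) * L)
    return np.stack(idx, axis=1).astype(np.int8)


@dataclass
class ExactSummary:
    """Exact log-partition function and marginals from full enumeration."""

    logZ: float
    p1: np.ndarray
    p2: np.ndarray


def exact_marginals(model: PottsModel, cap: int = 2**20) -> ExactSummary:
    """Brute-force enumeration oracle; only feasible for q^L <= ``cap``."""
    L, q = model.L, model.q
    n = q**L
    if n > cap:
        raise ValueError(f"q^L = {n} exceeds enumeration cap {cap}")
    states = enumerate_states(L, q)
    energies = np.zeros(n)
    for i in range(L):
        energies += model.h[i, states[:, i]]
    for i in range(L):
        for j in range(i + 1, L):
            energies += model.J[i, j][states[:, i], states[:, j]]
    m = energies.max()
    logZ = m + np.log(np.exp(energies - m).sum())
    P = np.exp(energies - logZ)
    p1 = np.zeros((L, q))
    for i in range(L):
        p1[i] = np.bincount(states[:, i], weights=P, minlength=q)
    p2 = np.zeros((L, L, q, q))
    for i in range(L):
        p2[i, i] = np.diag(p1[i])
        for j in range(i + 1, L):
            flat = states[:, i].astype(np.int64) * q + states[:, j]
            block = np.bincount(flat, weights=P, minlength=q * q).reshape(q, q)
            p2[i, j] = block
            p2[j, i] = block.T
    return ExactSummary(logZ=float(logZ), p1=p1, p2=p2)


def profile_init(stats: SiteStatistics) -> PottsModel:
    """Independent-site model h_i(a) = log f_i(a), J = 0.

    With the additive constant chosen as zero, the site marginals of the
    resulting model are exactly the (pseudocounted, hence strictly positive)
    input frequencies.
    """
    if np.any(stats.f1 <= 0):
        raise ValueError("profile initialisation requires strictly positive f_i")
    L, q = stats.f1.shape
    return PottsModel(h=np.log(stats.f1), J=np.zeros((L, L, q, q)))


@dataclass
class GaugeTransform:
    """Reparametrisation (g, K) leaving the Boltzmann measure invariant.

    ``K[i, j, a]`` acts on site i's state within the pair (i, j); the
    diagonal K[i, i] is ignored.
    """

    g: np.ndarray
    K: np.ndarray

    def apply(self, model: PottsModel) -> PottsModel:
        L, q = model.L, model.q
        if self.g.shape != (L,) or self.K.shape != (L, L, q):
            raise ValueError("gauge transform shape mismatch")
        K = self.K.copy()
        K[np.arange(L), np.arange(L)] = 0.0
        J = model.J + K[:, :, :, None] + K.transpose(1, 0, 2)[:, :, None, :]
        J[np.arange(L), np.arange(L)] = 0.0
        h = model.h + self.g[:, None] - K.sum(axis=1)
        return PottsModel(h=h, J=J, mask=_default_mask(L, q), gauge_tag="none")

    def inverse(self) -> "GaugeTransform":
        return GaugeTransform(g=-self.g, K=-self.K)


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Re-parametrise so every coupling block has zero row and column sums.

    The fields absorb the shift (so all sequence probabilities are unchanged)
    and are then centred to sum_a h_i(a) = 0.  The result is dense: a
    sparsity mask cannot survive the gauge change, so the returned model is
    fully active.
    """
    L, q = model.L, model.q
    row = model.J.mean(axis=3)               # mean over b -> (L, L, q)
    col = model.J.mean(axis=2)               # mean over a -> (L, L, q)
    tot = model.J.mean(axis=(2, 3))          # (L, L)
    J = (
        model.J
        - row[:, :, :, None]
        - col[:, :, None, :]
        + tot[:, :, None, None]
    )
    J[np.arange(L), np.arange(L)] = 0.0
    # inverse of the K used above: K[i,j,a] = -(row[i,j,a] - tot[i,j]/2)
    h = model.h + (row - tot[:, :, None] / 2.0).sum(axis=1)
    h = h - h.mean(axis=1, keepdims=True)
    return PottsModel(h=h, J=J, mask=_default_mask(L, q), gauge_tag="zero_sum")


def weakest_correlation_mask(stats: SiteStatistics) -> np.ndarray:
    """Gauge fixing by pinning weak couplings: per pair, inactivate the 2q-1
    entries with the smallest |empirical connected correlation|.

    Ties are broken lexicographically in (a, b).  Returns a boolean active
    mask of shape (L, L, q, q), symmetric, with False on the pinned entries.
    """
    if stats.alpha <= 0:
        raise ValueError("pseudocounted statistics required")
    c = np.abs(connected_correlations(stats))
    L, q = stats.L, stats.q
    k = 2 * q - 1
    mask = _default_mask(L, q)
    for i in range(L):
        for j in range(i + 1, L):
            order = np.argsort(c[i, j].ravel(), kind="stable")
            weak = order[:k]
            a, b = np.unravel_index(weak, (q, q))
            mask[i, j, a, b] = False
            mask[j, i, b, a] = False
    return mask


@dataclass
class ContactScores:
    """Frobenius norms F and APC-corrected scores S (symmetric, zero diagonal)."""

    F: np.ndarray
    S: np.ndarray


def frobenius_apc_scores(model: PottsModel, include_gap: bool = True) -> ContactScores:
    """Contact scores: zero-sum gauge, Frobenius norm, average-product correction.

    F_ij = sqrt( sum_{a,b} J'_ij(a,b)^2 ) with J' in the zero-sum gauge;
    S_ij = F_ij - Fbar_i Fbar_j / Fbar where Fbar_i averages F_ik over k != i
    and Fbar averages over all pairs.  ``include_gap=False`` drops the gap
    state from the norm (both conventions circulate in the field).
    """
    gauged = zero_sum_gauge(model)
    J = gauged.J if include_gap else gauged.J[:, :, 1:, 1:]
    F = np.sqrt((J**2).sum(axis=(2, 3)))
    L = model.L
    F[np.arange(L), np.arange(L)] = 0.0
    if L < 3:
        warnings.warn("APC undefined for L < 3; returning plain Frobenius norms")
        return ContactScores(F=F, S=F.copy())
    fbar_i = F.sum(axis=1) / (L - 1)
    fbar = F.sum() / (L * (L - 1))
    if fbar == 0.0:
        S = F.copy()
    else:
        S = F - np.outer(fbar_i, fbar_i) / fbar
    S[np.arange(L), np.arange(L)] = 0.0
    return ContactScores(F=F, S=S)


def write_scores(scores: ContactScores, path) -> None:
    """Write "i j F S" lines, 1-based indices, pairs i < j."""
    L = scores.F.shape[0]
    with open(path, "w") as fh:
        for i in range(L):
            for j in range(i + 1, L):
                fh.write(
                    f"{i + 1} {j + 1} {scores.F[i, j]:.8g} {scores.S[i, j]:.8g}\n"
                )
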