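"""Boltzmann-machine training of Potts models by stochastic gradient ascent.

Each epoch estimates the model marginals p_i, p_ij by MCMC and moves the
parameters along the log-posterior gradient

    h_i(a)     += eta_h [ f_i(a)    - p_i(a)    - reg ]
    J_ij(a, b) += eta_J [ f_ij(a,b) - p_ij(a,b) - reg ]

where the regularisation term is lambda_1 sign(.) (L1) or lambda_2 (.) (L2);
the two priors are alternatives, not additive.  Convergence is monitored on
the connected two-site correlations: training halts once

    eps_c = max_{i<j,a,b} | c^model_ij(a,b) - c^emp_ij(a,b) |

drops below a tolerance (default 1e-2).  eps_f and eps_s are the mean
absolute one- and two-site fitting errors, and the Pearson correlation
between model and empirical covariances tracks learning quality without
entering the halting rule.

Sparsification ("decimation") alternates convergence with pruning: active
couplings are ranked by the symmetric Kullback-Leibler divergence between
the current model and the model with that entry (or whole coupling block)
zeroed — both have closed forms, exact for a single removal — and the
lowest-scoring ones are masked until a target density is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .msa_io import MSA
from .mcmc_sampler import (
    ChainEnsemble,
    MCTimes,
    SampleBlock,
    estimate_marginals,
    init_chains,
    mean_pairwise_overlap,
    overlap_statistics,
    sample_epoch,
    update_mc_times,
)
from .potts_core import PottsModel, profile_init, zero_sum_gauge
from .preprocessing import (
    SiteStatistics,
    apply_pseudocount,
    compute_weights,
    connected_correlations,
    empirical_frequencies,
)

__all__ = [
    "TrainingConfig",
    "TrainerState",
    "ConvergenceMetrics",
    "FitResult",
    "gradient_update",
    "learning_rate_schedule",
    "convergence_metrics",
    "three_site_correlation",
    "decimation_scores",
    "decimate_step",
    "fit",
]


@dataclass
class TrainingConfig:
    """Knobs of one training run.  Learning-rate defaults follow the
    molecule-type convention (0.05 for proteins, 0.01 for RNA); sampler
    defaults are desk-scale (N_s=50 chains of N_c=10 samples, adaptive times
    from T_wait=10)."""

    eta_h: float = 0.05
    eta_J: float = 0.05
    lambda1: float = 0.0
    lambda2: float = 0.0
    alpha: float | None = None          # pseudocount; None -> 1/M_eff
    eps_c_target: float = 1e-2
    halt_patience: int = 1              # consecutive epochs below target required
    max_iter: int = 500
    # sampler settings
    n_chains: int = 50
    n_per_chain: int = 10
    t_wait: int = 10
    t_eq: int | None = None             # None -> 2 * t_wait
    max_t_wait: int = 10**5
    adaptive: bool = True
    persistent: bool = False
    skip_equilibration: bool = False
    sampler: str = "metropolis"
    chain_init: str = "uniform_random"
    # initialisation of the parameters
    init: str = "zero"                  # zero | profile | file
    # learning-rate schedule
    lr_schedule: str = "constant"       # constant | adagrad | search_then_converge
    tau: float = 1000.0
    adagrad_delta: float = 1e-8
    # decimation
    decimation: str = "off"             # off | element | block
    target_density: float = 1.0
    removal_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta_h <= 0 or self.eta_J <= 0:
            raise ValueError("learning rates must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("prior strengths must be non-negative")
        if not 0 < self.target_density <= 1:
            raise ValueError("target density must lie in (0, 1]")


@dataclass
class TrainerState:
    """Mutable per-run state: iteration counter, last gradient, and the
    accumulated squared gradients used by adagrad."""

    iteration: int = 0
    grad_h: np.ndarray | None = None
    grad_J: np.ndarray | None = None
    g2_h: np.ndarray | None = None
    g2_J: np.ndarray | None = None
    history: list = field(default_factory=list)


@dataclass
class ConvergenceMetrics:
    """eps_c (max connected-covariance error), eps_f / eps_s (mean one- and
    two-site fitting errors) and the covariance Pearson correlation
    (NaN when either covariance set is degenerate)."""

    eps_c: float
    eps_f: float
    eps_s: float
    pearson: float


def convergence_metrics(f: SiteStatistics, p: SiteStatistics) -> ConvergenceMetrics:
    if f.f1.shape != p.f1.shape:
        raise ValueError("statistics shapes do not match")
    L, q = f.L, f.q
    iu, ju = np.triu_indices(L, k=1)
    c_emp = connected_correlations(f)[iu, ju]
    c_mod = connected_correlations(p)[iu, ju]
    eps_c = float(np.abs(c_mod - c_emp).max()) if len(iu) else 0.0
    eps_f = float(np.abs(f.f1 - p.f1).sum() / (L * q))
    off = ~np.eye(L, dtype=bool)
    eps_s = float(np.abs(f.f2 - p.f2)[off].sum() / (L**2 * q**2))
    x, y = c_emp.ravel(), c_mod.ravel()
    if len(iu) == 0 or x.std() == 0.0 or y.std() == 0.0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(x, y)[0, 1])
    return ConvergenceMetrics(eps_c=eps_c, eps_f=eps_f, eps_s=eps_s, pearson=pearson)


def learning_rate_schedule(
    state: TrainerState, config: TrainingConfig
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Effective (eta_h, eta_J) for the current step.

    constant: the configured rates.  adagrad: eta / sqrt(G + delta) per
    parameter, with G the running sum of squared gradients (updated here, so
    the current gradient must already be stored in ``state``).
    search_then_converge: eta0 / (1 + t / tau).
    """
    if config.lr_schedule == "constant":
        return config.eta_h, config.eta_J
    if config.lr_schedule == "search_then_converge":
        damp = 1.0 + state.iteration / config.tau
        return config.eta_h / damp, config.eta_J / damp
    if config.lr_schedule == "adagrad":
        if state.grad_h is None or state.grad_J is None:
            raise ValueError("adagrad needs the current gradient in the state")
        if state.g2_h is None:
            state.g2_h = np.zeros_like(state.grad_h)
            state.g2_J = np.zeros_like(state.grad_J)
        state.g2_h += state.grad_h**2
        state.g2_J += state.grad_J**2
        return (
            config.eta_h / np.sqrt(state.g2_h + config.adagrad_delta),
            config.eta_J / np.sqrt(state.g2_J + config.adagrad_delta),
        )
    raise NotImplementedError(
        f"learning-rate schedule {config.lr_schedule!r} is not implemented"
    )


def gradient_update(
    model: PottsModel,
    f: SiteStatistics,
    p: SiteStatistics,
    config: TrainingConfig,
    state: TrainerState | None = None,
) -> PottsModel:
    """One in-place gradient-ascent step on the active parameters."""
    if config.lambda1 > 0 and config.lambda2 > 0:
        raise ValueError("L1 and L2 priors are alternatives; set only one")
    if f.f1.shape != p.f1.shape or f.f1.shape != model.h.shape:
        raise ValueError("statistics/model shape mismatch")
    if state is None:
        state = TrainerState()
    grad_h = f.f1 - p.f1
    grad_J = f.f2 - p.f2
    if config.lambda1 > 0:
        grad_h = grad_h - config.lambda1 * np.sign(model.h)
        grad_J = grad_J - config.lambda1 * np.sign(model.J)
    elif config.lambda2 > 0:
        grad_h = grad_h - config.lambda2 * model.h
        grad_J = grad_J - config.lambda2 * model.J
    state.grad_h, state.grad_J = grad_h, grad_J
    eta_h, eta_J = learning_rate_schedule(state, config)
    model.h += eta_h * grad_h
    step = eta_J * grad_J
    step[~model.mask] = 0.0
    # keep the tensor exactly symmetric: average the two images of each pair
    step = 0.5 * (step + step.transpose(1, 0, 3, 2))
    model.J += step
    return model


def three_site_correlation(
    source,
    triplet: tuple[int, int, int],
    states: tuple[int, int, int],
    weights: np.ndarray | None = None,
) -> float:
    """Connected three-site correlation c_ijk(a,b,c) of a sample source.

    c = f_ijk - f_ij f_k - f_ik f_j - f_jk f_i + 2 f_i f_j f_k, with all
    frequencies taken from ``source`` (a SampleBlock, an MSA with optional
    weights, or a plain code matrix).
    """
    i, j, k = triplet
    if len({i, j, k}) != 3:
        raise ValueError("triplet indices must be distinct")
    a, b, c = states
    if isinstance(source, SampleBlock):
        data, w = source.flat(), None
    elif isinstance(source, MSA):
        data, w = source.data, source.weights
    else:
        data, w = np.asarray(source), weights
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    if w is None:
        w = np.ones(data.shape[0])
    norm = w.sum()
    di = (data[:, i] == a).astype(float)
    dj = (data[:, j] == b).astype(float)
    dk = (data[:, k] == c).astype(float)
    f_i, f_j, f_k = (w @ di) / norm, (w @ dj) / norm, (w @ dk) / norm
    f_ij = (w @ (di * dj)) / norm
    f_ik = (w @ (di * dk)) / norm
    f_jk = (w @ (dj * dk)) / norm
    f_ijk = (w @ (di * dj * dk)) / norm
    return float(
        f_ijk - f_ij * f_k - f_ik * f_j - f_jk * f_i + 2.0 * f_i * f_j * f_k
    )


def decimation_scores(
    model: PottsModel, p: SiteStatistics, mode: str = "element"
) -> np.ndarray:
    """Symmetric-KL cost of removing each active coupling entry (or block).

    For one entry J = J_ij(a,b) with current model marginal p = p_ij(a,b),
    zeroing it reweights the measure by exp(-J) on the matching
    configurations, so the perturbed marginal is
    p' = p e^{-J} / (1 - p + p e^{-J}) and the symmetric KL divergence is
    exactly J (p - p').  Inactive entries get +inf (never selected).

    ``element`` returns an (L, L, q, q) score tensor; ``block`` an (L, L)
    matrix with the per-pair score sum_{a,b} (p_ij - p'_ij) J_ij where
    p'_ij(a,b) = p_ij(a,b) e^{-J_ij(a,b)} / sum_{cd} p_ij(c,d) e^{-J_ij(c,d)}.
    """
    if mode not in ("element", "block"):
        raise ValueError(f"unknown decimation mode {mode!r}")
    J = model.J
    pj = p.f2
    if mode == "element":
        e = np.exp(-J)
        denom = 1.0 - pj + pj * e
        p_prime = pj * e / denom
        scores = J * (pj - p_prime)
        scores[~model.mask] = np.inf
        return scores
    # block mode
    L = model.L
    e = np.exp(-J)
    w = pj * e
    denom = w.sum(axis=(2, 3), keepdims=True)
    p_prime = np.divide(w, denom, out=np.zeros_like(w), where=denom > 0)
    scores = (J * (pj - p_prime)).sum(axis=(2, 3))
    pair_active = model.mask.any(axis=(2, 3))
    scores[~pair_active] = np.inf
    scores[np.arange(L), np.arange(L)] = np.inf
    return scores


def decimate_step(
    model: PottsModel,
    scores: np.ndarray,
    removal_fraction: float = 0.1,
    mode: str = "element",
    n_remove: int | None = None,
) -> PottsModel:
    """Mask the lowest-scoring active entries (or whole pair blocks) in place.

    Exactly ``n_remove`` entries/blocks are removed (default: ceil of
    ``removal_fraction`` times the active count); ties break
    lexicographically.  Refuses to empty the model.
    """
    L, q = model.L, model.q
    iu, ju = np.triu_indices(L, k=1)
    if mode == "element":
        flat_scores = scores[iu, ju].ravel()      # (n_pairs * q * q,)
        active = model.mask[iu, ju].ravel()
    elif mode == "block":
        flat_scores = scores[iu, ju].ravel()      # (n_pairs,)
        active = model.mask[iu, ju].any(axis=(1, 2))
    else:
        raise ValueError(f"unknown decimation mode {mode!r}")
    n_active = int(active.sum())
    if n_active == 0:
        raise ValueError("model has no active entries")
    if n_remove is None:
        n_remove = ceil(removal_fraction * n_active)
    if n_remove >= n_active:
        raise ValueError("removal would empty the model")
    order = np.argsort(np.where(active, flat_scores, np.inf), kind="stable")
    chosen = order[:n_remove]
    if mode == "element":
        pair_idx, state_idx = np.divmod(chosen, q * q)
        a, b = np.divmod(state_idx, q)
        i, j = iu[pair_idx], ju[pair_idx]
        model.mask[i, j, a, b] = False
        model.mask[j, i, b, a] = False
        model.J[i, j, a, b] = 0.0
        model.J[j, i, b, a] = 0.0
    else:
        i, j = iu[chosen], ju[chosen]
        model.mask[i, j] = False
        model.mask[j, i] = False
        model.J[i, j] = 0.0
        model.J[j, i] = 0.0
    return model


@dataclass
class FitResult:
    """Outcome of :func:`fit`: the converged model in zero-sum gauge, the raw
    (un-gauged, possibly sparse) model, per-epoch metric rows, and status."""

    model: PottsModel
    raw_model: PottsModel
    history: list
    converged: bool
    f_stats: SiteStatistics
    times: MCTimes
    ensemble: ChainEnsemble
    reference_overlap: float | None = None


def _density(model: PottsModel, mode: str) -> float:
    L, q = model.L, model.q
    iu = np.triu_indices(L, k=1)
    if mode == "block":
        return float(model.mask[iu].any(axis=(1, 2)).mean())
    return float(model.mask[iu].mean())


def fit(
    msa: MSA,
    config: TrainingConfig,
    *,
    model: PottsModel | None = None,
    topology: np.ndarray | None = None,
    verbose: bool = False,
) -> FitResult:
    """Train a Potts model on an alignment.

    Pipeline: weights (reused from the MSA if present) -> empirical
    frequencies -> pseudocount -> initialisation (zero / profile / warm-start
    ``model``) -> training epochs of sampling, marginal estimation, overlap
    diagnostics, optional time adaptation, gradient update, convergence
    metrics — until eps_c reaches its target or ``max_iter`` epochs pass.
    With decimation enabled, pruning events alternate with re-convergence
    until the target density is reached.  ``topology`` (a boolean active
    mask) pins absent couplings to zero for the whole run.
    """
    rng = np.random.default_rng(config.seed)
    if msa.weights is not None:
        weights = msa.weights
    else:
        weights = compute_weights(msa).w
    msa = MSA(msa.names, msa.data, msa.alphabet, weights)
    stats = empirical_frequencies(msa)
    m_eff = float(weights.sum())
    alpha = config.alpha if config.alpha is not None else 1.0 / m_eff
    f = apply_pseudocount(stats, alpha)

    L, q = msa.length, msa.alphabet.q
    if config.init == "file":
        if model is None:
            raise ValueError("init='file' requires a warm-start model")
        model = model.copy()
    elif config.init == "profile":
        model = profile_init(f)
    elif config.init == "zero":
        model = PottsModel.zeros(L, q)
    else:
        raise ValueError(f"unknown initialisation {config.init!r}")
    if topology is not None:
        model.mask &= np.asarray(topology, dtype=bool)
        model.J[~model.mask] = 0.0

    ensemble = init_chains(
        config.chain_init,
        config.n_chains,
        L=L,
        q=q,
        msa=msa if config.chain_init == "msa_weighted" else None,
        rng=rng,
        persistent=config.persistent,
        skip_equilibration=config.skip_equilibration,
    )
    times = MCTimes.initial(config.t_wait, config.t_eq)
    state = TrainerState()
    try:
        q_msa = mean_pairwise_overlap(msa.data, rng)
    except ValueError:
        q_msa = None

    converged = False
    below_target = 0  # consecutive epochs with eps_c under the tolerance:
    # halting on a single noisy crossing would stop while the true error is
    # still at the tolerance, so the criterion must hold `halt_patience` times
    diagnostics_on = config.n_per_chain >= 3 and config.n_chains >= 2
    if config.adaptive and not diagnostics_on:
        raise ValueError("adaptive MC times need N_c >= 3 and N_s >= 2")
    for t in range(config.max_iter):
        block = sample_epoch(model, ensemble, times, config.n_per_chain, config.sampler)
        p = estimate_marginals(block)
        metrics = convergence_metrics(f, p)
        ostats = (
            overlap_statistics(block, rng=rng, reference_overlap=q_msa)
            if diagnostics_on
            else None
        )
        row = {
            "iteration": t,
            "eps_c": metrics.eps_c,
            "eps_f": metrics.eps_f,
            "eps_s": metrics.eps_s,
            "pearson": metrics.pearson,
            "mu_ext": ostats.mu_ext if ostats else float("nan"),
            "mu_int1": ostats.mu_int1 if ostats else float("nan"),
            "mu_int2": ostats.mu_int2 if ostats else float("nan"),
            "t_wait": times.t_wait,
            "active_parameters": model.n_active,
        }
        state.history.append(row)
        if verbose:
            import sys

            print(
                f"epoch {t}: eps_c={metrics.eps_c:.4g} eps_f={metrics.eps_f:.4g} "
                f"eps_s={metrics.eps_s:.4g} pearson={metrics.pearson:.4g} "
                f"t_wait={times.t_wait} active={model.n_active}",
                file=sys.stderr,
            )
        below_target = below_target + 1 if metrics.eps_c <= config.eps_c_target else 0
        if below_target >= config.halt_patience:
            if config.decimation == "off":
                converged = True
                break
            below_target = 0
            density = _density(model, config.decimation)
            if density <= config.target_density:
                converged = True
                break
            # prune towards the target, then keep training
            scores = decimation_scores(model, p, config.decimation)
            iu = np.triu_indices(L, k=1)
            if config.decimation == "block":
                n_active = int(model.mask[iu].any(axis=(1, 2)).sum())
                n_total = len(iu[0])
            else:
                n_active = int(model.mask[iu].sum())
                n_total = len(iu[0]) * q * q
            n_target = ceil(config.target_density * n_total)
            k = min(ceil(config.removal_fraction * n_active), n_active - n_target)
            if k <= 0:
                converged = True
                break
            decimate_step(model, scores, mode=config.decimation, n_remove=k)
            continue
        if config.adaptive and ostats is not None:
            times = update_mc_times(ostats, times, config.max_t_wait)
        gradient_update(model, f, p, config, state)
        state.iteration += 1
    if not converged and state.history:
        warnings.warn(
            f"training stopped at max_iter={config.max_iter} with "
            f"eps_c={state.history[-1]['eps_c']:.3g} above the "
            f"target {config.eps_c_target:.3g}"
        )
    return FitResult(
        model=zero_sum_gauge(model),
        raw_model=model,
        history=state.history,
        converged=converged,
        f_stats=f,
        times=times,
        ensemble=ensemble,
        reference_overlap=q_msa,
    )
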