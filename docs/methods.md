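# Methods

## Model

`pottsdca` fits a pairwise Potts (Markov random field) model over aligned
sequences of length L on a q-state alphabet whose first state is the
alignment gap:

    P(s) = Z⁻¹ exp( Σᵢ hᵢ(sᵢ) + Σᵢ<ⱼ Jᵢⱼ(sᵢ, sⱼ) ).

The model is the maximum-entropy distribution reproducing the one- and
two-site frequencies of the alignment; sequences are treated as i.i.d.
draws, with phylogenetic redundancy handled only through similarity
reweighting. Couplings are stored as a full L×L×q×q tensor with
J[j,i,b,a] = J[i,j,a,b] and zero diagonal, so the local energy differences
used by the samplers are plain gathers; a boolean mask of the same shape
pins inactive entries (imposed topologies, decimation) to exactly zero.

## Pre-processing

* **Reweighting.** w^μ = 1/k, k = number of sequences with ≥ 80 % identity
  to μ (inclusive, μ itself counted). Gap–gap positions count as identities
  by default (`match_gaps` flips this; with it off, a sequence always still
  counts itself). M_eff = Σ w^μ. The scan is O(M²L), chunked matrix products.
* **Gap filter.** Sequences with a run of more than 6 consecutive gaps can
  be dropped (`filter_gap_runs`), preventing a bias towards gapped samples.
* **Pseudocount.** f ← (1−α)f + α/q (pairs: α/q²); default α = 1/M_eff.
  The convex mixture preserves the marginalisation identity
  Σ_b f_ij(a,b) = f_i(a) exactly for every α, and makes all frequencies
  strictly positive so the profile fields log f are finite.

## Sampling

One sweep = L elementary moves. Metropolis picks a site uniformly at random
(with replacement) and proposes one of the q−1 other states uniformly;
acceptance is min(1, e^{ΔE}) computed from the O(L) local field. Gibbs does
a systematic scan 0…L−1, resampling each site from its exact conditional
(so for J = 0 a single pass yields an exact independent sample). Both
kernels are vectorised across chains; with a fixed seed trajectories are
bit-reproducible.

An epoch runs N_s chains for T_eq sweeps, then records N_c samples per
chain spaced T_wait sweeps apart. Chains are *transient* (re-initialised
every epoch, from uniform random sequences or from weighted natural
sequences) or *persistent* (carried across epochs; T_eq is still run each
epoch unless `skip_equilibration` is set, since the parameters moved since
the previous epoch).

**Adaptive times.** Three overlap families diagnose sampling quality: Q^ext
(different chains, same sampling time; computed over a random disjoint chain
pairing per time slice, which is O(N_s) rather than all-pairs O(N_s²)),
Q^int1 (consecutive samples of a chain), Q^int2 (two steps apart). The
"standard error" entering the tests is the standard error of the mean. If
|μ_ext − μ_int2| > 5√(se²_ext + se²_int2) the samples are not de-correlated
and T_wait doubles (T_prev remembers the pre-doubling value); otherwise, if
|μ_ext − μ_int1| < 5√(se²_ext + se²_int1) the chains de-correlate within a
single waiting interval and T_wait relaxes to ⌈(T_wait + T_prev)/2⌉. The
doubling test has priority. After every update T_eq = 2·T_wait; T_wait is
capped (default 10⁵). Defaults: N_s = 50, N_c = 10, initial T_wait = 10 —
all overridable; the out-of-equilibrium preset used in the benchmark is
persistent chains with fixed T_wait = 5, T_eq = 10.

## Training

Gradient ascent on the log-posterior: h += η_h(f₁ − p₁ − reg),
J += η_J(f₂ − p₂ − reg) on active entries, with reg = λ₁ sign(·)
(sub-gradient at 0 taken as 0, no proximal step) or λ₂ (·); the two priors
are mutually exclusive and apply to active entries only. Default
η = 0.05 (protein convention; 0.01 for RNA), same for fields and couplings.
Schedules: constant (default), adagrad (η/√(G+δ), δ = 10⁻⁸, G accumulated
per parameter), search-then-converge (η₀/(1+t/τ), τ = 1000). FIRE and
quasi-Newton schedules are deliberately not implemented.

**Convergence.** eps_c = max over pairs and states of the difference
between model and empirical connected correlations; eps_f and eps_s are the
mean absolute one- and two-site errors (eps_s summed over ordered pairs
i≠j and divided by L²q²); the Pearson correlation between the two
covariance sets is logged but never used for halting (it is reported as NaN
when either covariance set has zero variance). Because eps_c is estimated
from a finite MCMC sample, a single threshold crossing can be a favourable
noise draw while the true error still sits at the tolerance; `halt_patience`
therefore requires the tolerance to hold on that many consecutive epochs
(benchmark runs use 3) before training stops. Convergence is checked before
the gradient step, so the returned model is the one whose sampled marginals
met the tolerance.

**Decimation.** Removing one coupling entry J = J_ij(a,b) reweights the
Boltzmann measure by e^{−J} on configurations with (sᵢ,sⱼ) = (a,b), so the
pruned-model marginal is p′ = p e^{−J}/(1 − p + p e^{−J}) and the symmetric
Kullback–Leibler divergence between the two models is exactly J(p − p′);
the block score Σ_{ab}(p_ij − p′_ij)J_ij with
p′_ij ∝ p_ij e^{−J_ij} is likewise exact for removing one whole block.
(Both formulas are exact for a *single* removal; scoring all candidates at
once ignores their interaction, as any one-step ranking must.) At each
pruning event the lowest-scoring 10 % of active entries (ties broken
lexicographically, never more than needed to reach the target density) are
masked, training resumes, and the converge/prune alternation continues until
a converged model at the target density results.

**Gauge.** The parametrisation is redundant under
J_ij(a,b) → J_ij(a,b) + K[i,j](a) + K[j,i](b),
h_i(a) → h_i(a) + g_i − Σ_{j≠i} K[i,j](a); this form is verified by
property tests to leave every sequence probability unchanged. The zero-sum
gauge (row and column sums of every block vanish; fields centred) minimises
the coupling Frobenius norms and is applied before contact scoring and to
the model returned by `fit`. A gauge change cannot preserve a sparsity
mask, so the gauged model is dense and `fit` also returns the raw model
with its mask intact. As an alternative, `weakest_correlation_mask` fixes
the gauge before learning by pinning, per pair, the 2q−1 entries with the
weakest empirical connected correlations.

**Scores.** F_ij is the Frobenius norm of the zero-sum-gauge block (gap
state included by default; a flag excludes it, as both conventions exist),
and the average-product correction S_ij = F_ij − F̄ᵢF̄ⱼ/F̄ removes the
site-wise background. PPV is evaluated on pairs with |i−j| > 4; the
thresholded contact map keeps scores > 0.20.

## Synthetic benchmark

`fixtures.random_potts` plants a sparse model: pairs active i.i.d. with
probability `density`, active blocks N(0, coupling_scale²), fields
N(0, field_scale²) with defaults 1.0 and 0.3 — couplings of order one give
a clearly structured, non-trivially coupled system, while 0.3 keeps sites
away from near-deterministic conservation. `fixtures.synthetic_msa` draws
alignments exactly, by enumerating the q^L state space and inverting the
CDF — no MCMC enters the data generation, so sampler tests are not
circular. Synthetic alignments carry unit weights and no phylogeny: passing
tests demonstrate correctness of the inference machinery under the model's
own assumptions (i.i.d. data, modest L), not robustness to the tree-like
correlations, alignment errors and 21-state alphabets of real families.

The benchmark conditions used by the acceptance tests and
`scripts/acceptance.py`: planted L = 8, q = 3, density 0.3, coupling scale
1.0; training with profile initialisation, constant η = 0.05,
α = 1/M_eff, N_s = 1000 × N_c = 10 (precision runs) or N_s = 500
(recovery runs), adaptive times from T_wait = 10; the converged model is
re-sampled with T_eq = 5000, T_wait = 2500 and 2000 × 20 samples for the
final covariance check. These sizes keep a full run to minutes on one CPU
while leaving the MCMC noise floor (≈ 3·10⁻³ per covariance entry at
4·10⁴ samples) well under the 10⁻² tolerance being verified.

## Numerical notes and limitations

* Enumeration (`exact_marginals`) is capped at q^L ≤ 2²⁰ states; it serves
  as the oracle for samplers, gauges and decimation scores, and is
  cross-checked against an independent transfer-matrix implementation on
  chain topologies.
* Pair statistics are held as dense L×L×q×q tensors: transparent and fast
  at benchmark scale, but memory grows as (Lq)²/2 — at protein-family scale
  (L ≈ 500) a streaming implementation would be needed.
* Metropolis proposals exclude the current state; either convention is
  valid Metropolis–Hastings, this one wastes no proposals.
* Parameter files are 0-based plain text ("J i j a b value" / "h i a
  value"); external files in other dialects must be converted. Weight files
  are one decimal per line. Topology and contact files are 1-based "i j"
  pair lists.
* The profile initialisation requires strictly positive frequencies, hence
  a positive pseudocount.
* Unknown residues and '.' map to the gap state; with heavily ambiguous
  data this inflates gap statistics.
* PCA one-hot covariance is (Lq)×(Lq) and eigendecomposed densely — fine at
  desk scale, quadratic in Lq beyond it.
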