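import numpy as np
import pytest

from pottsdca.fixtures import random_potts, synthetic_msa
from pottsdca.potts_core import PottsModel, exact_marginals
from pottsdca.preprocessing import SiteStatistics, apply_pseudocount, empirical_frequencies
from pottsdca.trainer import (
    TrainerState,
    TrainingConfig,
    convergence_metrics,
    decimate_step,
    decimation_scores,
    fit,
    gradient_update,
    learning_rate_schedule,
    three_site_correlation,
)


def stats_pair(f1, f2_block):
    """Build a 2-site SiteStatistics from one q x q joint block."""
    q = f1.shape[1]
    f2 = np.zeros((2, 2, q, q))
    f2[0, 1] = f2_block
    f2[1, 0] = f2_block.T
    for i in range(2):
        f2[i, i] = np.diag(f1[i])
    return SiteStatistics(f1=f1, f2=f2, alpha=0.01, kind="pseudocounted")


class TestGradientUpdate:
    def test_stationary_at_matching_marginals(self):
        f1 = np.array([[0.6, 0.4], [0.3, 0.7]])
        block = np.outer(f1[0], f1[1])
        f = stats_pair(f1, block)
        p = stats_pair(f1, block)
        model = PottsModel.zeros(2, 2)
        model.h[:] = 1.0
        before = model.h.copy()
        gradient_update(model, f, p, TrainingConfig())
        np.testing.assert_array_equal(model.h, before)
        assert np.all(model.J == 0)

    def test_field_step_is_eta_times_gradient(self):
        f1 = np.array([[0.6, 0.4]])
        p1 = np.array([[0.4, 0.6]])
        f = SiteStatistics(f1=f1, f2=np.zeros((1, 1, 2, 2)))
        p = SiteStatistics(f1=p1, f2=np.zeros((1, 1, 2, 2)))
        model = PottsModel.zeros(1, 2)
        gradient_update(model, f, p, TrainingConfig(eta_h=0.05))
        assert model.h[0, 0] == pytest.approx(0.01)

    def test_l2_prior_shrinks_couplings(self):
        f1 = np.full((2, 2), 0.5)
        block = np.full((2, 2), 0.25)
        f = stats_pair(f1, block)
        p = stats_pair(f1, block)
        model = PottsModel.zeros(2, 2)
        model.set_coupling(0, 1, np.ones((2, 2)))
        gradient_update(
            model, f, p, TrainingConfig(eta_J=0.1, lambda2=0.5)
        )
        np.testing.assert_allclose(model.J[0, 1], 0.95)

    def test_l1_and_l2_together_rejected(self):
        f = stats_pair(np.full((2, 2), 0.5), np.full((2, 2), 0.25))
        model = PottsModel.zeros(2, 2)
        with pytest.raises(ValueError):
            gradient_update(
                model, f, f, TrainingConfig(lambda1=0.1, lambda2=0.1)
            )

    def test_masked_entries_stay_zero(self):
        f1 = np.array([[0.9, 0.1], [0.9, 0.1]])
        f = stats_pair(f1, np.outer(f1[0], f1[1]) + 0.05 * np.array([[1, -1], [-1, 1]]))
        p = stats_pair(f1, np.outer(f1[0], f1[1]))
        model = PottsModel.zeros(2, 2)
        model.mask[0, 1, 0, 0] = model.mask[1, 0, 0, 0] = False
        gradient_update(model, f, p, TrainingConfig())
        assert model.J[0, 1, 0, 0] == 0.0
        assert model.J[0, 1, 1, 1] != 0.0


class TestLearningRateSchedule:
    def test_constant(self):
        cfg = TrainingConfig(eta_h=0.05, eta_J=0.05, lr_schedule="constant")
        assert learning_rate_schedule(TrainerState(), cfg) == (0.05, 0.05)

    def test_adagrad_first_step(self):
        cfg = TrainingConfig(eta_h=0.05, eta_J=0.05, lr_schedule="adagrad")
        state = TrainerState(
            grad_h=np.array([[2.0]]), grad_J=np.array([[[[2.0]]]])
        )
        eta_h, eta_J = learning_rate_schedule(state, cfg)
        assert eta_h[0, 0] == pytest.approx(0.025, rel=1e-4)
        assert eta_J[0, 0, 0, 0] == pytest.approx(0.025, rel=1e-4)

    def test_search_then_converge_halves_at_tau(self):
        cfg = TrainingConfig(eta_h=0.05, eta_J=0.05,
                             lr_schedule="search_then_converge", tau=100.0)
        state = TrainerState(iteration=100)
        eta_h, _ = learning_rate_schedule(state, cfg)
        assert eta_h == pytest.approx(0.025)

    def test_unknown_schedule_not_implemented(self):
        cfg = TrainingConfig(lr_schedule="fire")
        with pytest.raises(NotImplementedError):
            learning_rate_schedule(TrainerState(), cfg)


class TestConvergenceMetrics:
    def test_perfect_match_with_nondegenerate_covariances(self):
        f1 = np.array([[0.6, 0.4], [0.3, 0.7]])
        block = np.outer(f1[0], f1[1]) + 0.05 * np.array([[1, -1], [-1, 1]])
        f = stats_pair(f1, block)
        m = convergence_metrics(f, f)
        assert m.eps_c == 0.0 and m.eps_f == 0.0 and m.eps_s == 0.0
        assert m.pearson == pytest.approx(1.0)

    def test_degenerate_covariances_give_nan_pearson(self):
        f1 = np.array([[0.5, 0.5], [0.5, 0.5]])
        block = np.outer(f1[0], f1[1])  # exactly factorised: zero covariance
        f = stats_pair(f1, block)
        m = convergence_metrics(f, f)
        assert np.isnan(m.pearson) and m.eps_c == 0.0

    def test_hand_computed_metrics(self):
        f1 = np.array([[0.6, 0.4], [0.5, 0.5]])
        p1 = np.array([[0.5, 0.5], [0.5, 0.5]])
        fb = np.array([[0.4, 0.2], [0.1, 0.3]])
        pb = np.array([[0.25, 0.25], [0.25, 0.25]])
        f, p = stats_pair(f1, fb), stats_pair(p1, pb)
        m = convergence_metrics(f, p)
        # c_emp = fb - outer(f1[0], f1[1]); c_mod = 0
        c_emp = fb - np.outer(f1[0], f1[1])
        assert m.eps_c == pytest.approx(np.abs(c_emp).max())
        assert m.eps_f == pytest.approx(np.abs(f1 - p1).sum() / 4)
        assert m.eps_s == pytest.approx(2 * np.abs(fb - pb).sum() / 16)


class TestThreeSiteCorrelation:
    def test_factorised_frequencies_give_zero(self, rng):
        # independent sites: connected three-point correlation vanishes
        data = rng.integers(0, 3, size=(6000, 3))
        c = three_site_correlation(data, (0, 1, 2), (1, 2, 0))
        # finite-sample value; compare against the exact counting identity
        assert abs(c) < 0.01

    def test_permutation_invariance(self, rng):
        data = rng.integers(0, 3, size=(500, 4))
        c1 = three_site_correlation(data, (0, 1, 3), (1, 2, 0))
        c2 = three_site_correlation(data, (1, 3, 0), (2, 0, 1))
        c3 = three_site_correlation(data, (3, 0, 1), (0, 1, 2))
        assert c1 == pytest.approx(c2) == pytest.approx(c3)

    def test_against_direct_counting(self):
        data = np.array(
            [[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1], [1, 0, 1], [0, 1, 0]]
        )
        w = np.array([1.0, 0.5, 1.0, 0.25, 1.0, 0.5])
        a, b, c = 0, 1, 1
        W = w.sum()
        fi = w[data[:, 0] == a].sum() / W
        fj = w[data[:, 1] == b].sum() / W
        fk = w[data[:, 2] == c].sum() / W
        fij = w[(data[:, 0] == a) & (data[:, 1] == b)].sum() / W
        fik = w[(data[:, 0] == a) & (data[:, 2] == c)].sum() / W
        fjk = w[(data[:, 1] == b) & (data[:, 2] == c)].sum() / W
        fijk = w[(data[:, 0] == a) & (data[:, 1] == b) & (data[:, 2] == c)].sum() / W
        expected = fijk - fij * fk - fik * fj - fjk * fi + 2 * fi * fj * fk
        got = three_site_correlation(data, (0, 1, 2), (a, b, c), weights=w)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_distinct_indices_required(self):
        with pytest.raises(ValueError):
            three_site_correlation(np.zeros((3, 4), dtype=int), (0, 0, 1), (0, 0, 0))


def brute_force_symmetric_kl(model, i, j, a, b):
    """Oracle: symmetric KL between the model and the model with one
    coupling entry zeroed, by full enumeration."""
    from pottsdca.potts_core import enumerate_states, log_score

    pruned = model.copy()
    block = pruned.J[i, j].copy()
    block[a, b] = 0.0
    pruned.set_coupling(i, j, block)
    states = enumerate_states(model.L, model.q)
    lp = np.array([log_score(model, s) for s in states])
    lq = np.array([log_score(pruned, s) for s in states])
    p = np.exp(lp - lp.max())
    p /= p.sum()
    qd = np.exp(lq - lq.max())
    qd /= qd.sum()
    return float((p * np.log(p / qd)).sum() + (qd * np.log(qd / p)).sum())


class TestDecimation:
    def test_zero_coupling_scores_zero(self):
        model = PottsModel.zeros(2, 2)
        p = stats_pair(np.full((2, 2), 0.5), np.full((2, 2), 0.25))
        scores = decimation_scores(model, p, "element")
        assert np.all(scores[0, 1] == 0.0)

    def test_closed_form_single_entry(self):
        # J = ln 2 with marginal p = 1/2 -> p' = 1/3, score = ln2 * (1/2 - 1/3)
        model = PottsModel.zeros(2, 2)
        block = np.zeros((2, 2))
        block[1, 1] = np.log(2)
        model.set_coupling(0, 1, block)
        f1 = np.full((2, 2), 0.5)
        joint = np.full((2, 2), 1 / 6)
        joint[1, 1] = 0.5
        p = stats_pair(f1, joint)
        scores = decimation_scores(model, p, "element")
        assert scores[0, 1, 1, 1] == pytest.approx(np.log(2) / 6, rel=1e-12)

    @pytest.mark.parametrize("q", [2, 3])
    def test_element_score_equals_brute_force_kl(self, q, rng):
        planted = random_potts(2, q, 1.0, coupling_scale=0.9, seed=q)
        model = planted.model
        exact = exact_marginals(model)
        p = SiteStatistics(f1=exact.p1, f2=exact.p2, kind="model")
        scores = decimation_scores(model, p, "element")
        for a in range(q):
            for b in range(q):
                oracle = brute_force_symmetric_kl(model, 0, 1, a, b)
                assert scores[0, 1, a, b] == pytest.approx(oracle, abs=1e-10)

    def test_block_score_equals_brute_force_block_kl(self, rng):
        planted = random_potts(3, 2, 1.0, coupling_scale=0.8, seed=5)
        model = planted.model
        exact = exact_marginals(model)
        p = SiteStatistics(f1=exact.p1, f2=exact.p2, kind="model")
        scores = decimation_scores(model, p, "block")
        # oracle: zero the whole (0,1) block and compute symmetric KL
        pruned = model.copy()
        pruned.set_coupling(0, 1, np.zeros((2, 2)))
        from pottsdca.potts_core import enumerate_states, log_score

        states = enumerate_states(3, 2)
        lp = np.array([log_score(model, s) for s in states])
        lq = np.array([log_score(pruned, s) for s in states])
        p_ = np.exp(lp - lp.max()); p_ /= p_.sum()
        q_ = np.exp(lq - lq.max()); q_ /= q_.sum()
        oracle = float((p_ * np.log(p_ / q_)).sum() + (q_ * np.log(q_ / p_)).sum())
        assert scores[0, 1] == pytest.approx(oracle, abs=1e-10)

    def test_scores_nonnegative(self, rng):
        model = random_potts(4, 3, 1.0, seed=8).model
        exact = exact_marginals(model)
        p = SiteStatistics(f1=exact.p1, f2=exact.p2, kind="model")
        scores = decimation_scores(model, p, "element")
        iu = np.triu_indices(4, k=1)
        assert scores[iu].min() >= -1e-15

    def test_decimate_removes_exact_count(self):
        model = random_potts(4, 3, 1.0, seed=3).model
        exact = exact_marginals(model)
        p = SiteStatistics(f1=exact.p1, f2=exact.p2, kind="model")
        scores = decimation_scores(model, p, "element")
        before = model.n_active
        decimate_step(model, scores, mode="element", n_remove=7)
        assert model.n_active == before - 7
        model.validate()

    def test_block_mode_masks_whole_pair(self):
        model = random_potts(4, 2, 1.0, seed=6).model
        exact = exact_marginals(model)
        p = SiteStatistics(f1=exact.p1, f2=exact.p2, kind="model")
        scores = decimation_scores(model, p, "block")
        decimate_step(model, scores, mode="block", n_remove=1)
        weakest = int(np.argmin([scores[i, j] for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]]))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        i, j = pairs[weakest]
        assert not model.mask[i, j].any()
        assert np.all(model.J[i, j] == 0)

    def test_masked_entries_never_rescored(self):
        model = random_potts(3, 2, 1.0, seed=9).model
        exact = exact_marginals(model)
        p = SiteStatistics(f1=exact.p1, f2=exact.p2, kind="model")
        scores = decimation_scores(model, p, "element")
        decimate_step(model, scores, mode="element", n_remove=2)
        scores2 = decimation_scores(model, p, "element")
        assert np.isinf(scores2[~model.mask]).all()

    def test_emptying_model_rejected(self):
        model = PottsModel.zeros(2, 2)
        scores = np.zeros((2, 2, 2, 2))
        with pytest.raises(ValueError):
            decimate_step(model, scores, mode="element", n_remove=4)


class TestFit:
    def test_profile_data_recovers_zero_couplings(self):
        # data drawn from an independent-site model: inferred couplings in
        # the zero-sum gauge must be near zero
        truth = PottsModel.zeros(5, 3)
        rng = np.random.default_rng(4)
        truth.h = rng.normal(0, 0.7, size=(5, 3))
        msa = synthetic_msa(truth, 10_000, seed=5)
        cfg = TrainingConfig(
            init="profile", n_chains=300, n_per_chain=10, max_iter=150,
            eps_c_target=5e-3, seed=6,
        )
        result = fit(msa, cfg)
        assert np.abs(result.model.J).max() < 0.1

    def test_fixed_point_keeps_history_and_mask(self, tiny_msa):
        cfg = TrainingConfig(
            init="profile", n_chains=100, n_per_chain=5, adaptive=False,
            max_iter=3, eps_c_target=1e-12, seed=0,
        )
        with pytest.warns(UserWarning, match="max_iter"):
            result = fit(tiny_msa, cfg)
        assert len(result.history) == 3
        assert result.model.gauge_tag == "zero_sum"
        assert not result.converged

    def test_topology_pins_absent_couplings(self, tiny_msa):
        L, q = tiny_msa.length, tiny_msa.alphabet.q
        topo = np.zeros((L, L, q, q), dtype=bool)
        topo[0, 1] = topo[1, 0] = True
        cfg = TrainingConfig(
            init="profile", n_chains=100, n_per_chain=5, adaptive=False,
            max_iter=5, eps_c_target=1e-12, seed=0,
        )
        with pytest.warns(UserWarning):
            result = fit(tiny_msa, cfg, topology=topo)
        raw = result.raw_model
        assert np.all(raw.J[0, 2] == 0) and np.all(raw.J[2, 3] == 0)
        assert raw.J[0, 1].any()

    def test_loglikelihood_nondecreasing_with_exact_marginals(self):
        # convexity: with exact (noise-free) marginals and a small step the
        # log-likelihood of the data never decreases
        planted = random_potts(3, 2, 1.0, coupling_scale=0.8, seed=11)
        msa = synthetic_msa(planted.model, 4000, seed=12)
        stats = apply_pseudocount(empirical_frequencies(msa), 1e-4)
        from pottsdca.potts_core import log_score

        model = PottsModel.zeros(3, 2)
        cfg = TrainingConfig(eta_h=0.1, eta_J=0.1)
        def loglik(m):
            ex = exact_marginals(m)
            return (
                sum(log_score(m, s) for s in msa.data) / msa.n_sequences
                - ex.logZ
            )
        prev = loglik(model)
        for _ in range(30):
            ex = exact_marginals(model)
            p = SiteStatistics(f1=ex.p1, f2=ex.p2, kind="model")
            gradient_update(model, stats, p, cfg)
            cur = loglik(model)
            assert cur >= prev - 1e-12
            prev = cur
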