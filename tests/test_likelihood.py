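"""Trial-likelihood correctness: closed forms, internal consistency,
normalization, grid convergence, and Monte-Carlo agreement."""

import numpy as np
import pandas as pd
import pytest

from wmarc.circular import wrap_signed
from wmarc.likelihood import (
    LikelihoodConfig,
    dataset_loglik,
    trial_loglik,
    trial_logliks,
)
from wmarc.likelihood import _nonlapse_prior_frame, _nonlapse_uniform_prior
from wmarc.observer import (
    ArcGrid,
    ModelSpec,
    ObserverParams,
    log_arc_policy_matrix,
    simulate_responses,
)


def _trial(condition, stimulus, estimate, arc, prior_mean=np.nan):
    return dict(condition=condition, stimulus=stimulus, estimate=estimate,
                arc_size=arc, prior_mean=prior_mean)


class TestClosedForms:
    def test_pure_lapse_uniform_session(self, base_params):
        # lambda = 1: density is (1/360) x lapse arc policy mass / step
        p = base_params.replace(lapse_rate=1.0)
        model = ModelSpec("known", "uniform_only")
        grid = ArcGrid()
        lp = log_arc_policy_matrix(np.array([0.0]), p, grid)[0]
        for arc in (0.0, 45.0, 90.0):
            ll = trial_loglik(_trial("uniform", 10.0, 77.0, arc), p, model)
            expected = np.log(1.0 / 360.0) + lp[int(arc)]
            assert ll == pytest.approx(expected, abs=1e-10)

    def test_pure_lapse_prior_used(self, base_params):
        # NY lapse in a von Mises session: estimate density is the believed
        # prior raised to the estimation exponent
        p = base_params.replace(lapse_rate=1.0)
        model = ModelSpec("known", "NY")
        grid = ArcGrid()
        lp = log_arc_policy_matrix(np.array([p.kappa_w]), p, grid)[0]
        from wmarc.circular import VonMises, vm_pdf
        est_d = vm_pdf(30.0, VonMises(0.0, p.est_exponent * p.kappa_w))
        ll = trial_loglik(_trial("von_mises", 100.0, 130.0, 60.0, prior_mean=100.0),
                          p, model)
        assert ll == pytest.approx(np.log(est_d) + lp[60], abs=1e-10)

    def test_never_minus_inf_with_lapse(self, base_params):
        # a wildly improbable response still has finite log density when
        # lapses are possible
        p = base_params.replace(softmax_temp=0.02, lapse_rate=0.02)
        model = ModelSpec("known", "uniform_only")
        ll = trial_loglik(_trial("uniform", 0.0, 180.0, 180.0), p, model)
        assert np.isfinite(ll)


class TestInternalConsistency:
    @pytest.mark.parametrize("knowledge", ["known", "no_knowledge", "limited",
                                           "fixed_precision"])
    def test_uniform_fast_path_equals_general_path(self, knowledge, base_params):
        model = ModelSpec(knowledge, "uniform_only")
        cfg = LikelihoodConfig()
        de = np.array([-40.0, 0.0, 25.0, 140.0])
        bins = np.array([15, 40, 80, 170])
        fast = _nonlapse_uniform_prior(de, bins, base_params, model, cfg)
        full = _nonlapse_prior_frame(np.zeros(4), de, bins, 0.0,
                                     base_params, model, cfg)
        np.testing.assert_allclose(fast, full, rtol=1e-8)

    def test_dataset_loglik_sums_trials(self, base_params, known_uniform_table):
        model = ModelSpec("known", "uniform_only")
        cfg = LikelihoodConfig.fast()
        sub = known_uniform_table.head(40)
        total = dataset_loglik(sub, base_params, model, cfg)
        loop = sum(trial_loglik(row, base_params, model, cfg)
                   for _, row in sub.iterrows())
        assert total == pytest.approx(loop, abs=1e-9)
        doubled = dataset_loglik(pd.concat([sub, sub]), base_params, model, cfg)
        assert doubled == pytest.approx(2 * total, abs=1e-9)

    def test_empty_table_zero(self, base_params):
        assert dataset_loglik(pd.DataFrame(columns=["condition", "stimulus",
                                                    "estimate", "arc_size"]),
                              base_params, ModelSpec("known", "uniform_only")) == 0.0

    def test_row_order_invariant(self, base_params, yy_joint_table):
        model = ModelSpec("known", "YY")
        cfg = LikelihoodConfig.fast()
        sub = yy_joint_table.head(60)
        shuffled = sub.sample(frac=1.0, random_state=0)
        assert dataset_loglik(sub, base_params, model, cfg) == pytest.approx(
            dataset_loglik(shuffled, base_params, model, cfg), abs=1e-9)

    def test_fixed_precision_is_single_node_case(self, base_params):
        # the fixed-precision model is the kappa-grid-of-one special case
        model = ModelSpec("fixed_precision", "uniform_only")
        tiny = LikelihoodConfig(kappa_grid_size=1)
        big = LikelihoodConfig(kappa_grid_size=50)
        t = _trial("uniform", 0.0, 20.0, 45.0)
        assert trial_loglik(t, base_params, model, tiny) == pytest.approx(
            trial_loglik(t, base_params, model, big), abs=1e-12)


class TestNormalization:
    @pytest.mark.parametrize("knowledge,prior,cond", [
        ("known", "uniform_only", "uniform"),
        ("no_knowledge", "uniform_only", "uniform"),
        ("limited", "uniform_only", "uniform"),
        ("fixed_precision", "uniform_only", "uniform"),
        ("known", "YY", "von_mises"),
        ("known", "NY", "von_mises"),
    ])
    def test_density_integrates_to_one(self, knowledge, prior, cond, base_params):
        model = ModelSpec(knowledge, prior)
        cfg = LikelihoodConfig.fast(memory_grid_size=90)
        est = np.arange(-179.5, 180.5, 1.0) + 50.0
        arcs = np.arange(0.0, 181.0)
        ee, aa = np.meshgrid(est, arcs, indexing="ij")
        tab = pd.DataFrame(dict(condition=cond, stimulus=20.0,
                                estimate=ee.ravel(), arc_size=aa.ravel(),
                                prior_mean=50.0))
        total = np.exp(trial_logliks(tab, base_params, model, cfg)).sum()
        assert total == pytest.approx(1.0, abs=1e-3)


class TestGridConvergence:
    def test_loglik_stable_under_refinement(self, base_params, yy_joint_table):
        # doubling the default quadrature changes the log-likelihood by
        # < 0.1 per 1,000 trials
        model = ModelSpec("known", "YY")
        default = LikelihoodConfig()
        doubled = LikelihoodConfig(kappa_grid_size=200, memory_grid_size=720)
        sub = yy_joint_table[yy_joint_table["participant"] == 1]
        a = dataset_loglik(sub, base_params, model, default)
        b = dataset_loglik(sub, base_params, model, doubled)
        assert abs(a - b) < 0.1 * len(sub) / 1000.0

    def test_fast_preset_bias_is_bounded(self, base_params, yy_joint_table):
        # the reduced-accuracy fitting preset sits within a few millinats per
        # trial of the default quadrature (shared across models in CV, so the
        # common bias cancels in comparisons)
        model = ModelSpec("known", "YY")
        sub = yy_joint_table[yy_joint_table["participant"] == 1]
        a = dataset_loglik(sub, base_params, model, LikelihoodConfig())
        b = dataset_loglik(sub, base_params, model, LikelihoodConfig.fast())
        assert abs(a - b) / len(sub) < 5e-3

    def test_lookup_acceleration_matches_exact(self, base_params, yy_joint_table):
        model = ModelSpec("known", "YY")
        exact = LikelihoodConfig(kappa_grid_size=16, memory_grid_size=120)
        approx = LikelihoodConfig.fast()
        sub = yy_joint_table[yy_joint_table["participant"] == 1]
        a = trial_logliks(sub, base_params, model, exact)
        b = trial_logliks(sub, base_params, model, approx)
        assert np.max(np.abs(a - b)) < 5e-3


class TestTrueKappaWeightingSwitch:
    def test_noop_for_known_model(self, base_params):
        t = _trial("uniform", 0.0, 20.0, 45.0)
        a = trial_loglik(t, base_params, ModelSpec("known", "uniform_only"))
        b = trial_loglik(t, base_params,
                         ModelSpec("known", "uniform_only",
                                   belief_weight_true_kappa=True))
        assert a == pytest.approx(b, abs=1e-12)

    def test_changes_no_knowledge_estimates(self, base_params, rng):
        """With true-kappa weighting the No-Knowledge estimate spread varies
        with encoding precision; the likelihood tracks the simulation."""
        model = ModelSpec("no_knowledge", "uniform_only",
                          belief_weight_true_kappa=True)
        base = ModelSpec("no_knowledge", "uniform_only")
        t = _trial("uniform", 0.0, 5.0, 60.0)
        assert trial_loglik(t, base_params, model) != pytest.approx(
            trial_loglik(t, base_params, base), abs=1e-6)
        est, arc = simulate_responses(np.zeros(300_000), base_params, model,
                                      "uniform", rng)
        d = wrap_signed(est)
        for cell_e, cell_a in [(0.0, 40.0), (30.0, 80.0)]:
            p_hat = np.mean((np.abs(wrap_signed(d - cell_e)) < 0.5)
                            & (arc == cell_a))
            tt = _trial("uniform", 0.0, cell_e, cell_a)
            p_model = np.exp(trial_loglik(tt, base_params, model))
            se = np.sqrt(max(p_hat, 1e-7) * (1 - p_hat) / len(d))
            assert abs(p_model - p_hat) < 3.5 * se


class TestMonteCarloOracle:
    @pytest.mark.parametrize("knowledge,prior,cond", [
        ("known", "uniform_only", "uniform"),
        ("limited", "uniform_only", "uniform"),
        ("known", "YY", "von_mises"),
    ])
    def test_density_matches_simulation(self, knowledge, prior, cond, base_params):
        """exp(trial_loglik) tracks a large simulation histogram cell-by-cell."""
        model = ModelSpec(knowledge, prior)
        rng = np.random.default_rng(17)
        s, pm = 150.0, 100.0
        est, arc = simulate_responses(np.full(400_000, s), base_params, model,
                                      cond, rng, prior_mean=pm)
        d = wrap_signed(est - s)
        z_scores = []
        for cell_e, cell_a in [(0.0, 30.0), (25.0, 60.0), (-45.0, 90.0)]:
            p_hat = np.mean((np.abs(wrap_signed(d - cell_e)) < 0.5)
                            & (arc == cell_a))
            t = _trial(cond, s, s + cell_e, cell_a, prior_mean=pm)
            p_model = np.exp(trial_loglik(t, base_params, model))
            se = np.sqrt(max(p_hat, 1e-7) * (1 - p_hat) / len(d))
            z_scores.append((p_model - p_hat) / se)
        assert np.all(np.abs(z_scores) < 3.5), z_scores
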