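"""Generative observer-model components and trial simulation."""

import numpy as np
import pytest

from wmarc.circular import VonMises, circ_sd_sample, kappa_to_circ_sd, wrap_signed
from wmarc.likelihood import count_free_params, free_param_names
from wmarc.observer import (
    TRUE_PRIOR_KAPPA,
    ArcGrid,
    ModelSpec,
    ObserverParams,
    arc_policy,
    draw_encoding_precision,
    encode,
    expected_utility_curve,
    lapse_branch,
    log_arc_policy_matrix,
    memory_uncertainty,
    points_fn,
    sample_estimate,
    simulate_responses,
    simulate_trial,
)


class TestSpecsAndParams:
    def test_unknown_variants_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("psychic", "YY")
        with pytest.raises(ValueError):
            ModelSpec("known", "ZZ")

    @pytest.mark.parametrize("knowledge,prior,expected", [
        ("known", "uniform_only", 6),
        ("no_knowledge", "uniform_only", 7),
        ("limited", "uniform_only", 8),
        ("fixed_precision", "uniform_only", 5),
        ("known", "YY", 7),
        ("known", "YN", 7),
        ("known", "NY", 7),
        ("known", "NN", 6),
        ("known", "TT", 6),
        ("limited", "YY", 9),   # the family's maximum
    ])
    def test_free_parameter_ledger(self, knowledge, prior, expected):
        model = ModelSpec(knowledge, prior)
        assert count_free_params(model) == expected
        assert len(free_param_names(model)) == expected

    def test_tt_pins_prior_width(self, base_params):
        tt = ModelSpec("known", "TT")
        assert base_params.effective_kappa_w(tt) == TRUE_PRIOR_KAPPA
        yy = ModelSpec("known", "YY")
        assert base_params.effective_kappa_w(yy) == base_params.kappa_w

    def test_validation_catches_bad_values(self):
        model = ModelSpec("known", "uniform_only")
        with pytest.raises(ValueError):
            ObserverParams(gamma_mean=-1.0).validate(model)
        with pytest.raises(ValueError):
            ObserverParams(lapse_rate=1.5).validate(model)
        with pytest.raises(ValueError):
            ObserverParams(softmax_temp=0.0).validate(model)


class TestEncoding:
    def test_fixed_precision_constant(self, rng):
        model = ModelSpec("fixed_precision", "uniform_only")
        p = ObserverParams(kappa_const=5.0)
        draws = draw_encoding_precision(p, model, rng, size=100)
        assert np.all(draws == 5.0)

    def test_gamma_mean_recovered(self, rng):
        model = ModelSpec("known", "uniform_only")
        p = ObserverParams(gamma_mean=8.0, gamma_scale=2.0)
        draws = draw_encoding_precision(p, model, rng, size=100_000)
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 8.0) < 3 * se

    def test_small_scale_degenerates_to_mean(self, rng):
        model = ModelSpec("known", "uniform_only")
        p = ObserverParams(gamma_mean=8.0, gamma_scale=1e-6)
        draws = draw_encoding_precision(p, model, rng, size=1000)
        assert np.all(np.abs(draws - 8.0) < 0.05)

    def test_encode_limits(self, rng):
        assert abs(wrap_signed(encode(40.0, 1e8, rng) - 40.0)) < 0.5
        flat = encode(np.full(20000, 40.0), 0.0, rng)
        # uniform on the circle: mean resultant near zero
        assert circ_sd_sample(flat) > 150.0

    def test_encoding_sd_matches_stimulus_concentration(self, rng):
        draws = encode(np.zeros(100_000), TRUE_PRIOR_KAPPA, rng)
        assert circ_sd_sample(draws) == pytest.approx(60.0, abs=1.0)


class TestMemoryUncertainty:
    def test_variants(self, base_params):
        p = base_params
        assert memory_uncertainty(3.0, p, ModelSpec("known", "uniform_only")) == 3.0
        assert memory_uncertainty(3.0, p, ModelSpec("no_knowledge", "uniform_only")) == p.kappa_fixed
        lim = ModelSpec("limited", "uniform_only")
        assert memory_uncertainty(p.kappa_threshold / 2, p, lim) == 0.0
        assert memory_uncertainty(p.kappa_threshold * 2, p, lim) == p.kappa_fixed
        fx = ModelSpec("fixed_precision", "uniform_only")
        assert memory_uncertainty(3.0, p, fx) == p.kappa_const

    def test_vectorized(self, base_params):
        lim = ModelSpec("limited", "uniform_only")
        kappa = np.array([0.1, 10.0])
        out = memory_uncertainty(kappa, base_params, lim)
        np.testing.assert_allclose(out, [0.0, base_params.kappa_fixed])


class TestRewardAndPolicy:
    @pytest.mark.parametrize("A,expected", [(0.0, 100.0), (180.0, 0.0), (90.0, 50.0)])
    def test_points_linear(self, A, expected):
        assert points_fn(A) == expected

    def test_points_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            points_fn(200.0)

    def test_eu_uniform_closed_form(self):
        # uniform posterior, alpha=1: EU(A) = (A/180) * 100 * (180-A)/180
        grid = ArcGrid()
        eu = expected_utility_curve(VonMises(0, 0.0), 1.0, grid)
        A = grid.values
        np.testing.assert_allclose(eu, (A / 180.0) * 100.0 * (180.0 - A) / 180.0,
                                   rtol=1e-10)
        assert A[np.argmax(eu)] == 90.0
        assert eu[0] == 0.0 and eu[-1] == 0.0

    def test_eu_monte_carlo_oracle(self, rng):
        # EU = hit rate x points for arcs centered on the posterior mean
        posterior = VonMises(0.0, 2.0)
        grid = ArcGrid()
        eu = expected_utility_curve(posterior, 1.0, grid)
        draws = np.rad2deg(rng.vonmises(0.0, 2.0, size=200_000))
        for A in (30.0, 60.0, 120.0):
            hits = np.abs(draws) <= A
            mc = hits.mean() * points_fn(A)
            se = np.std(hits * points_fn(A)) / np.sqrt(len(draws))
            assert abs(eu[int(A)] - mc) < 3 * se

    def test_softmax_properties(self):
        eu = np.array([1.0, 2.0, 3.0])
        p = arc_policy(eu, 1.0)
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(arc_policy(eu + 7.0, 1.0), p, rtol=1e-12)
        flat = arc_policy(np.zeros(5), 1.0)
        np.testing.assert_allclose(flat, 0.2)
        cold = arc_policy(eu, 1e-9)
        assert cold[2] == pytest.approx(1.0)
        hot = arc_policy(eu, 1e9)
        np.testing.assert_allclose(hot, 1 / 3, rtol=1e-6)

    def test_log_policy_matrix_rows_normalized(self, base_params):
        grid = ArcGrid()
        lp = log_arc_policy_matrix(np.array([0.0, 1.0, 10.0, 200.0]),
                                   base_params, grid)
        np.testing.assert_allclose(np.exp(lp).sum(axis=1), 1.0, rtol=1e-10)


class TestSampling:
    def test_estimate_exponent_scales_width(self, rng):
        post = VonMises(10.0, 2.0)
        draws = np.array([sample_estimate(post, 2.0, rng) for _ in range(20000)])
        sd = circ_sd_sample(wrap_signed(draws - 10.0))
        assert sd == pytest.approx(kappa_to_circ_sd(4.0), abs=1.5)

    def test_estimate_infinite_exponent_collapses(self, rng):
        post = VonMises(10.0, 2.0)
        assert sample_estimate(post, 1e8, rng) == pytest.approx(10.0, abs=0.5)

    def test_lapse_branch_uniform(self, base_params):
        est_dist, policy = lapse_branch(ModelSpec("known", "NN"), base_params,
                                        "von_mises", prior_mean=50.0)
        assert est_dist.kappa == 0.0
        assert policy.sum() == pytest.approx(1.0)

    def test_lapse_branch_prior_used(self, base_params):
        est_dist, _ = lapse_branch(ModelSpec("known", "NY"), base_params,
                                   "von_mises", prior_mean=50.0)
        assert est_dist.kappa == base_params.kappa_w
        assert est_dist.mu == pytest.approx(50.0)

    def test_uniform_lapse_policy_peaks_near_90(self, base_params):
        # argmax of the uniform-EU closed form at alpha=1 is A=90; a small
        # temperature concentrates the policy there
        p = base_params.replace(softmax_temp=0.1)
        _, policy = lapse_branch(ModelSpec("known", "uniform_only"), p, "uniform")
        grid = ArcGrid()
        assert abs(grid.values[np.argmax(policy)] - 90.0) <= 2.0


class TestSimulateTrial:
    def test_full_lapse_matches_lapse_branch(self, base_params, rng):
        model = ModelSpec("known", "uniform_only")
        p = base_params.replace(lapse_rate=1.0)
        est, arc = simulate_trial(40.0, p, model, "uniform", rng)
        assert -180.0 < est <= 180.0 and 0.0 <= arc <= 180.0
        # estimates uniform: KS against uniform over many draws
        ests = np.array([simulate_trial(40.0, p, model, "uniform", rng)[0]
                         for _ in range(2000)])
        from scipy import stats as sps
        pval = sps.kstest((ests + 180.0) / 360.0, "uniform").pvalue
        assert pval > 1e-4

    def test_noiseless_limit(self, rng):
        model = ModelSpec("known", "uniform_only")
        p = ObserverParams(gamma_mean=5000.0, gamma_scale=0.01, est_exponent=5.0,
                           softmax_temp=0.01, risk_alpha=1.0, lapse_rate=0.0)
        est, arc = zip(*(simulate_trial(40.0, p, model, "uniform", rng)
                         for _ in range(50)))
        errs = np.abs(wrap_signed(np.array(est) - 40.0))
        assert np.max(errs) < 3.0
        assert np.max(arc) <= 10.0

    def test_error_arc_correlation_sign(self, base_params, rng):
        # dispersed precision induces a positive error-arc correlation under
        # Known; constant precision with no lapses gives none
        from scipy import stats as sps
        s = np.zeros(4000)
        dispersed = base_params.replace(lapse_rate=0.0, gamma_scale=4.0)
        est, arc = simulate_responses(s, dispersed,
                                      ModelSpec("known", "uniform_only"),
                                      "uniform", rng)
        r_known = sps.spearmanr(np.abs(wrap_signed(est)), arc).statistic
        p_fix = base_params.replace(lapse_rate=0.0)
        est, arc = simulate_responses(s, p_fix,
                                      ModelSpec("fixed_precision", "uniform_only"),
                                      "uniform", rng)
        r_fixed = sps.spearmanr(np.abs(wrap_signed(est)), arc).statistic
        assert r_known > 0.15
        assert abs(r_fixed) < 0.08

    def test_tt_equals_yy_with_pinned_width(self, base_params):
        p = base_params.replace(kappa_w=TRUE_PRIOR_KAPPA)
        s = np.linspace(0, 359, 500)
        out_tt = simulate_responses(
            s, p, ModelSpec("known", "TT"), "von_mises",
            np.random.default_rng(7), prior_mean=100.0)
        out_yy = simulate_responses(
            s, p, ModelSpec("known", "YY"), "von_mises",
            np.random.default_rng(7), prior_mean=100.0)
        np.testing.assert_array_equal(out_tt[0], out_yy[0])
        np.testing.assert_array_equal(out_tt[1], out_yy[1])

    def test_yy_shift_increases_with_arc_nn_flat(self, base_params, rng):
        # prior attraction scales with reported uncertainty under YY;
        # absent under NN
        from wmarc.circular import wrap_signed as ws
        s = np.full(6000, 60.0)  # 60 deg clockwise of the prior mean
        pm = 0.0
        p = base_params.replace(gamma_mean=4.0, lapse_rate=0.0)
        est_yy, _ = simulate_responses(s, p, ModelSpec("known", "YY"),
                                       "von_mises", rng, prior_mean=pm)
        shift_yy = np.mean(ws(est_yy - 60.0) * -np.sign(ws(60.0 - pm)))
        est_nn, _ = simulate_responses(s, p, ModelSpec("known", "NN"),
                                       "von_mises", rng, prior_mean=pm)
        shift_nn = np.mean(ws(est_nn - 60.0) * -np.sign(ws(60.0 - pm)))
        assert shift_yy > 3.0
        assert abs(shift_nn) < 2.0


class TestArcGrid:
    def test_default_grid(self):
        g = ArcGrid()
        assert g.n == 181 and g.values[0] == 0.0 and g.values[-1] == 180.0

    def test_bin_index_rounds(self):
        g = ArcGrid()
        assert g.bin_index(37.4) == 37
        assert g.bin_index(180.0) == 180

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            ArcGrid.with_step(7.0)
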