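import numpy as np
import pytest

import rrtvar as rv
from rrtvar._core import GRatioConstants, T1DConstants, dp_decoder, np_decoder
from rrtvar.theory import (
    class_bias,
    class_callable,
    class_mse,
    core_callable,
    delta_method_mse,
    gratio_callable,
    min_mse_t1d_theory,
    min_mse_t1n_theory,
    min_mse_tgratio_theory,
    mse_t0_theory,
    mse_tratio_theory,
    optimum_class_constants,
    optimum_gratio_psi,
    ratio_callable,
    tnp1_theory,
    tnp2_theory,
    dp_theory_terms,
    np_theory_terms,
)

N = 500
RTOL = 1e-6


class TestOracleAgreement:
    """Every closed form must match the generic delta-method MSE."""

    def test_t0(self, dp_moments, dp_params):
        dec = dp_decoder(dp_params)
        assert mse_t0_theory(dp_moments, dp_params, N) == pytest.approx(
            delta_method_mse(core_callable(dec), dp_moments, N), rel=RTOL)

    def test_ratio(self, dp_moments, dp_params):
        dec = dp_decoder(dp_params)
        assert mse_tratio_theory(dp_moments, dp_params, N) == pytest.approx(
            delta_method_mse(ratio_callable(dec, dp_moments.var_x1),
                             dp_moments, N), rel=RTOL)

    def test_gratio_at_optimum(self, dp_moments, dp_params):
        dec = dp_decoder(dp_params)
        psi = optimum_gratio_psi(dp_moments, dec, N)
        t_star = dec.census_value(dp_moments.var_z, dp_moments.mean_z)
        c = GRatioConstants(omega=(psi - dp_moments.var_x1) / t_star)
        assert min_mse_tgratio_theory(dp_moments, dp_params, N) == pytest.approx(
            delta_method_mse(gratio_callable(dec, dp_moments.var_x1, c),
                             dp_moments, N), rel=RTOL)

    @pytest.mark.parametrize("k", [(1.0, 0.0, 0.0), (0.9, 0.5, -0.3)])
    @pytest.mark.parametrize("lam", [(0.0, 0.0), (1.0, 1.0), (2.0, -0.5)])
    def test_class_arbitrary_constants(self, dp_moments, dp_params, k, lam):
        dec = dp_decoder(dp_params)
        closed = class_mse(dp_moments, dec, *k, *lam, N)
        oracle = delta_method_mse(
            class_callable(dec, dp_moments.var_x1, dp_moments.var_x2, *k, *lam),
            dp_moments, N)
        assert closed == pytest.approx(oracle, rel=RTOL)

    @pytest.mark.parametrize("mode", ["consistent", "paper"])
    def test_np_estimators(self, pop1, mode):
        params = rv.NPModelParams(g=0.5, a=1.0, var_r=0.5, var_s=0.5, mode=mode)
        z = rv.scramble_proposed(pop1.y_values, params, seed=12)
        mom = rv.compute_population_moments(pop1, z)
        dec = np_decoder(params)
        assert tnp1_theory(mom, params, N)[1] == pytest.approx(
            delta_method_mse(core_callable(dec), mom, N), rel=RTOL)
        assert tnp2_theory(mom, params, N)[1] == pytest.approx(
            delta_method_mse(ratio_callable(dec, mom.var_x1), mom, N), rel=RTOL)
        (w1, w2, w3), _ = optimum_class_constants(mom, dec, 1.0, 1.0, N)
        assert class_mse(mom, dec, w1, w2, w3, 1.0, 1.0, N) == pytest.approx(
            delta_method_mse(class_callable(dec, mom.var_x1, mom.var_x2,
                                            w1, w2, w3, 1.0, 1.0), mom, N),
            rel=RTOL)


class TestClosedFormStructure:
    def test_t0_no_scrambling_limit(self, pop1):
        params = rv.DPModelParams(var_s=0.0, var_t=0.0)
        mom = rv.compute_population_moments(pop1, pop1.y_values)
        theta = 1.0 / N
        expected = theta * mom.var_z ** 2 * (mom.mu[(4, 0, 0)] - 1.0)
        assert mse_t0_theory(mom, params, N) == pytest.approx(expected, rel=1e-12)

    def test_gratio_never_worse_than_t0(self, dp_moments, dp_params):
        assert min_mse_tgratio_theory(dp_moments, dp_params, N) <= \
            mse_t0_theory(dp_moments, dp_params, N) + 1e-12

    def test_gratio_uncorrelated_auxiliary(self):
        # independent X1: mu220 ~ 1, mu120 ~ 0 => no ratio gain
        pop = rv.generate_population(np.diag([10.0, 2.0, 2.0]), (3, 3, 3),
                                     100_000, seed=55)
        params = rv.DPModelParams(var_s=0.5, var_t=0.5)
        z = rv.scramble_dp(pop.y_values, params, seed=56)
        mom = rv.compute_population_moments(pop, z)
        t0 = mse_t0_theory(mom, params, N)
        assert min_mse_tgratio_theory(mom, params, N) == pytest.approx(t0, rel=0.01)

    def test_t1d_reduces_to_t0(self, dp_moments, dp_params):
        c = T1DConstants(1.0, 0.0, 0.0, 0.0, 0.0)
        _, mse, _ = rv.t1d_theory(dp_moments, dp_params, c, N)
        assert mse == pytest.approx(mse_t0_theory(dp_moments, dp_params, N),
                                    rel=1e-12)

    def test_tnp1_g1_limits(self, pop1):
        params = rv.NPModelParams(g=1.0, a=1.0, var_r=0.5, var_s=0.5)
        z = rv.scramble_proposed(pop1.y_values, params, seed=14)
        mom = rv.compute_population_moments(pop1, z)
        bias, mse = tnp1_theory(mom, params, N)
        assert bias == 0.0
        theta = 1.0 / N
        core = theta * mom.var_z ** 2 * (mom.mu[(4, 0, 0)] - 1.0)
        resid = (mom.var_z - params.a ** 2 * params.var_s - mom.var_y) ** 2
        assert mse == pytest.approx(core + resid, rel=1e-12)

    def test_t1n_reduces_to_tnp1(self, np_moments, np_params):
        from rrtvar._core import T1NConstants
        c = T1NConstants(1.0, 0.0, 0.0, 0.0, 0.0)
        _, mse, _ = rv.t1n_theory(np_moments, np_params, c, N)
        assert mse == pytest.approx(tnp1_theory(np_moments, np_params, N)[1],
                                    rel=1e-12)

    def test_min_mse_dominates_subclass(self, dp_moments, dp_params):
        dec = dp_decoder(dp_params)
        mn = min_mse_t1d_theory(dp_moments, dp_params, 1.0, 1.0, N)
        assert mn <= mse_t0_theory(dp_moments, dp_params, N) + 1e-12
        assert mn <= mse_tratio_theory(dp_moments, dp_params, N) + 1e-12
        assert mn <= min_mse_tgratio_theory(dp_moments, dp_params, N) + 1e-12

    def test_min_mse_lambda_invariant(self, dp_moments, dp_params):
        # the auxiliary constants absorb the generalization exponents, so
        # the fully optimized MSE does not depend on (lambda1, lambda2)
        a = min_mse_t1d_theory(dp_moments, dp_params, 0.0, 0.0, N)
        b = min_mse_t1d_theory(dp_moments, dp_params, 2.0, -1.0, N)
        assert a == pytest.approx(b, rel=1e-9)

    def test_strict_paper_variants_differ(self, dp_moments, dp_params):
        assert mse_t0_theory(dp_moments, dp_params, N, strict_paper=True) != \
            pytest.approx(mse_t0_theory(dp_moments, dp_params, N), rel=1e-3)
        assert min_mse_t1d_theory(dp_moments, dp_params, 1.0, 1.0, N,
                                  strict_paper=True) != \
            pytest.approx(min_mse_t1d_theory(dp_moments, dp_params, 1.0, 1.0, N),
                          rel=1e-3)

    def test_terms_invariants(self, dp_moments, dp_params, np_moments, np_params):
        terms = dp_theory_terms(dp_moments, dp_params, 1.0, 1.0, N)
        m = dp_moments.mu
        assert terms.a6 == pytest.approx(
            (m[(0, 4, 0)] - 1) * (m[(0, 0, 4)] - 1) - (m[(0, 2, 2)] - 1) ** 2)
        assert terms.a6 > 0
        assert terms.a7 > 0
        nterms = np_theory_terms(np_moments, np_params, 1.0, 1.0, N)
        assert nterms.b5 != 0 and nterms.b7 != 0


class TestDeltaMethodOracle:
    def test_identity_estimator(self, dp_moments):
        est = lambda sz, s1, s2, zb: sz
        theta = 1.0 / N
        expected = (dp_moments.var_z - dp_moments.var_y) ** 2 \
            + theta * dp_moments.var_z ** 2 * (dp_moments.mu[(4, 0, 0)] - 1.0)
        assert delta_method_mse(est, dp_moments, N) == pytest.approx(expected,
                                                                     rel=1e-9)

    def test_constant_estimator(self, dp_moments):
        est = lambda sz, s1, s2, zb: 4.2
        expected = (4.2 - dp_moments.var_y) ** 2
        assert delta_method_mse(est, dp_moments, N) == pytest.approx(expected)


class TestNPDecodingConsistency:
    def test_census_gap_closed_form(self):
        # decoding with the printed denominator on literally-simulated data
        # leaves a census bias of 2 g (1-g) sigma_W^2 / G
        g, a, var_r, var_s = 0.5, 1.0, 0.5, 0.5
        mean_y, var_y = 3.0, 10.0
        consistent = rv.NPModelParams(g=g, a=a, var_r=var_r, var_s=var_s,
                                      mode="consistent")
        paper = rv.NPModelParams(g=g, a=a, var_r=var_r, var_s=var_s, mode="paper")
        true_var_z = np_decoder(consistent).encode_variance(var_y, mean_y)
        gap = np_decoder(paper).census_value(true_var_z, mean_y) - var_y
        sigma_w2 = var_y + a ** 2 * var_s
        assert gap == pytest.approx(2 * g * (1 - g) * sigma_w2 / paper.G, rel=1e-12)

    def test_census_gap_monte_carlo(self):
        g, a, var_r, var_s = 0.5, 1.0, 0.5, 0.5
        rng = np.random.default_rng(60)
        y = rng.normal(3.0, np.sqrt(10.0), 2_000_000)
        params = rv.NPModelParams(g=g, a=a, var_r=var_r, var_s=var_s, mode="paper")
        z = rv.scramble_proposed(y, params, seed=61)
        decoded = np_decoder(params).census_value(np.var(z, ddof=1), z.mean())
        sigma_w2 = np.var(y, ddof=1) + a ** 2 * var_s
        expected_gap = 2 * g * (1 - g) * sigma_w2 / params.G
        assert decoded - np.var(y, ddof=1) == pytest.approx(expected_gap, rel=0.05)


class TestEfficiencyCompare:
    def test_dp_table(self, dp_moments2, dp_params):
        df = rv.efficiency_compare(dp_moments2, dp_params, N,
                                   ["ratio", "gratio", "t1D", "t1D(3)"])
        row = df.set_index("tag")
        assert row.loc["t1D", "better_than_baseline"]
        assert row.loc["gratio", "better_than_baseline"]
        # population II has rho > 1/sqrt(2): the plain ratio helps too
        assert row.loc["ratio", "better_than_baseline"]

    def test_reduction_member_has_zero_difference(self, dp_moments, dp_params):
        dec = dp_decoder(dp_params)
        mse = class_mse(dp_moments, dec, 1.0, 0.0, 0.0, 0.0, 0.0, N)
        assert mse - mse_t0_theory(dp_moments, dp_params, N) == pytest.approx(0.0,
                                                                              abs=1e-12)

    def test_np_table(self, np_moments, np_params):
        df = rv.efficiency_compare(np_moments, np_params, N, ["tNP2", "t1N"])
        row = df.set_index("tag")
        assert row.loc["t1N", "better_than_baseline"]

    def test_sign_matches_monte_carlo(self, pop2):
        # theory-predicted ordering signs agree with the MC-estimated ones
        cfg = rv.SimulationConfig(cov=rv.POPULATION_II_COV, model="dp",
                                  sample_sizes=(500,), var_s_values=(0.2,),
                                  replications=8000, seed=42)
        res = {r.estimator: r for r in rv.run_monte_carlo(cfg, population=pop2)}
        for tag in ("ratio", "gratio", "t1D"):
            theory_sign = res[tag].theory_mse < res["t0"].theory_mse
            mc_sign = res[tag].empirical_mse < res["t0"].empirical_mse
            assert theory_sign == mc_sign


class TestBias:
    def test_t1d_bias_matches_monte_carlo(self, pop1):
        params = rv.DPModelParams(var_s=0.2, var_t=0.5)
        n = 200
        z = rv.scramble_dp(pop1.y_values, params, seed=3)
        mom = rv.compute_population_moments(pop1, z)
        dec = dp_decoder(params)
        (k1, k2, k3), _ = optimum_class_constants(mom, dec, 1.0, 1.0, n)
        predicted = class_bias(mom, dec, k1, k2, k3, 1.0, 1.0, n)
        cfg = rv.SimulationConfig(model="dp", sample_sizes=(n,),
                                  var_s_values=(0.2,), replications=40_000,
                                  seed=9, estimators=("t1D",))
        r = rv.run_monte_carlo(cfg, population=pop1)[0]
        se = np.sqrt(r.empirical_mse / cfg.replications)
        assert abs((r.mean_estimate - pop1.var_y) - predicted) < 4 * se

    def test_tnp1_bias_sign(self, np_moments, np_params):
        bias, _ = tnp1_theory(np_moments, np_params, N)
        assert bias < 0  # the zbar^2 plug-in always over-subtracts
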