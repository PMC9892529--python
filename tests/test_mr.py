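import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lipomr.mr import (
    bh_fdr,
    bidirectional_mr,
    egger_regression,
    iterative_pleiotropy_prune,
    ivw_estimate,
    modified_cochran_q,
    multivariable_adjusted_mr,
    per_variant_ratios,
    wald_ratio_fieller,
    wald_from_summary,
)
from lipomr.twas import CollinearityError


class TestFiellerWald:
    def test_point_estimate_is_ratio(self):
        est = wald_ratio_fieller(0.2, 0.05, 0.4, 0.05)
        assert est.wald_beta == pytest.approx(0.5)

    def test_zero_numerator_interval_straddles_zero(self):
        est = wald_ratio_fieller(0.0, 0.05, 0.4, 0.02)
        assert est.wald_beta == 0.0
        assert est.fieller_low < 0 < est.fieller_high

    def test_weak_instrument_flagged_unbounded(self):
        est = wald_ratio_fieller(0.1, 0.05, 0.01, 0.05)
        assert est.weak_instrument
        assert est.fieller_low == -np.inf and est.fieller_high == np.inf

    def test_agrees_with_delta_method_for_strong_instrument(self):
        # at F >> 100 the Fieller and delta-method widths converge
        est = wald_ratio_fieller(0.3, 0.01, 0.5, 0.01)
        delta_se = np.sqrt(0.01 ** 2 / 0.5 ** 2
                           + 0.3 ** 2 * 0.01 ** 2 / 0.5 ** 4)
        assert est.robust_se == pytest.approx(delta_se, rel=0.05)

    @given(by=st.floats(-0.5, 0.5), bx=st.floats(0.2, 1.0))
    @settings(max_examples=60, derandomize=True)
    def test_bounded_interval_contains_point_estimate(self, by, bx):
        est = wald_ratio_fieller(by, 0.05, bx, 0.02)
        if not est.weak_instrument:
            assert est.fieller_low <= est.wald_beta <= est.fieller_high

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio_fieller(0.1, 0.05, 0.0, 0.05)


class TestPerVariantRatios:
    def test_identity_ratios(self):
        g = np.array([0.2, 0.5, 0.9])
        out = per_variant_ratios(g, g * 0 + 0.01, g, g * 0 + 0.01)
        np.testing.assert_allclose(out["beta"], 1.0)

    def test_delta_method_arithmetic(self):
        out = per_variant_ratios([0.6], [0.05], [0.3], [0.05])
        assert out["beta"][0] == pytest.approx(0.5)
        var = 0.05 ** 2 / 0.36 + 0.09 * 0.05 ** 2 / 0.6 ** 4
        assert var == pytest.approx(0.00868, abs=2e-5)
        assert out["se"][0] == pytest.approx(np.sqrt(var), abs=1e-10)
        assert out["se"][0] == pytest.approx(0.0932, abs=5e-4)

    def test_variance_matches_parametric_bootstrap(self):
        rng = np.random.default_rng(9)
        n = 1_000_000
        g = rng.normal(0.6, 0.05, n)
        G = rng.normal(0.3, 0.05, n)
        emp = np.var(G / g)
        out = per_variant_ratios([0.6], [0.05], [0.3], [0.05])
        assert out["se"][0] ** 2 == pytest.approx(emp, rel=0.03)

    def test_zero_gamma_raises(self):
        with pytest.raises(ZeroDivisionError):
            per_variant_ratios([0.0], [0.1], [0.1], [0.1])


class TestIVW:
    def test_single_variant_is_its_ratio(self):
        import pandas as pd
        r = pd.DataFrame({"beta": [0.42], "se": [0.1]})
        assert ivw_estimate(r)[0] == pytest.approx(0.42)

    def test_equal_variances_arithmetic_mean(self):
        import pandas as pd
        r = pd.DataFrame({"beta": [0.1, 0.5], "se": [0.2, 0.2]})
        assert ivw_estimate(r)[0] == pytest.approx(0.3)

    def test_matches_weighted_mean_oracle(self, rng):
        import pandas as pd
        b = rng.normal(size=10)
        s = rng.uniform(0.05, 0.3, 10)
        beta, se = ivw_estimate(pd.DataFrame({"beta": b, "se": s}))
        w = 1 / s ** 2
        assert beta == pytest.approx(np.sum(w * b) / np.sum(w), abs=1e-12)
        assert se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)


class TestModifiedQ:
    def test_all_ratios_equal_gives_zero(self):
        g = np.array([0.2, 0.4, 0.8, 0.3])
        rep = modified_cochran_q(g, g * 0 + 0.01, 0.5 * g, g * 0 + 0.01)
        assert rep.Q == pytest.approx(0.0, abs=1e-12)
        assert rep.p_Q == pytest.approx(1.0)
        assert rep.df == 3

    def test_q_equals_sum_of_contributions(self, rng):
        g = rng.uniform(0.1, 0.5, 15)
        rep = modified_cochran_q(g, g * 0 + 0.02,
                                 0.3 * g + rng.normal(0, 0.02, 15),
                                 g * 0 + 0.02)
        assert rep.Q == pytest.approx(rep.q_contributions.sum(), abs=1e-8)
        assert rep.Q >= 0

    def test_planted_outlier_gets_largest_contribution(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(100):
            g = rng.uniform(0.05, 0.15, 20)
            se_g = np.full(20, 0.01)
            se_G = np.full(20, 0.01)
            G = 0.3 * g + rng.normal(0, se_G)
            G[7] += 0.5 * g[7]  # direct effect on one instrument variant
            rep = modified_cochran_q(rng.normal(g, se_g), se_g, G, se_G)
            hits += int(np.argmax(rep.q_contributions)) == 7
        assert hits >= 95


class TestIterativePrune:
    def _null_draw(self, rng, J=20):
        g = rng.uniform(0.05, 0.15, J)
        se_g = np.full(J, 0.005)
        se_G = np.full(J, 0.01)
        return rng.normal(g, se_g), se_g, 0.3 * g + rng.normal(0, se_G), se_G

    def test_null_mostly_removes_nothing(self):
        rng = np.random.default_rng(17)
        empty = 0
        for _ in range(100):
            kept, rep = iterative_pleiotropy_prune(*self._null_draw(rng))
            empty += len(rep.removed_variants) == 0
        assert empty >= 90

    def test_threshold_one_prunes_to_two_variants(self, rng):
        g, se_g, G, se_G = self._null_draw(rng)
        kept, rep = iterative_pleiotropy_prune(g, se_g, G, se_G,
                                               threshold_p=1.0)
        assert len(kept) == 2
        assert len(rep.removed_variants) == 18

    def test_fewer_than_three_variants_rejected(self):
        with pytest.raises(ValueError):
            iterative_pleiotropy_prune([0.1, 0.2], [0.01, 0.01],
                                       [0.1, 0.2], [0.01, 0.01])


class TestEgger:
    def test_exact_proportionality_zero_intercept(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger_regression(g, 0.7 * g, np.full(4, 0.05))
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope == pytest.approx(0.7, abs=1e-12)

    def test_directional_pleiotropy_detected(self):
        rng = np.random.default_rng(19)
        detected, intercepts = 0, []
        for _ in range(100):
            g = rng.uniform(0.05, 0.3, 40)
            se_G = np.full(40, 0.01)
            G = 0.3 * g + 0.1 + rng.normal(0, se_G)
            res = egger_regression(g, G, se_G)
            intercepts.append(res.intercept)
            detected += res.intercept_p < 0.05
        assert detected >= 80
        assert np.mean(intercepts) == pytest.approx(0.1, abs=0.01)

    def test_needs_three_variants(self):
        with pytest.raises(ValueError):
            egger_regression([0.1, 0.2], [0.1, 0.2], [0.05, 0.05])


def _slope_se(y, x):
    n = y.size
    xc = x - x.mean()
    b = xc @ (y - y.mean()) / (xc @ xc)
    resid = y - y.mean() - b * xc
    se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
    return b, se


class TestMultivariable:
    def _one_sample(self, rng, n=2000, direct=0.0):
        dos = rng.binomial(2, 0.3, n).astype(float)
        giv = 0.5 * dos + rng.normal(0, 1, n)
        giv = (giv - giv.mean()) / giv.std()
        lipid = 0.22 * giv + rng.normal(0, 1, n)
        expr = 0.4 * lipid + direct * dos + rng.normal(0, 1, n)
        return lipid, expr, giv, dos

    def test_independent_covariate_leaves_estimate(self, rng):
        lipid, expr, giv, _ = self._one_sample(rng)
        indep = rng.normal(size=lipid.size)
        adj = multivariable_adjusted_mr(lipid, expr, giv, indep)
        unadj = wald_ratio_fieller(*_slope_se(expr, giv), *_slope_se(lipid, giv))
        assert abs(adj.wald_beta - unadj.wald_beta) < 1 * adj.robust_se

    def test_adjusting_for_cis_variant_removes_direct_pleiotropy(self):
        rng = np.random.default_rng(23)
        closer = 0
        for _ in range(60):
            lipid, expr, giv, dos = self._one_sample(rng, direct=0.3)
            unadj = wald_ratio_fieller(*_slope_se(expr, giv),
                                       *_slope_se(lipid, giv))
            adj = multivariable_adjusted_mr(lipid, expr, giv, dos)
            closer += abs(adj.wald_beta - 0.4) < abs(unadj.wald_beta - 0.4)
        assert closer >= 54  # >= 90%

    def test_collinear_covariate_rejected(self, rng):
        lipid, expr, giv, _ = self._one_sample(rng)
        with pytest.raises(CollinearityError):
            multivariable_adjusted_mr(lipid, expr, giv, giv * 2.0)


class TestBidirectional:
    def test_recovers_reverse_effect(self):
        rng = np.random.default_rng(29)
        n = 4000
        dos = rng.binomial(2, 0.3, n).astype(float)
        expr = 0.5 * dos + rng.normal(0, 1, n)
        lipid = 0.3 * expr + rng.normal(0, 1, n)
        est = bidirectional_mr(expr, lipid, dos)
        assert est.method == "reverse"
        assert abs(est.wald_beta - 0.3) < 3 * est.robust_se

    def test_unrelated_variant_raises_or_is_weak(self, rng):
        n = 500
        dos = np.zeros(n)
        dos[0] = 1e-9  # essentially no variation -> no eQTL effect
        expr = rng.normal(size=n)
        lipid = rng.normal(size=n)
        est = bidirectional_mr(expr, lipid, dos + rng.binomial(2, 0.3, n))
        assert est.weak_instrument or est.p > 0.001


class TestTwoSample:
    def test_zero_outcome_beta_zero_estimate(self):
        est = wald_from_summary(0.5, 0.05, 0.0, 0.02)
        assert est.wald_beta == 0.0

    def test_delta_se_matches_bootstrap(self):
        est = wald_from_summary(0.5, 0.05, 0.2, 0.02)
        assert est.wald_beta == pytest.approx(0.4)
        rng = np.random.default_rng(31)
        boot = rng.normal(0.2, 0.02, 500_000) / rng.normal(0.5, 0.05, 500_000)
        delta_se = np.sqrt(0.02 ** 2 / 0.25 + 0.04 * 0.05 ** 2 / 0.0625)
        assert est.robust_se == pytest.approx(delta_se, rel=0.05)
        assert delta_se == pytest.approx(np.std(boot), rel=0.03)

    def test_flipping_both_alleles_is_identity(self):
        a = wald_from_summary(0.5, 0.05, 0.2, 0.02,
                              eqtl_alleles=("A", "G"),
                              outcome_alleles=("A", "G"))
        b = wald_from_summary(0.5, 0.05, -0.2, 0.02,
                              eqtl_alleles=("A", "G"),
                              outcome_alleles=("G", "A"))
        assert a.wald_beta == pytest.approx(b.wald_beta)

    def test_incompatible_alleles_raise(self):
        with pytest.raises(ValueError):
            wald_from_summary(0.5, 0.05, 0.2, 0.02,
                              eqtl_alleles=("A", "G"),
                              outcome_alleles=("A", "C"))


class TestBH:
    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        adj, _ = bh_fdr([0.02] * 5)
        np.testing.assert_allclose(adj, 0.02)

    def test_step_up_arithmetic(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5])
        assert rej.tolist() == [True, True, True, False]

    def test_matches_manual_step_up(self, rng):
        p = rng.uniform(size=40)
        adj, _ = bh_fdr(p)
        # manual step-up oracle
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        manual = np.minimum.accumulate(stepped[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(manual, 1)
        np.testing.assert_allclose(adj, out, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
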