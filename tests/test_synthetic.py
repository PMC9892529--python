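import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipomr.preprocess import inverse_normal_transform
from lipomr.synthetic import (
    SimulationConfig,
    plant_pleiotropy,
    simulate_outcome_summary_stats,
    simulate_study,
)


def _int_expr(counts_row, lib):
    return inverse_normal_transform(np.log((counts_row + 0.5) / lib))


class TestSimulateStudy:
    def test_identical_seed_bitwise_identical(self):
        cfg = SimulationConfig(cohorts=("LL",), samples_per_cohort=(100,),
                               n_genes=30)
        a = simulate_study(cfg, seed=5)
        b = simulate_study(cfg, seed=5)
        for ca, cb in zip(a.cohorts, b.cohorts):
            pd.testing.assert_frame_equal(ca.counts, cb.counts)
            pd.testing.assert_frame_equal(ca.dosages, cb.dosages)
            pd.testing.assert_frame_equal(ca.lipids, cb.lipids)
        pd.testing.assert_frame_equal(a.summary_stats, b.summary_stats)

    def test_allele_frequency_matches_maf(self):
        cfg = SimulationConfig(cohorts=("LL",), samples_per_cohort=(10_000,),
                               mafs=0.3, n_variants=10, n_genes=5, n_causal=0)
        study = simulate_study(cfg, seed=6)
        freq = study.cohorts[0].dosages.iloc[:, :10].to_numpy().mean() / 2
        assert freq == pytest.approx(0.3, abs=0.01)

    def test_cell_percentages_sum_to_100(self, small_study):
        from lipomr.synthetic import CELL_COLUMNS
        for c in small_study.cohorts:
            s = c.covariates[CELL_COLUMNS].sum(axis=1)
            np.testing.assert_allclose(s, 100.0, atol=1e-9)

    def test_null_config_gene_pvalues_uniform(self):
        """With every effect zeroed the expression-lipid scan is null."""
        cfg = SimulationConfig(
            cohorts=("LL",), samples_per_cohort=(800,), n_genes=5000,
            n_causal=0, confounder_lipid=0.0, confounder_gene_sd=0.0,
            hidden_loading_sd=0.0, cell_loading_sd=0.0,
        )
        study = simulate_study(cfg, seed=7)
        c = study.cohorts[0]
        lipid = inverse_normal_transform(c.lipids["TG"].to_numpy(float))
        lib = c.counts.sum(axis=0).to_numpy(float)
        E = np.log((c.counts.to_numpy(float) + 0.5) / lib)
        E = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
        lip = (lipid - lipid.mean()) / lipid.std()
        r = E @ lip / len(lip)
        z = r * np.sqrt(len(lip))
        p = 2 * stats.norm.sf(np.abs(z))
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_causal_beta_recovered_by_ols(self):
        gene = "GENE00003"
        cfg = SimulationConfig(cohorts=("LL",), samples_per_cohort=(2000,),
                               n_genes=50, causal_genes={gene: 0.3},
                               confounder_lipid=0.0, confounder_gene_sd=0.0)
        study = simulate_study(cfg, seed=8)
        c = study.cohorts[0]
        lib = c.counts.sum(axis=0).to_numpy(float)
        y = _int_expr(c.counts.loc[gene].to_numpy(float), lib)
        x = inverse_normal_transform(c.lipids["TG"].to_numpy(float))
        b, res = np.polyfit(x, y, 1, cov=False), None
        slope = b[0]
        se = np.sqrt((1 - np.corrcoef(x, y)[0, 1] ** 2) / (2000 - 2))
        assert abs(slope - 0.3) < 3 * se

    def test_discovery_weights_near_truth(self):
        study = simulate_study(SimulationConfig(n_genes=5, n_causal=0), seed=9)
        ss = study.summary_stats
        truth = study.truth.variant_effects_on_lipid
        z = (ss["beta"] - ss["id"].map(truth)) / ss["se"]
        assert np.all(np.abs(z) < 4.5)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            SimulationConfig(mafs=0.7).validate()
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_genes=0).validate()
        with pytest.raises(ValueError, match="sum below 1"):
            SimulationConfig(instrument_r2=0.8,
                             confounder_lipid=0.6).validate()

    def test_lipid_correlations_near_targets(self):
        cfg = SimulationConfig(cohorts=("LL",), samples_per_cohort=(20_000,),
                               n_genes=5, n_causal=0)
        c = simulate_study(cfg, seed=10).cohorts[0]
        corr = c.lipids[["TG", "HDL", "LDL"]].corr()
        assert corr.loc["TG", "HDL"] == pytest.approx(-0.48, abs=0.04)
        assert corr.loc["TG", "LDL"] == pytest.approx(0.45, abs=0.04)

    def test_friedewald_consistency_of_tc(self, small_study):
        lip = small_study.cohorts[0].lipids
        np.testing.assert_allclose(
            lip["TC"], lip["LDL"] + lip["HDL"] + lip["TG"] / 2.2, atol=1e-9)


class TestPlantPleiotropy:
    def _study(self, seed=12):
        cfg = SimulationConfig(cohorts=("LL",), samples_per_cohort=(300,),
                               n_genes=20, n_causal=0)
        return simulate_study(cfg, seed=seed)

    def test_zero_effect_counts_unchanged(self):
        a = self._study()
        before = a.cohorts[0].counts.copy()
        plant_pleiotropy(a, "var0000", "GENE00005", 0.0)
        pd.testing.assert_frame_equal(a.cohorts[0].counts, before)

    def test_effect_shifts_only_target_gene(self):
        a = self._study()
        before = a.cohorts[0].counts.copy()
        plant_pleiotropy(a, "var0000", "GENE00005", 0.8)
        after = a.cohorts[0].counts
        changed = (after != before).any(axis=1)
        assert changed["GENE00005"]
        assert changed.sum() == 1
        assert a.truth.pleiotropic_edges[("var0000", "GENE00005")] == 0.8

    def test_planted_variant_has_largest_q_contribution(self):
        from lipomr.mr import modified_cochran_q
        rng_hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                cohorts=("LL",), samples_per_cohort=(5000,), n_variants=20,
                n_genes=20, causal_genes={"GENE00001": 0.3},
                variant_effect_signs=(1.0,) * 20)
            study = simulate_study(cfg, seed=100 + seed)
            plant_pleiotropy(study, "var0004", "GENE00001", 0.5)
            c = study.cohorts[0]
            lib = c.counts.sum(axis=0).to_numpy(float)
            y = _int_expr(c.counts.loc["GENE00001"].to_numpy(float), lib)
            x = inverse_normal_transform(c.lipids["TG"].to_numpy(float))
            D = c.dosages.iloc[:, :20].to_numpy(float)
            Dc = D - D.mean(0)
            sxx = (Dc ** 2).sum(0)
            gam = Dc.T @ (x - x.mean()) / sxx
            Gam = Dc.T @ (y - y.mean()) / sxx
            se_g = np.sqrt(((x - x.mean()) ** 2).sum() / (5000 - 2) / sxx)
            se_G = np.sqrt(((y - y.mean()) ** 2).sum() / (5000 - 2) / sxx)
            rep = modified_cochran_q(gam, se_g, Gam, se_G)
            rng_hits += int(np.argmax(rep.q_contributions)) == 4
        assert rng_hits >= 9

    def test_unknown_variant_or_gene_rejected(self):
        a = self._study()
        with pytest.raises(KeyError):
            plant_pleiotropy(a, "nope", "GENE00001", 0.1)
        with pytest.raises(KeyError):
            plant_pleiotropy(a, "var0000", "NOPE", 0.1)


class TestOutcomeSummaryStats:
    def _truth(self, seed=14):
        cfg = SimulationConfig(cohorts=("LL",), samples_per_cohort=(50,),
                               n_genes=10, causal_genes={"GENE00002": 0.3})
        return simulate_study(cfg, seed=seed).truth

    def test_null_gene_effect_centered_on_zero(self):
        truth = self._truth()
        zs = []
        for seed in range(200):
            ss = simulate_outcome_summary_stats(truth, {"GENE00002": 0.0},
                                                seed=seed)
            zs.append(float(ss["beta"][0] / ss["se"][0]))
        assert np.mean(zs) == pytest.approx(0.0, abs=0.2)
        assert np.std(zs) == pytest.approx(1.0, abs=0.15)

    def test_two_sample_wald_recovers_effect(self):
        from lipomr.mr import wald_from_summary
        truth = self._truth()
        vid, eqtl_beta, maf = truth.eqtl_effects["GENE00002"]
        ss = simulate_outcome_summary_stats(truth, {"GENE00002": 0.4},
                                            external_n=100_000, seed=3)
        est = wald_from_summary(eqtl_beta, 1e-8, float(ss["beta"][0]),
                                float(ss["se"][0]))
        assert abs(est.wald_beta - 0.4) < 3 * est.robust_se

    def test_doubling_n_halves_se(self):
        truth = self._truth()
        a = simulate_outcome_summary_stats(truth, {"GENE00002": 0.1},
                                           external_n=50_000, seed=4)
        b = simulate_outcome_summary_stats(truth, {"GENE00002": 0.1},
                                           external_n=200_000, seed=4)
        assert float(a["se"][0] / b["se"][0]) == pytest.approx(2.0, rel=1e-9)

    def test_missing_eqtl_rejected(self):
        truth = self._truth()
        with pytest.raises(KeyError):
            simulate_outcome_summary_stats(truth, {"GENE00009": 0.1})
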