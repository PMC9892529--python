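"""Monte-Carlo evaluation of the MR pipeline on synthetic truth.

Each routine plants a known causal structure with the synthetic-study
generator (or a parametric summary-level equivalent), runs the relevant
part of the analysis, and scores the result against truth: Fieller
interval coverage, iterative Q-pruning recovery of planted pleiotropy,
type-I error of the full pipeline under confounded nulls, bidirectional
direction identification, and null calibration of the Q statistic and the
Egger intercept test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .mr import (egger_regression, iterative_pleiotropy_prune, ivw_estimate,
                 modified_cochran_q, per_variant_ratios, wald_ratio_fieller)
from .pipeline import RunConfig, model_covariates, run_study_analysis
from .preprocess import inverse_normal_transform
from .instruments import InstrumentDefinition, build_giv
from .synthetic import SimulationConfig, simulate_study
from .twas import fit_gene_model, meta_fixed_effect

__all__ = [
    "fieller_coverage",
    "qprune_recovery",
    "pipeline_type1_error",
    "bidirectional_direction_rate",
    "q_null_calibration",
    "egger_null_calibration",
]


def _child_seed(seed, rep):
    return int((seed * 1_000_003 + 7919 * rep + 1) % (2 ** 31 - 1))


def fieller_coverage(n_sims: int = 10_000, f_stat: float = 30.0,
                     ratio: float = 0.5, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Fraction of nominal 1-alpha Fieller intervals covering the true ratio.

    Parametric draws of the two stage estimates at an instrument strength
    of about ``f_stat`` (moderate by default, where the delta-method
    interval starts to fail but Fieller should remain calibrated).
    """
    rng = np.random.default_rng(seed)
    se_x = se_y = 0.1
    bx = np.sqrt(f_stat) * se_x
    by = ratio * bx
    bx_hat = rng.normal(bx, se_x, n_sims)
    by_hat = rng.normal(by, se_y, n_sims)
    covered = 0
    for i in range(n_sims):
        est = wald_ratio_fieller(by_hat[i], se_y, bx_hat[i], se_x, alpha=alpha)
        if est.fieller_low <= ratio <= est.fieller_high:
            covered += 1
    return covered / n_sims


def _log_cpm_int(counts_row, lib_size):
    return inverse_normal_transform(np.log((counts_row + 0.5) / lib_size))


def _simple_slopes(y, D):
    """Per-column OLS slope and SE of y on each dosage column of D."""
    n = y.size
    Dc = D - D.mean(axis=0)
    yc = y - y.mean()
    sxx = (Dc ** 2).sum(axis=0)
    beta = Dc.T @ yc / sxx
    resid_var = ((yc ** 2).sum() - beta ** 2 * sxx) / (n - 2)
    return beta, np.sqrt(resid_var / sxx)


def qprune_recovery(n_reps: int = 200, n: int = 5000, n_variants: int = 20,
                    pleio_effect: float = 0.5, causal_beta: float = 0.3,
                    threshold_p: float = 0.05, seed: int = 0) -> dict:
    """Recovery of two planted pleiotropic variants by iterative Q-pruning.

    Each replicate simulates a single 5,000-sample cohort with a
    20-variant instrument in which two variants also act directly on the
    causal gene.  Per-variant Wald ratios are formed from simple dosage
    regressions on the INT lipid and INT log-CPM expression; pruning is
    scored on whether it removes exactly the planted pair, and on how much
    it shrinks the bias of the pooled causal estimate.
    """
    exact = 0
    bias_pre, bias_post = [], []
    for rep in range(n_reps):
        s = _child_seed(seed, rep)
        gene = "GENE00000"
        planted = {("var0000", gene): pleio_effect,
                   ("var0001", gene): pleio_effect}
        cfg = SimulationConfig(
            cohorts=("LL",), samples_per_cohort=(n,),
            n_variants=n_variants, n_genes=40,
            variant_effect_signs=(1.0,) * n_variants,
            causal_genes={gene: causal_beta},
            pleiotropic_edges=planted,
        )
        study = simulate_study(cfg, seed=s)
        c = study.cohorts[0]
        lib = c.counts.sum(axis=0).to_numpy(float)
        expr = _log_cpm_int(c.counts.loc[gene].to_numpy(float), lib)
        lipid = inverse_normal_transform(c.lipids["TG"].to_numpy(float))
        ids = [f"var{j:04d}" for j in range(n_variants)]
        D = c.dosages[ids].to_numpy(float)
        gamma, se_g = _simple_slopes(lipid, D)
        Gamma, se_G = _simple_slopes(expr, D)
        kept, report = iterative_pleiotropy_prune(
            gamma, se_g, Gamma, se_G, variant_ids=ids, threshold_p=threshold_p)
        if set(report.removed_variants) == {"var0000", "var0001"}:
            exact += 1
        # causal estimate: Wald ratio on the weighted-dosage instrument,
        # rebuilt from the surviving variants after pruning
        weights = study.summary_stats.set_index("id")["beta"]

        def giv_wald(variant_subset):
            raw = c.dosages[variant_subset].to_numpy(float) @ \
                weights.loc[variant_subset].to_numpy()
            giv = (raw - raw.mean()) / raw.std(ddof=1)
            bx, sx = _simple_slopes(lipid, giv[:, None])
            by, sy = _simple_slopes(expr, giv[:, None])
            return wald_ratio_fieller(by[0], sy[0], bx[0], sx[0]).wald_beta

        bias_pre.append(giv_wald(ids) - causal_beta)
        bias_post.append(giv_wald(kept) - causal_beta)
    pre = float(np.mean(bias_pre))
    post = float(np.mean(bias_post))
    return {
        "exact_removal_rate": exact / n_reps,
        "bias_pre": pre,
        "bias_post": post,
        "bias_reduction": 1.0 - abs(post) / abs(pre),
    }


def pipeline_type1_error(n_genes: int = 1000, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Type-I error of the full MR pipeline under confounded null genes.

    One full six-cohort study (consortium sample sizes) with no causal
    lipid -> gene effects but the shared confounder active, so the naive
    association scan is biased.  MR is run on every gene; the returned
    rate is the fraction of null genes with MR p below ``alpha``.
    """
    cfg = SimulationConfig(n_genes=n_genes, n_causal=0)
    study = simulate_study(cfg, seed=seed)
    res = run_study_analysis(study, RunConfig(mr_genes="all"))
    mr = res["mr"]
    rate = float((mr["p"] < alpha).mean())
    return {"rate": rate, "n_genes": int(len(mr)),
            "naive_inflation": float(res["twas_cohort"]["inflation"].mean())}


def _meta_stage(study, prep_rows, y_key, x_key):
    assocs = []
    for c, row in zip(study.cohorts, prep_rows):
        a = fit_gene_model(row[y_key], row[x_key], covariates=row["covars"],
                           gene="g", cohort=c.cohort_id)
        assocs.append(a)
    return meta_fixed_effect(assocs)


def bidirectional_direction_rate(n_reps: int = 40, causal_beta: float = 0.4,
                                 alpha: float = 0.05, seed: int = 0) -> dict:
    """How often forward-only truth yields (significant forward, null reverse).

    Each replicate is a six-cohort study with one gene causally affected by
    the lipid (no reverse edge).  Forward MR uses the lipid instrument; the
    reverse test instruments the gene's expression with its strongest
    cis-eQTL.  Success requires forward p < alpha and reverse p > alpha.
    """
    gene = "GENE00000"
    fwd_hits, rev_nulls, joint = 0, 0, 0
    for rep in range(n_reps):
        s = _child_seed(seed, rep)
        cfg = SimulationConfig(n_genes=40, causal_genes={gene: causal_beta})
        study = simulate_study(cfg, seed=s)
        defn = InstrumentDefinition(
            trait="TG",
            variants=study.summary_stats[["id", "ea", "oa", "beta", "p"]])
        prep_rows = []
        for c in study.cohorts:
            lib = c.counts.sum(axis=0).to_numpy(float)
            prep_rows.append({
                "expr": _log_cpm_int(c.counts.loc[gene].to_numpy(float), lib),
                "lipid": inverse_normal_transform(c.lipids["TG"].to_numpy(float)),
                "giv": build_giv(defn, c.dosages[list(defn.variants["id"])]).score,
                "eqtl": c.dosages[f"eqtl_{gene}"].to_numpy(float),
                "covars": model_covariates(c.covariates),
            })
        fx = _meta_stage(study, prep_rows, "lipid", "giv")
        fy = _meta_stage(study, prep_rows, "expr", "giv")
        fwd = wald_ratio_fieller(fy.beta, fy.se, fx.beta, fx.se, gene=gene)
        rx = _meta_stage(study, prep_rows, "expr", "eqtl")
        ry = _meta_stage(study, prep_rows, "lipid", "eqtl")
        rev = wald_ratio_fieller(ry.beta, ry.se, rx.beta, rx.se, gene=gene,
                                 method="reverse")
        f_ok = fwd.p < alpha
        r_ok = rev.p > alpha
        fwd_hits += f_ok
        rev_nulls += r_ok
        joint += f_ok and r_ok
    return {"joint_rate": joint / n_reps, "forward_rate": fwd_hits / n_reps,
            "reverse_null_rate": rev_nulls / n_reps}


def q_null_calibration(n_reps: int = 2000, n_variants: int = 20,
                       ratio: float = 0.3, seed: int = 0) -> dict:
    """KS comparison of the modified Q statistic against chi-square(J-1).

    Summary-level parametric replicates with strong instruments and no
    pleiotropy; returns the KS p-value of the simulated Q distribution
    against its asymptotic reference.
    """
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.06, 0.12, n_variants)
    se_g = np.full(n_variants, 0.005)
    se_G = np.full(n_variants, 0.01)
    qs = np.empty(n_reps)
    for rep in range(n_reps):
        g_hat = rng.normal(gamma, se_g)
        G_hat = rng.normal(ratio * gamma, se_G)
        qs[rep] = modified_cochran_q(g_hat, se_g, G_hat, se_G).Q
    ks = stats.kstest(qs, stats.chi2(n_variants - 1).cdf)
    return {"ks_p": float(ks.pvalue), "mean_Q": float(qs.mean()),
            "df": n_variants - 1}


def egger_null_calibration(n_reps: int = 1000, n_variants: int = 40,
                           ratio: float = 0.3, pleio_sd: float = 0.02,
                           seed: int = 0) -> dict:
    """Uniformity of the Egger intercept p under balanced pleiotropy.

    Direct effects are mean-zero, so there is no directional pleiotropy
    and the intercept test should be a valid null test; returns the KS
    p-value of its p-values against Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    ps = np.empty(n_reps)
    for rep in range(n_reps):
        gamma = rng.uniform(0.05, 0.15, n_variants)
        se_G = np.full(n_variants, 0.01)
        alpha_j = rng.normal(0.0, pleio_sd, n_variants)
        G_hat = ratio * gamma + alpha_j + rng.normal(0.0, se_G)
        ps[rep] = egger_regression(gamma, G_hat, se_G).intercept_p
    ks = stats.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(ps.mean())}
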