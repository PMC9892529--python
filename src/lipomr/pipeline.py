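"""End-to-end orchestration: simulate -> preprocess -> instruments -> TWAS -> MR.

The association stage regresses each gene's normalized expression on the
lipid; genes passing the Bonferroni threshold feed the MR stage, which
re-estimates each association causally via the genetic instrument with
iterative pleiotropy pruning, and applies BH-FDR over the tested set.
``run_study_analysis`` performs the analysis in memory on a simulated (or
assembled) study; ``run_pipeline`` wraps it with TSV/JSON artifacts and a
manifest, driven by a YAML config.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from . import io as lio
from .instruments import InstrumentDefinition, build_giv, validate_instrument
from .mr import (bh_fdr, iterative_pleiotropy_prune, wald_ratio_fieller)
from .preprocess import friedewald_ldl, inverse_normal_transform, normalize_counts
from .synthetic import CELL_COLUMNS, SimulationConfig, simulate_study
from .twas import (bonferroni_threshold, correct_inflation,
                   estimate_latent_factors, fit_all_genes, fit_gene_model,
                   meta_fixed_effect_frame)

__all__ = ["RunConfig", "run_study_analysis", "run_pipeline"]

MODEL_COVARIATES = ["age", "sex", "WBC", "RBC", "pct_monocytes",
                    "pct_lymphocytes", "pct_neutrophils", "pct_eosinophils"]


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    seed: int = 0
    out: str = "runs/out"
    exposure: str = "TG"
    bonferroni_alpha: float = 0.05
    q_threshold: float = 0.05
    fdr_q: float = 0.05
    k_latent: int = 5
    max_zero_fraction: float = 0.20
    drop_cell_type: str = "pct_basophils"
    extra_covariates: tuple = ()    # e.g. smoking status, lipid medication
    mr_genes: str = "significant"   # or "all"
    simulation: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "preprocess": True, "giv": True,
        "twas": True, "mr": True,
    })

    def __post_init__(self):
        for name, v in [("bonferroni_alpha", self.bonferroni_alpha),
                        ("q_threshold", self.q_threshold),
                        ("fdr_q", self.fdr_q)]:
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def model_covariates(covariates: pd.DataFrame,
                     drop_cell_type: str = "pct_basophils",
                     extra: tuple = ()) -> np.ndarray:
    """Covariate design block: age, sex, WBC, RBC and four cell fractions.

    One of the five fractions (basophils by default) is dropped because the
    fractions sum to 100 and would otherwise be collinear with the
    intercept; its effect is absorbed there.  ``extra`` names additional
    sensitivity-analysis columns (e.g. smoking status, lipid-lowering
    medication) to append when present.
    """
    cols = [c for c in MODEL_COVARIATES + CELL_COLUMNS + list(extra)
            if c in covariates.columns and c != drop_cell_type]
    seen, ordered = set(), []
    for c in cols:
        if c not in seen:
            seen.add(c)
            ordered.append(c)
    return covariates[ordered].to_numpy(float)


def _prepare_cohort(cohort, run_cfg: RunConfig):
    """Normalize expression, INT the lipid, assemble the covariate block."""
    norm = normalize_counts(cohort.counts,
                            max_zero_fraction=run_cfg.max_zero_fraction)
    lipids = cohort.lipids.copy()
    if "LDL" not in lipids.columns and {"TC", "HDL", "TG"} <= set(lipids.columns):
        lipids["LDL"] = friedewald_ldl(lipids["TC"], lipids["HDL"], lipids["TG"])
    lipid_int = inverse_normal_transform(lipids[run_cfg.exposure].to_numpy(float))
    covars = model_covariates(cohort.covariates, run_cfg.drop_cell_type,
                              extra=run_cfg.extra_covariates)
    return {"norm": norm, "lipid_int": lipid_int, "covars": covars}


def run_study_analysis(study, run_cfg: RunConfig | None = None) -> dict:
    """Full in-memory analysis of a (simulated) study.

    Returns a dict of DataFrames: per-cohort and meta TWAS associations,
    instrument validation, per-variant association summaries, and the MR
    results for the selected genes (Bonferroni-significant by default),
    with iterative Q-pruning and BH-FDR applied.
    """
    cfg = run_cfg or RunConfig()
    prep = [_prepare_cohort(c, cfg) for c in study.cohorts]
    kept_genes = sorted(set.intersection(*[set(p["norm"].kept_genes) for p in prep]))
    m_tests = len(kept_genes)

    # --- instrument construction and validation, per cohort
    defn = InstrumentDefinition(
        trait=cfg.exposure,
        variants=study.summary_stats.rename(columns=str.lower)[
            ["id", "ea", "oa", "beta", "p"]],
    )
    positions = {r["id"]: (r["chrom"], r["pos"])
                 for _, r in study.summary_stats.iterrows()}
    givs, validation_rows = [], []
    for c, p in zip(study.cohorts, prep):
        score = build_giv(defn, c.dosages[list(defn.variants["id"])],
                          positions=positions)
        givs.append(score)
        rep = validate_instrument(score, p["lipid_int"],
                                  confounders=c.covariates[
                                      ["age", "sex", "WBC", "RBC"]])
        validation_rows.append({"cohort": c.cohort_id, **{k: rep[k] for k in
                                ("n", "r2", "f_stat", "p_first_stage")}})
    validation = pd.DataFrame(validation_rows)

    # --- TWAS: lipid exposure, latent factors, inflation correction, meta
    twas_cohort, factors_lipid = [], []
    for c, p in zip(study.cohorts, prep):
        expr = p["norm"].values.loc[kept_genes]
        fac = estimate_latent_factors(expr, covariates=p["covars"],
                                      k=cfg.k_latent, exposure=p["lipid_int"])
        factors_lipid.append(fac)
        assoc = fit_all_genes(expr, p["lipid_int"], covariates=p["covars"],
                              factors=fac, exposure_label=cfg.exposure,
                              cohort=c.cohort_id)
        if len(assoc) >= 100:
            zc, (bias, infl) = correct_inflation(assoc["z"].to_numpy())
        else:  # too few genes for empirical-null estimation; pass through
            zc, (bias, infl) = assoc["z"].to_numpy(), (0.0, 1.0)
        assoc["z_raw"] = assoc["z"]
        assoc["z"] = zc
        # rescale (beta, se) coherently so z = beta/se still holds post-correction
        assoc["se"] = assoc["se"] * infl
        assoc["beta"] = zc * assoc["se"]
        assoc["p"] = 2.0 * sps.norm.sf(np.abs(zc))
        assoc["bias"] = bias
        assoc["inflation"] = infl
        twas_cohort.append(assoc)
    twas_cohort = pd.concat(twas_cohort, ignore_index=True)
    twas_meta = meta_fixed_effect_frame(twas_cohort)
    threshold = bonferroni_threshold(cfg.bonferroni_alpha, m_tests)
    twas_meta["significant"] = twas_meta["p"] < threshold
    sign_all = twas_cohort.groupby("gene")["beta"].apply(
        lambda b: int((np.sign(b) == np.sign(b.iloc[0])).all()))
    twas_meta["direction_consistent"] = twas_meta["gene"].map(sign_all).astype(bool)

    if cfg.mr_genes == "all":
        mr_gene_list = list(twas_meta["gene"])
    else:
        mr_gene_list = list(twas_meta.loc[twas_meta["significant"], "gene"])

    results = {
        "twas_cohort": twas_cohort,
        "twas_meta": twas_meta,
        "instrument_validation": validation,
        "bonferroni_threshold": threshold,
        "m_tests": m_tests,
        "kept_genes": kept_genes,
    }
    if not mr_gene_list:
        results["mr"] = pd.DataFrame()
        return results

    # --- per-variant first- and second-stage associations, meta-analyzed
    variant_ids = givs[0].variants_used
    gamma_rows, Gamma_frames = [], []
    expr_mr = [p["norm"].values.loc[mr_gene_list] for p in prep]
    for c, p, e in zip(study.cohorts, prep, expr_mr):
        for vid in variant_ids:
            d = c.dosages[vid].to_numpy(float)
            a = fit_gene_model(p["lipid_int"], d, covariates=p["covars"],
                               gene="lipid", exposure_label=vid,
                               cohort=c.cohort_id)
            gamma_rows.append({"variant": vid, "cohort": c.cohort_id,
                               "beta": a.beta, "se": a.se, "n": a.n})
            G = fit_all_genes(e, d, covariates=p["covars"],
                              genes=mr_gene_list, exposure_label=vid,
                              cohort=c.cohort_id)
            G["variant"] = vid
            Gamma_frames.append(G)
    gamma = pd.DataFrame(gamma_rows)
    w = 1.0 / gamma["se"] ** 2
    gmeta = gamma.assign(_w=w, _wb=w * gamma["beta"]).groupby("variant")
    gamma_meta = pd.DataFrame({
        "beta": gmeta["_wb"].sum() / gmeta["_w"].sum(),
        "se": gmeta["_w"].sum() ** -0.5,
    }).loc[variant_ids]
    Gamma_all = pd.concat(Gamma_frames, ignore_index=True)
    wG = 1.0 / Gamma_all["se"] ** 2
    Gg = Gamma_all.assign(_w=wG, _wb=wG * Gamma_all["beta"]).groupby(
        ["gene", "variant"])
    Gamma_meta = pd.DataFrame({
        "beta": Gg["_wb"].sum() / Gg["_w"].sum(),
        "se": Gg["_w"].sum() ** -0.5,
    })

    # --- full-instrument Wald components (reused when nothing is pruned)
    def giv_stage_meta(scores, expr_subset=None, gene=None):
        rows = []
        for c, p, s, fac in zip(study.cohorts, prep, scores, factors_lipid):
            a_x = fit_gene_model(p["lipid_int"], s, covariates=p["covars"],
                                 gene="lipid", cohort=c.cohort_id)
            rows.append(("x", c.cohort_id, a_x.beta, a_x.se))
            if gene is not None:
                y = p["norm"].values.loc[gene].to_numpy(float)
                a_y = fit_gene_model(y, s, covariates=p["covars"], factors=fac,
                                     gene=gene, cohort=c.cohort_id)
                rows.append(("y", c.cohort_id, a_y.beta, a_y.se))
        df = pd.DataFrame(rows, columns=["stage", "cohort", "beta", "se"])
        out = {}
        for st, sub in df.groupby("stage"):
            ww = 1.0 / sub["se"] ** 2
            out[st] = (float((ww * sub["beta"]).sum() / ww.sum()),
                       float(ww.sum() ** -0.5))
        return out

    full_scores = [g.score for g in givs]
    full_x = giv_stage_meta(full_scores)["x"]

    giv_expr = []
    for c, p, s, fac in zip(study.cohorts, prep, full_scores, factors_lipid):
        e = p["norm"].values.loc[mr_gene_list]
        giv_expr.append(fit_all_genes(e, s, covariates=p["covars"], factors=fac,
                                      genes=mr_gene_list,
                                      exposure_label="GIV", cohort=c.cohort_id))
    giv_expr = pd.concat(giv_expr, ignore_index=True)
    wE = 1.0 / giv_expr["se"] ** 2
    gE = giv_expr.assign(_w=wE, _wb=wE * giv_expr["beta"]).groupby("gene")
    giv_expr_meta = pd.DataFrame({
        "beta": gE["_wb"].sum() / gE["_w"].sum(),
        "se": gE["_w"].sum() ** -0.5,
    })

    weights = defn.variants.set_index("id")["beta"]
    mr_rows = []
    for gene in mr_gene_list:
        Gg_gene = Gamma_meta.loc[gene].loc[variant_ids]
        kept_ids, report = iterative_pleiotropy_prune(
            gamma_meta["beta"].to_numpy(), gamma_meta["se"].to_numpy(),
            Gg_gene["beta"].to_numpy(), Gg_gene["se"].to_numpy(),
            variant_ids=variant_ids, threshold_p=cfg.q_threshold)
        if report.removed_variants:
            pruned_scores = []
            for c in study.cohorts:
                raw = c.dosages[kept_ids].to_numpy(float) @ weights.loc[kept_ids].to_numpy()
                pruned_scores.append((raw - raw.mean()) / raw.std(ddof=1))
            st = giv_stage_meta(pruned_scores, gene=gene)
            bx, sx = st["x"]
            by, sy = st["y"]
        else:
            bx, sx = full_x
            by, sy = (float(giv_expr_meta.loc[gene, "beta"]),
                      float(giv_expr_meta.loc[gene, "se"]))
        est = wald_ratio_fieller(by, sy, bx, sx, gene=gene,
                                 exposure=cfg.exposure)
        mr_rows.append({
            "gene": gene, "exposure": cfg.exposure, "beta": est.wald_beta,
            "se": est.robust_se, "fieller_low": est.fieller_low,
            "fieller_high": est.fieller_high, "p": est.p,
            "weak_instrument": est.weak_instrument,
            "Q": report.Q, "p_Q": report.p_Q,
            "n_removed": len(report.removed_variants),
            "removed_ids": ",".join(report.removed_variants),
            "method": "wald",
        })
    mr = pd.DataFrame(mr_rows)
    mr["p_fdr"], mr["fdr_significant"] = bh_fdr(
        mr["p"].clip(lower=np.nextafter(0, 1)), q=cfg.fdr_q)
    results["mr"] = mr
    results["gamma_meta"] = gamma_meta
    results["Gamma_meta"] = Gamma_meta
    return results


def run_pipeline(run_cfg: RunConfig) -> Path:
    """Execute the configured stages, writing TSV outputs and a manifest.

    Returns the run directory.  Any stage failure raises with the stage
    named; the manifest records versions, seeds, thresholds, and per-stage
    row counts (the MR stage consumes exactly the Bonferroni-significant
    TWAS gene-lipid pairs).
    """
    out = Path(run_cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "lipomr_version": __version__,
        "python": platform.python_version(),
        "seed": run_cfg.seed,
        "exposure": run_cfg.exposure,
        "thresholds": {"bonferroni_alpha": run_cfg.bonferroni_alpha,
                       "q_threshold": run_cfg.q_threshold,
                       "fdr_q": run_cfg.fdr_q},
        "stages": {},
    }
    stage = "simulate"
    try:
        sim_cfg = SimulationConfig(**run_cfg.simulation)
        study = simulate_study(sim_cfg, seed=run_cfg.seed)
        for c in study.cohorts:
            lio.write_dosages(c.dosages, out / f"dosages_{c.cohort_id}.tsv")
            lio.write_counts(c.counts, out / f"counts_{c.cohort_id}.tsv")
            lio.write_phenotypes(c.lipids, c.covariates,
                                 out / f"phenotypes_{c.cohort_id}.tsv")
        lio.write_summary_stats(study.summary_stats, out / "instrument_weights.tsv")
        manifest["stages"]["simulate"] = {
            "cohorts": len(study.cohorts),
            "samples": int(sum(len(c.dosages) for c in study.cohorts)),
            "genes": study.cohorts[0].counts.shape[0],
            "variants": len(study.truth.variant_effects_on_lipid),
        }
        stage = "analysis"
        res = run_study_analysis(study, run_cfg)
        lio.write_tsv(res["twas_cohort"], out / "twas_cohort.tsv")
        lio.write_tsv(res["twas_meta"], out / "twas_meta.tsv")
        lio.write_tsv(res["instrument_validation"], out / "giv_validation.tsv")
        lio.write_tsv(res["mr"], out / "mr_results.tsv")
        n_sig = int(res["twas_meta"]["significant"].sum())
        manifest["stages"]["twas"] = {
            "genes_tested": int(res["m_tests"]),
            "bonferroni_threshold": res["bonferroni_threshold"],
            "significant": n_sig,
        }
        manifest["stages"]["mr"] = {
            "associations_tested": int(len(res["mr"])),
            "fdr_significant": int(res["mr"]["fdr_significant"].sum())
            if len(res["mr"]) else 0,
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out
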