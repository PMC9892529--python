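"""Synthetic multi-cohort lipid/genotype/expression studies with known truth.

Emulates a six-cohort whole-blood RNA-seq consortium: per-cohort dosage
genotypes at configurable minor-allele frequencies, blood lipids (TG,
HDL-C, LDL-C, TC in mmol/L) generated as weighted sums of variant effects
plus a shared confounder and noise, and a negative-binomial count matrix
whose gene-wise log-means carry (i) a planted causal lipid effect for a
subset of genes, (ii) direct (pleiotropic) variant effects for another
subset, (iii) loadings on hidden batch factors and on measured
cell-composition covariates, and (iv) cis-eQTL effects used by the
reverse-direction and two-sample analyses.  The generating causal graph is
returned alongside the data, so every downstream estimate can be scored
against truth.

Cohort sample sizes and phenotype means/SDs default to the six-cohort
consortium the pipeline targets (n = 183, 741, 642, 797, 169, 697;
total 3,229).  The shared latent confounder enters both the lipid and the
gene means, so a naive transcriptome-wide regression is biased while the
genetic instrument, being independent of the confounder, is not — the
property the MR stage of the pipeline exists to exploit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "TruthGraph",
    "CohortData",
    "SimulatedStudy",
    "simulate_study",
    "plant_pleiotropy",
    "simulate_outcome_summary_stats",
]

# Per-cohort phenotype profile: n, % male, then (mean, sd) pairs.
COHORT_PROFILES = {
    "CODAM": dict(n=183, pct_male=56, age=(65.33, 7.05), tg=(1.58, 0.80),
                  ldl=(3.93, 1.00), hdl=(1.34, 0.33), mono=(7.13, 2.11),
                  lymph=(32.48, 10.23), neutro=(57.12, 10.99), eos=(2.75, 2.03),
                  wbc=(6.76, 1.52), rbc=(4.77, 0.37)),
    "LL": dict(n=741, pct_male=42, age=(45.33, 13.15), tg=(1.14, 0.88),
               ldl=(3.30, 0.97), hdl=(1.55, 0.41), mono=(7.47, 2.42),
               lymph=(31.87, 8.56), neutro=(56.81, 9.39), eos=(2.89, 1.85),
               wbc=(6.52, 1.41), rbc=(4.71, 0.34)),
    "LLS": dict(n=642, pct_male=47, age=(58.83, 6.61), tg=(1.93, 1.22),
                ldl=(3.82, 0.98), hdl=(1.42, 0.44), mono=(7.35, 2.43),
                lymph=(32.69, 8.16), neutro=(55.98, 8.72), eos=(2.79, 1.63),
                wbc=(6.61, 1.63), rbc=(4.72, 0.35)),
    "NTR": dict(n=797, pct_male=35, age=(38.18, 15.21), tg=(1.30, 0.74),
                ldl=(3.20, 0.96), hdl=(1.43, 0.38), mono=(7.96, 2.80),
                lymph=(34.59, 8.68), neutro=(53.80, 9.39), eos=(3.04, 1.99),
                wbc=(6.41, 1.57), rbc=(4.71, 0.39)),
    "PAN": dict(n=169, pct_male=63, age=(62.55, 9.55), tg=(1.85, 1.07),
                ldl=(3.83, 0.97), hdl=(1.44, 0.37), mono=(7.28, 2.46),
                lymph=(32.58, 8.60), neutro=(56.44, 8.88), eos=(2.82, 1.73),
                wbc=(6.95, 2.06), rbc=(4.66, 0.34)),
    "RS": dict(n=697, pct_male=42, age=(67.61, 5.93), tg=(1.48, 0.86),
               ldl=(3.71, 0.94), hdl=(1.51, 0.44), mono=(7.46, 2.41),
               lymph=(33.93, 7.90), neutro=(54.65, 8.60), eos=(2.91, 1.82),
               wbc=(6.44, 1.70), rbc=(4.68, 0.36)),
}

CELL_COLUMNS = ["pct_monocytes", "pct_lymphocytes", "pct_neutrophils",
                "pct_eosinophils", "pct_basophils"]


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic consortium.

    Defaults reproduce the target study conditions: 6 cohorts with the
    consortium sample sizes, a 40-variant instrument explaining 5% of the
    lipid variance (the observed instruments explained 4.0-6.4%), a shared
    confounder loading 0.3 on the lipid, five hidden batch factors, and a
    negative-binomial count model with unit biological log-variance.
    """

    cohorts: tuple = tuple(COHORT_PROFILES)
    samples_per_cohort: tuple | None = None  # None -> profile defaults
    n_variants: int = 40
    mafs: float | tuple | None = None        # None -> Uniform(0.05, 0.5)
    variant_effect_signs: tuple | None = None  # None -> random +-1 per variant
    n_genes: int = 1000
    n_causal: int = 10
    causal_beta: float = 0.3
    causal_genes: dict | None = None         # explicit gene -> beta overrides
    pleiotropic_edges: dict = field(default_factory=dict)  # (variant, gene) -> effect
    reverse_edges: dict = field(default_factory=dict)      # gene -> effect on lipid
    eqtl_beta: float = 0.4                   # per-allele cis effect, log-expr scale
    eqtl_genes: tuple | str = "auto"         # "auto": causal + reverse genes
    instrument_r2: float = 0.05
    confounder_lipid: float = 0.3
    confounder_gene_sd: float = 0.10
    n_hidden: int = 5
    hidden_loading_sd: float = 0.15
    cell_loading_sd: float = 0.05
    nb_dispersion: float = 0.05
    base_log_mean: float = float(np.log(500.0))
    base_log_sd: float = 1.0
    depth_log_sd: float = 0.2
    lipid_corr: tuple = (-0.48, 0.45, -0.12)  # (TG-HDL, TG-LDL, HDL-LDL)
    external_n: int = 188_577
    exposure: str = "TG"

    def validate(self):
        if self.n_variants <= 0 or self.n_genes <= 0 or len(self.cohorts) <= 0:
            raise ValueError("dimensions must be positive")
        if self.samples_per_cohort is not None:
            if len(self.samples_per_cohort) != len(self.cohorts):
                raise ValueError("samples_per_cohort length must match cohorts")
            if any(n <= 0 for n in self.samples_per_cohort):
                raise ValueError("dimensions must be positive")
        if self.mafs is not None:
            m = np.atleast_1d(np.asarray(self.mafs, float))
            if np.any((m <= 0) | (m > 0.5)):
                raise ValueError("MAF must lie in (0, 0.5]")
        if not 0 < self.instrument_r2 < 1:
            raise ValueError("instrument R^2 must lie in (0, 1)")
        rev_var = sum(e ** 2 for e in self.reverse_edges.values())
        if self.instrument_r2 + self.confounder_lipid ** 2 + rev_var >= 1:
            raise ValueError(
                "requested lipid variance components (instrument R^2 + "
                "confounder^2 + reverse effects^2) must sum below 1"
            )
        if self.n_causal > self.n_genes:
            raise ValueError("more causal genes than genes")


@dataclass
class TruthGraph:
    """The generating causal graph: every planted edge, by mechanism."""

    variant_effects_on_lipid: dict
    causal_gene_effects: dict
    pleiotropic_edges: dict
    hidden_loadings: pd.DataFrame
    reverse_edges: dict
    eqtl_effects: dict          # gene -> (variant id, per-allele beta, maf)
    variant_mafs: dict = field(default_factory=dict)


@dataclass
class CohortData:
    """One cohort's genotypes, phenotypes and expression counts."""

    cohort_id: str
    dosages: pd.DataFrame       # sample x variant, values in [0, 2]
    counts: pd.DataFrame        # gene x sample, non-negative integers
    lipids: pd.DataFrame        # sample x {TG, HDL, LDL, TC} in mmol/L
    covariates: pd.DataFrame    # sample x {age, sex, WBC, RBC, 5 cell pcts}
    log_mu: np.ndarray = field(default=None, repr=False)  # generator internals

    def __post_init__(self):
        n = len(self.dosages)
        if not (len(self.lipids) == len(self.covariates) == self.counts.shape[1] == n):
            raise ValueError("inconsistent sample dimension across fields")
        d = self.dosages.to_numpy()
        if np.any(d < 0) or np.any(d > 2):
            raise ValueError("dosages must lie in [0, 2]")
        c = self.counts.to_numpy()
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        cell_sum = self.covariates[CELL_COLUMNS].sum(axis=1).to_numpy()
        if not np.allclose(cell_sum, 100.0, atol=1e-6):
            raise ValueError("cell-type percentages must sum to 100 per sample")


@dataclass
class SimulatedStudy:
    cohorts: list
    truth: TruthGraph
    summary_stats: pd.DataFrame
    config: SimulationConfig
    seed: int

    def __iter__(self):  # allow (cohorts, truth, stats) unpacking
        return iter((self.cohorts, self.truth, self.summary_stats))


def _rng(seed, *streams) -> np.random.Generator:
    keys = [int(seed)] + [s if isinstance(s, int) else zlib.crc32(str(s).encode())
                          for s in streams]
    return np.random.default_rng(np.random.SeedSequence(keys))


def _draw_counts(rng, mu, dispersion):
    nb_n = 1.0 / dispersion
    p = nb_n / (nb_n + mu)
    return rng.negative_binomial(nb_n, p)


def _cell_fractions(rng, prof, n):
    cells = np.column_stack([
        np.clip(rng.normal(prof["mono"][0], prof["mono"][1], n), 0.2, None),
        np.clip(rng.normal(prof["lymph"][0], prof["lymph"][1], n), 1.0, None),
        np.clip(rng.normal(prof["neutro"][0], prof["neutro"][1], n), 1.0, None),
        np.clip(rng.normal(prof["eos"][0], prof["eos"][1], n), 0.05, None),
        np.clip(rng.normal(0.55, 0.25, n), 0.01, None),  # basophils: remainder type
    ])
    return cells / cells.sum(axis=1, keepdims=True) * 100.0


def _lipid_residual_corr(cfg, tg_resid_sd):
    tg_hdl, tg_ldl, hdl_ldl = cfg.lipid_corr
    r_eh = tg_hdl / tg_resid_sd
    r_el = tg_ldl / tg_resid_sd
    C = np.array([[1.0, r_eh, r_el], [r_eh, 1.0, hdl_ldl], [r_el, hdl_ldl, 1.0]])
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("requested lipid correlations are not jointly feasible "
                         "with the configured lipid variance components") from err


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Generate the full multi-cohort study plus its truth graph.

    All gene- and variant-level parameters (MAFs, loadings, causal gene
    selection) are drawn once from a global stream; sample-level randomness
    uses one independent stream per cohort derived deterministically from
    the master seed and the cohort index, so identical seed and config give
    bitwise-identical output and cohorts can be regenerated independently.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    grng = _rng(seed, "globals")

    J = cfg.n_variants
    variants = [f"var{j:04d}" for j in range(J)]
    if cfg.mafs is None:
        mafs = grng.uniform(0.05, 0.5, J)
    else:
        mafs = np.broadcast_to(np.atleast_1d(np.asarray(cfg.mafs, float)), (J,)).copy()
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]

    # per-allele lipid effects: equal variance share, random signs
    if cfg.variant_effect_signs is not None:
        signs = np.broadcast_to(
            np.asarray(cfg.variant_effect_signs, float), (J,)).copy()
    else:
        signs = grng.choice([-1.0, 1.0], J)
    b = signs * np.sqrt(cfg.instrument_r2 / (J * 2.0 * mafs * (1.0 - mafs)))

    if cfg.causal_genes is not None:
        causal = dict(cfg.causal_genes)
        unknown = set(causal) - set(genes)
        if unknown:
            raise KeyError(f"unknown causal genes: {sorted(unknown)}")
    else:
        picked = list(grng.choice(cfg.n_genes, size=cfg.n_causal, replace=False))
        causal = {genes[i]: cfg.causal_beta for i in sorted(picked)}
    for g in cfg.reverse_edges:
        if g not in genes:
            raise KeyError(f"unknown reverse-edge gene: {g}")
        if g in causal:
            raise ValueError(f"gene {g} cannot be both causal and reverse")

    if cfg.eqtl_genes == "auto":
        eqtl_gene_list = sorted(set(causal) | set(cfg.reverse_edges))
    else:
        eqtl_gene_list = list(cfg.eqtl_genes)
    eqtl_maf = {}
    eqtl_effects = {}
    for g in eqtl_gene_list:
        m = float(grng.uniform(0.1, 0.5))
        eqtl_maf[g] = m
        eqtl_effects[g] = (f"eqtl_{g}", cfg.eqtl_beta, m)

    gene_idx = {g: i for i, g in enumerate(genes)}
    base = grng.normal(cfg.base_log_mean, cfg.base_log_sd, cfg.n_genes)
    conf_load = grng.normal(0.0, cfg.confounder_gene_sd, cfg.n_genes)
    hidden_load = grng.normal(0.0, cfg.hidden_loading_sd, (cfg.n_genes, cfg.n_hidden))
    cell_load = grng.normal(0.0, cfg.cell_loading_sd, (cfg.n_genes, 3))

    beta_vec = np.zeros(cfg.n_genes)
    for g, eff in causal.items():
        beta_vec[gene_idx[g]] = eff
    pleio = dict(cfg.pleiotropic_edges)
    for (v, g) in pleio:
        if v not in variants:
            raise KeyError(f"unknown pleiotropy variant: {v}")
        if g not in genes:
            raise KeyError(f"unknown pleiotropy gene: {g}")

    # per-gene residual biological variance so total latent variance is ~1
    struct_var = (beta_vec ** 2 + conf_load ** 2
                  + (hidden_load ** 2).sum(axis=1) + (cell_load ** 2).sum(axis=1))
    for g in eqtl_gene_list:
        m = eqtl_maf[g]
        struct_var[gene_idx[g]] += cfg.eqtl_beta ** 2 * 2 * m * (1 - m)
    for (v, g), eff in pleio.items():
        m = mafs[variants.index(v)]
        struct_var[gene_idx[g]] += eff ** 2 * 2 * m * (1 - m)
    resid_sd = np.sqrt(np.clip(1.0 - struct_var, 0.05, None))

    rev_var = sum(e ** 2 for e in cfg.reverse_edges.values())
    tg_resid_var = 1.0 - cfg.instrument_r2 - cfg.confounder_lipid ** 2 - rev_var
    chol = _lipid_residual_corr(cfg, np.sqrt(tg_resid_var))

    truth = TruthGraph(
        variant_effects_on_lipid=dict(zip(variants, b)),
        causal_gene_effects=dict(causal),
        pleiotropic_edges=dict(pleio),
        hidden_loadings=pd.DataFrame(hidden_load, index=genes,
                                     columns=[f"hidden{k+1}" for k in range(cfg.n_hidden)]),
        reverse_edges=dict(cfg.reverse_edges),
        eqtl_effects=eqtl_effects,
        variant_mafs=dict(zip(variants, mafs)),
    )
    for g, (vid, _, m) in eqtl_effects.items():
        truth.variant_mafs[vid] = m

    sizes = (cfg.samples_per_cohort if cfg.samples_per_cohort is not None
             else tuple(COHORT_PROFILES[c]["n"] for c in cfg.cohorts))

    cohorts = []
    for ci, (cname, n) in enumerate(zip(cfg.cohorts, sizes)):
        prof = COHORT_PROFILES.get(cname, COHORT_PROFILES["LL"])
        rng = _rng(seed, "cohort", ci)
        sample_ids = [f"{cname}_{i:05d}" for i in range(n)]

        dos = rng.binomial(2, mafs, size=(n, J)).astype(float)
        eqtl_dos = {g: rng.binomial(2, eqtl_maf[g], size=n).astype(float)
                    for g in eqtl_gene_list}
        C = rng.normal(0.0, 1.0, n)
        H = rng.normal(0.0, 1.0, (n, cfg.n_hidden))
        cells = _cell_fractions(rng, prof, n)
        cells_std = (cells[:, :3] - cells[:, :3].mean(axis=0)) / cells[:, :3].std(axis=0)

        gscore = (dos - 2.0 * mafs) @ b

        # exogenous latent expression (everything but the causal lipid path)
        eps = rng.normal(0.0, 1.0, (n, cfg.n_genes))
        X0 = (eps * resid_sd
              + np.outer(C, conf_load)
              + H @ hidden_load.T
              + cells_std @ cell_load.T)
        for g in eqtl_gene_list:
            m = eqtl_maf[g]
            X0[:, gene_idx[g]] += cfg.eqtl_beta * (eqtl_dos[g] - 2 * m)
        for (v, g), eff in pleio.items():
            vj = variants.index(v)
            X0[:, gene_idx[g]] += eff * (dos[:, vj] - 2 * mafs[vj])

        tg_resid3 = rng.normal(0.0, 1.0, (n, 3)) @ chol.T
        tg_l = (gscore + cfg.confounder_lipid * C
                + sum(eff * X0[:, gene_idx[g]] for g, eff in cfg.reverse_edges.items())
                + np.sqrt(tg_resid_var) * tg_resid3[:, 0])
        hdl_l, ldl_l = tg_resid3[:, 1], tg_resid3[:, 2]

        tg = np.clip(prof["tg"][0] + prof["tg"][1] * tg_l, 0.05, None)
        hdl = np.clip(prof["hdl"][0] + prof["hdl"][1] * hdl_l, 0.05, None)
        ldl = np.clip(prof["ldl"][0] + prof["ldl"][1] * ldl_l, 0.05, None)
        tc = ldl + hdl + tg / 2.2
        lipids = pd.DataFrame({"TG": tg, "HDL": hdl, "LDL": ldl, "TC": tc},
                              index=sample_ids)

        covariates = pd.DataFrame({
            "age": rng.normal(prof["age"][0], prof["age"][1], n),
            "sex": rng.binomial(1, prof["pct_male"] / 100.0, n).astype(float),
            "WBC": np.clip(rng.normal(prof["wbc"][0], prof["wbc"][1], n), 0.5, None),
            "RBC": np.clip(rng.normal(prof["rbc"][0], prof["rbc"][1], n), 1.0, None),
            **{col: cells[:, k] for k, col in enumerate(CELL_COLUMNS)},
        }, index=sample_ids)

        latent = X0 + np.outer(tg_l, beta_vec)
        depth = rng.normal(0.0, cfg.depth_log_sd, n)
        log_mu = (base[None, :] + latent + depth[:, None]).T  # gene x sample
        counts = _draw_counts(rng, np.exp(log_mu), cfg.nb_dispersion)

        dos_df = pd.DataFrame(dos, index=sample_ids, columns=variants)
        for g in eqtl_gene_list:
            dos_df[f"eqtl_{g}"] = eqtl_dos[g]
        cohorts.append(CohortData(
            cohort_id=cname,
            dosages=dos_df,
            counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
            lipids=lipids,
            covariates=covariates,
            log_mu=log_mu,
        ))

    summary_stats = _discovery_summary_stats(cfg, seed, variants, mafs, b)
    return SimulatedStudy(cohorts=cohorts, truth=truth,
                          summary_stats=summary_stats, config=cfg, seed=seed)


def _discovery_summary_stats(cfg, seed, variants, mafs, b) -> pd.DataFrame:
    """External discovery-GWAS weights: true effects plus 1/sqrt(2 maf (1-maf) N) noise.

    Drawn from an independent stream, mimicking non-overlapping discovery
    samples (two-sample instrument weights).
    """
    rng = _rng(seed, "discovery")
    se = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * cfg.external_n)
    beta_hat = b + rng.normal(0.0, se)
    z = beta_hat / se
    return pd.DataFrame({
        "chrom": ["1"] * len(variants),
        "pos": [2_000_000 * (j + 1) for j in range(len(variants))],
        "id": variants,
        "ea": "A",
        "oa": "G",
        "eaf": mafs,
        "beta": beta_hat,
        "se": se,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
        "n": cfg.external_n,
        "trait": cfg.exposure,
    })


def plant_pleiotropy(study: SimulatedStudy, variant: str, gene: str,
                     effect: float) -> SimulatedStudy:
    """Give ``variant`` a direct effect on ``gene``, bypassing the lipid.

    The gene's log-mean gains ``effect * (dosage - 2 maf)`` in every cohort
    and its counts are re-drawn from a stream keyed by (seed, cohort,
    variant, gene).  An effect of zero leaves the log-means — and hence the
    study — untouched.  The truth graph is updated in place.
    """
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    if variant not in study.truth.variant_effects_on_lipid:
        raise KeyError(f"unknown instrument variant: {variant}")
    if gene not in study.cohorts[0].counts.index:
        raise KeyError(f"unknown gene: {gene}")
    if effect == 0.0:
        return study
    cfg = study.config
    for ci, cohort in enumerate(study.cohorts):
        if gene not in cohort.counts.index:
            raise KeyError(f"unknown gene: {gene}")
        gi = cohort.counts.index.get_loc(gene)
        maf = study.truth.variant_mafs[variant]
        d = cohort.dosages[variant].to_numpy(float)
        cohort.log_mu[gi] = cohort.log_mu[gi] + effect * (d - 2.0 * maf)
        rng = _rng(study.seed, "pleio", ci, variant, gene)
        cohort.counts.iloc[gi] = _draw_counts(
            rng, np.exp(cohort.log_mu[gi]), cfg.nb_dispersion)
    edges = dict(study.truth.pleiotropic_edges)
    edges[(variant, gene)] = edges.get((variant, gene), 0.0) + effect
    study.truth.pleiotropic_edges = edges
    return study


def simulate_outcome_summary_stats(truth: TruthGraph, gene_outcome_betas: dict,
                                   external_n: int = 100_000,
                                   seed: int = 0,
                                   trait: str = "outcome") -> pd.DataFrame:
    """GWAS-style outcome summary statistics with a known gene -> outcome effect.

    For each listed gene the outcome effect of its cis-eQTL variant is
    eqtl_beta * gene_outcome_beta plus noise at the 1/sqrt(2 maf (1-maf) N)
    scale, feeding the two-sample MR stage.
    """
    rows = []
    rng = _rng(seed, "outcome", trait)
    for g, b_out in gene_outcome_betas.items():
        if g not in truth.eqtl_effects:
            raise KeyError(f"no cis-eQTL defined for gene {g}")
        vid, eqtl_beta, maf = truth.eqtl_effects[g]
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * external_n)
        beta = eqtl_beta * b_out + rng.normal(0.0, se)
        z = beta / se
        rows.append({"id": vid, "gene": g, "ea": "A", "oa": "G", "eaf": maf,
                     "beta": beta, "se": se,
                     "p": float(2.0 * stats.norm.sf(abs(z))),
                     "n": external_n, "trait": trait})
    return pd.DataFrame(rows)
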