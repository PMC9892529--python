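"""Weighted genetic instrumental variables (GIVs) for lipid exposures.

A GIV is the weighted sum of risk-allele dosages, GI = sum_i beta_i *
dosage_i, with weights taken from an external discovery GWAS, restricted
to variants that are far apart (> 1 Mb) and nearly independent
(r^2 < 0.10), and scaled to mean 0 / SD 1.  Instrument strength is
summarized by the first-stage F statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InstrumentDefinition",
    "InstrumentScore",
    "prune_variants",
    "build_giv",
    "validate_instrument",
    "first_stage_f",
]


@dataclass
class InstrumentDefinition:
    """Variant weights for one exposure trait.

    ``variants`` is a DataFrame with columns ``id``, ``ea`` (effect
    allele), ``oa`` (other allele), ``beta`` (discovery GWAS per-allele
    effect) and optionally ``p`` (discovery p, used for pruning ties).
    """

    trait: str
    variants: pd.DataFrame
    distance_bp: int = 1_000_000
    r2_max: float = 0.10

    def __post_init__(self):
        v = self.variants
        if v["id"].duplicated().any():
            raise ValueError("variant IDs must be unique")
        b = v["beta"].to_numpy(float)
        if not np.all(np.isfinite(b)) or np.any(b == 0):
            raise ValueError("weights must be finite and non-zero")


@dataclass
class InstrumentScore:
    """Standardized per-sample instrument score."""

    score: np.ndarray
    trait: str
    variants_used: list
    pruned: list = field(default_factory=list)
    raw_mean: float = 0.0
    raw_sd: float = 1.0


def prune_variants(defn: InstrumentDefinition, positions=None, r2_matrix=None):
    """Greedy distance/LD pruning: keep, by ascending discovery p, variants
    that are > ``distance_bp`` from and have r^2 < ``r2_max`` with every
    variant already kept.

    ``positions`` maps id -> (chrom, pos); ``r2_matrix`` is a DataFrame of
    pairwise r^2 (or None, meaning independence — the identity matrix).
    Ties in p break by larger |weight|, then genomic position.
    """
    v = defn.variants.copy()
    if "p" in v.columns and v["p"].notna().all():
        order_key = v["p"].to_numpy(float)
    else:
        order_key = -np.abs(v["beta"].to_numpy(float))
    pos_key = np.arange(len(v))
    if positions is not None:
        pos_key = np.array([positions[i][1] for i in v["id"]])
    order = np.lexsort((pos_key, -np.abs(v["beta"].to_numpy(float)), order_key))
    kept, pruned = [], []
    for idx in order:
        vid = v["id"].iloc[idx]
        ok = True
        for kid in kept:
            if positions is not None:
                c1, p1 = positions[vid]
                c2, p2 = positions[kid]
                if c1 == c2 and abs(p1 - p2) <= defn.distance_bp:
                    ok = False
                    break
            if r2_matrix is not None and vid in getattr(r2_matrix, "index", ()):
                if float(r2_matrix.loc[vid, kid]) >= defn.r2_max:
                    ok = False
                    break
        (kept if ok else pruned).append(vid)
    keep_order = [i for i in v["id"] if i in set(kept)]
    return keep_order, pruned


def build_giv(defn: InstrumentDefinition, dosages: pd.DataFrame,
              positions=None, r2_matrix=None,
              dosage_alleles=None) -> InstrumentScore:
    """Build the standardized weighted-dosage instrument score.

    ``dosages`` is a sample x variant DataFrame in [0, 2], columns named by
    variant ID.  When ``dosage_alleles`` (id -> (ea, oa) of the dosage
    coding) is given, variants whose discovery effect allele is the dosage
    file's other allele are reconciled by flipping dosage to 2 - dosage;
    irreconcilable allele pairs raise.
    """
    missing = [i for i in defn.variants["id"] if i not in dosages.columns]
    if missing:
        raise KeyError(f"variants absent from dosages: {missing}")
    kept, pruned = prune_variants(defn, positions=positions, r2_matrix=r2_matrix)
    if not kept:
        raise ValueError("no variants remain after pruning")
    v = defn.variants.set_index("id").loc[kept]
    score = np.zeros(len(dosages))
    for vid, row in v.iterrows():
        d = dosages[vid].to_numpy(float)
        if dosage_alleles is not None and vid in dosage_alleles:
            ea_d, oa_d = dosage_alleles[vid]
            if row["ea"] == ea_d:
                pass
            elif row["ea"] == oa_d and row["oa"] == ea_d:
                d = 2.0 - d
            else:
                raise ValueError(f"unresolvable allele mismatch for {vid}")
        score += row["beta"] * d
    mu = float(score.mean())
    sd = float(score.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate instrument: zero variance score")
    return InstrumentScore(
        score=(score - mu) / sd, trait=defn.trait, variants_used=list(kept),
        pruned=list(pruned), raw_mean=mu, raw_sd=sd,
    )


def first_stage_f(r2: float, n: int) -> float:
    """First-stage F statistic for a single instrument: (n-2) R^2 / (1-R^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 <= r2 < 1:
        raise ValueError("R^2 must lie in [0, 1)")
    return (n - 2) * r2 / (1.0 - r2)


def validate_instrument(score: InstrumentScore, lipid, confounders=None) -> dict:
    """Instrument validity report: strength and confounder independence.

    Regresses the lipid on the score for the first-stage R^2 and
    F = (n-2) R^2 / (1-R^2), and each supplied confounder on the score for
    association p-values (a valid instrument should show none).
    """
    g = np.asarray(score.score, float)
    y = np.asarray(lipid, float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    r = float(np.corrcoef(g, y)[0, 1])
    r2 = r * r
    f = first_stage_f(r2, n)
    p_first = float(stats.f.sf(f, 1, n - 2))
    report = {"n": n, "r2": r2, "f_stat": f, "p_first_stage": p_first,
              "confounder_p": {}}
    if confounders is not None:
        conf = pd.DataFrame(confounders)
        for name in conf.columns:
            c = conf[name].to_numpy(float)
            rc = float(np.corrcoef(g, c)[0, 1])
            fc = first_stage_f(rc * rc, n)
            report["confounder_p"][name] = float(stats.f.sf(fc, 1, n - 2))
    return report
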