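"""Phenotype derivation and expression normalization.

Covers the standard preprocessing applied before any association testing:
Friedewald derivation of LDL cholesterol, rank-based inverse normal
transformation (INT), removal of sparsely expressed genes, TMM
(trimmed mean of M-values) between-sample normalization factors, and
genotype quality-control filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizedMatrix",
    "friedewald_ldl",
    "inverse_normal_transform",
    "filter_genes",
    "tmm_factors",
    "qc_variants",
    "normalize_counts",
]

#: Triglyceride concentration (mmol/L) above which the Friedewald formula
#: is considered invalid (400 mg/dL, the standard clinical bound).
FRIEDEWALD_TG_MAX = 4.52


def friedewald_ldl(tc, hdl, tg, tg_max: float = FRIEDEWALD_TG_MAX):
    """Derive LDL cholesterol via the Friedewald formula (mmol/L units).

    LDL-C = TC - HDL-C - TG/2.2.  Samples with TG above ``tg_max`` get a
    missing value with a warning, as the formula is unreliable there.

    Accepts scalars or array-likes; returns a float or ndarray.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise ValueError("lipid concentrations must be non-negative")
    ldl = tc - hdl - tg / 2.2
    invalid = tg > tg_max
    if np.any(invalid):
        warnings.warn(
            f"{int(np.sum(invalid))} sample(s) with TG > {tg_max} mmol/L: "
            "Friedewald LDL-C set to missing",
            stacklevel=2,
        )
        ldl = np.where(invalid, np.nan, ldl)
    if ldl.ndim == 0:
        return float(ldl)
    return ldl


def inverse_normal_transform(x, c: float = 0.375):
    """Rank-based inverse normal transform with Blom offset ``c`` = 3/8.

    Maps values to ``Phi^-1((rank - c) / (n - 2c + 1))`` where ranks are
    average ranks over the non-missing entries; missing values propagate.

    Raises ``ValueError`` for fewer than 3 non-missing values or a
    constant vector (all ranks tied).
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("inverse normal transform requires >= 3 non-missing values")
    vals = x[mask]
    if np.all(vals == vals[0]):
        raise ValueError("constant vector: all ranks tied, INT undefined")
    ranks = stats.rankdata(vals, method="average")
    out[mask] = stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))
    return out


def filter_genes(counts: pd.DataFrame, max_zero_fraction: float = 0.20) -> list:
    """Return genes expressed in enough samples.

    A gene is kept iff the fraction of samples with zero counts is strictly
    below ``max_zero_fraction`` (genes with zeros in at least that fraction
    of samples are removed).

    Parameters
    ----------
    counts : gene x sample DataFrame of non-negative integers.
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    zero_frac = (counts.to_numpy() == 0).mean(axis=1)
    return list(counts.index[zero_frac < max_zero_fraction])


def tmm_factors(
    counts,
    ref_sample=None,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
    weighted: bool = True,
) -> np.ndarray:
    """Per-sample TMM normalization factors.

    Computes, for each sample against a reference sample, the weighted
    trimmed mean of gene-wise log2 expression ratios (M-values), trimming
    the most extreme 30% of M-values on each side and 5% of A-values
    (average log expression), weighting by asymptotic binomial (delta
    method) variances.  Factors are rescaled to geometric mean 1.

    Parameters
    ----------
    counts : gene x sample array or DataFrame of raw counts.
    ref_sample : column index of the reference; default is the sample whose
        upper-quartile count fraction is closest to the mean upper quartile.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be a 2-D gene x sample matrix")
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    n_samples = X.shape[1]
    if ref_sample is None:
        with np.errstate(divide="ignore"):
            uq = np.array(
                [np.quantile(X[:, j][X[:, j] > 0] / lib[j], 0.75) if (X[:, j] > 0).any() else 0.0
                 for j in range(n_samples)]
            )
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))
    ref = X[:, ref_sample]
    nref = lib[ref_sample]

    factors = np.ones(n_samples)
    for j in range(n_samples):
        obs = X[:, j]
        nobs = lib[j]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            raise ValueError(f"sample {j} shares no expressed genes with reference")
        o, r = obs[ok], ref[ok]
        m = np.log2((o / nobs) / (r / nref))
        a = 0.5 * np.log2((o / nobs) * (r / nref))
        v = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
        n = m.size
        # double trim on ranks of M and A, matching the canonical procedure
        lo_m = np.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_expr_trim) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            f = 0.0
        elif weighted:
            f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        else:
            f = np.mean(m[keep])
        if not np.isfinite(f):
            f = 0.0
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def qc_variants(metrics: pd.DataFrame,
                min_info: float = 0.5,
                min_hwe_p: float = 1e-4,
                min_call_rate: float = 0.95,
                min_maf: float = 0.05) -> list:
    """Genotype QC: return variant IDs passing all four filters.

    A variant is removed iff info < 0.5, Hardy-Weinberg p < 1e-4,
    call rate < 0.95, or minor allele frequency < 0.05 (all strict
    comparisons).  Variants with any missing metric are removed with a
    warning.

    Parameters
    ----------
    metrics : DataFrame indexed by variant ID with columns
        ``info``, ``hwe_p``, ``call_rate``, ``maf``.
    """
    required = ["info", "hwe_p", "call_rate", "maf"]
    missing_cols = [c for c in required if c not in metrics.columns]
    if missing_cols:
        raise ValueError(f"missing QC metric columns: {missing_cols}")
    vals = metrics[required]
    has_na = vals.isna().any(axis=1)
    if has_na.any():
        warnings.warn(
            f"{int(has_na.sum())} variant(s) with missing QC metrics removed",
            stacklevel=2,
        )
    keep = (
        ~has_na
        & (vals["info"] >= min_info)
        & (vals["hwe_p"] >= min_hwe_p)
        & (vals["call_rate"] >= min_call_rate)
        & (vals["maf"] >= min_maf)
    )
    return list(metrics.index[keep])


@dataclass
class NormalizedMatrix:
    """TMM-normalized, inverse-normal-transformed expression.

    Attributes
    ----------
    values : gene x sample DataFrame after INT of TMM-scaled counts.
    kept_genes : genes surviving the sparsity filter.
    scaling_factors : per-sample TMM factor (geometric mean 1).
    """

    values: pd.DataFrame
    kept_genes: list = field(default_factory=list)
    scaling_factors: np.ndarray | None = None


def normalize_counts(counts: pd.DataFrame,
                     max_zero_fraction: float = 0.20,
                     int_offset: float = 0.375) -> NormalizedMatrix:
    """Full expression normalization: filter, TMM, log-CPM, per-gene INT.

    Genes with zeros in at least ``max_zero_fraction`` of samples are
    dropped, per-sample TMM factors computed on the remaining counts, counts
    converted to log2 CPM on TMM-effective library sizes, and each gene row
    inverse-normal transformed.
    """
    kept = filter_genes(counts, max_zero_fraction)
    sub = counts.loc[kept]
    factors = tmm_factors(sub)
    eff_lib = sub.to_numpy().sum(axis=0) * factors
    cpm = np.log2((sub.to_numpy() + 0.5) / eff_lib[None, :] * 1e6)
    transformed = np.vstack([
        inverse_normal_transform(row, c=int_offset) for row in cpm
    ]) if len(kept) else np.empty((0, sub.shape[1]))
    values = pd.DataFrame(transformed, index=kept, columns=sub.columns)
    return NormalizedMatrix(values=values, kept_genes=kept, scaling_factors=factors)
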