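"""Per-cohort transcriptome-wide association and fixed-effect meta-analysis.

Each gene's inverse-normal-transformed expression is regressed on an
exposure (a lipid level, a genetic instrumental variable, or a single
variant dosage) together with age, sex, white and red blood-cell counts,
four of the five differential cell fractions (one dropped to avoid
collinearity with the implicit intercept), and k latent factors estimated
from the expression residuals.  Per-cohort z-scores are recalibrated
against an empirical null before inverse-variance meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAssociation",
    "LatentFactors",
    "CollinearityError",
    "estimate_latent_factors",
    "fit_gene_model",
    "fit_all_genes",
    "correct_inflation",
    "meta_fixed_effect",
    "bonferroni_threshold",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient (e.g. all five cell fractions included)."""


@dataclass
class GeneAssociation:
    """Effect of one exposure on one gene in one cohort (or meta-analyzed)."""

    gene: str
    exposure: str
    beta: float
    se: float
    z: float
    p: float
    cohort: str
    n: int


@dataclass
class LatentFactors:
    """Sample x k matrix of latent confounder estimates.

    Columns are mean-zero with unit sample variance and mutually orthogonal.
    """

    factors: np.ndarray
    k: int


def _design(n, exposure=None, covariates=None, factors=None):
    cols = [np.ones(n)]
    if exposure is not None:
        cols.append(np.asarray(exposure, dtype=float))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    if factors is not None:
        f = factors.factors if isinstance(factors, LatentFactors) else np.asarray(factors, float)
        if f.ndim == 1:
            f = f[:, None]
        cols.append(f)
    return np.column_stack(cols)


def _check_full_rank(X):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            "remove collinear covariates (e.g. drop one cell fraction)"
        )


def estimate_latent_factors(expression, covariates=None, k: int = 5,
                            exposure=None) -> LatentFactors:
    """Estimate k latent confounders from expression residuals.

    The sample x gene matrix is residualized on the known covariates, its
    top-k left singular vectors are taken as factor estimates, and — when an
    exposure is supplied — the factors are additionally residualized on the
    exposure so the exposure's own signal is not absorbed.  Returned columns
    are re-orthogonalized, mean zero, unit variance.

    ``expression`` is gene x sample (matrix or DataFrame); transposed
    internally.
    """
    E = np.asarray(expression, dtype=float)
    Y = E.T  # sample x gene
    n = Y.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    X = _design(n, covariates=covariates)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ coef
    if k >= min(R.shape):
        raise ValueError(f"k={k} exceeds the rank bound of the residual matrix")
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    F = U[:, :k]
    if exposure is not None:
        Xe = _design(n, exposure=exposure)
        coef_e, *_ = np.linalg.lstsq(Xe, F, rcond=None)
        F = F - Xe @ coef_e
    # re-orthogonalize and standardize to mean 0, unit variance
    F = F - F.mean(axis=0)
    Q, _ = np.linalg.qr(F)
    Q = Q - Q.mean(axis=0)
    F = Q / Q.std(axis=0, ddof=1)
    return LatentFactors(factors=F, k=k)


def fit_gene_model(expression_row, exposure, covariates=None, factors=None,
                   gene: str = "gene", exposure_label: str = "exposure",
                   cohort: str = "cohort") -> GeneAssociation:
    """OLS of one gene's (INT) expression on the exposure plus covariates.

    Covariates follow the standard model: age, sex, WBC, RBC and four cell
    fractions (caller drops one fraction — conventionally basophils — to
    keep the design full rank).  The returned association carries the
    exposure coefficient, its standard error, and a two-sided normal p.
    """
    y = np.asarray(expression_row, dtype=float)
    X = _design(y.size, exposure=exposure, covariates=covariates, factors=factors)
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[mask], X[mask]
    _check_full_rank(X)
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    sigma2 = resid @ resid / (n - p)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(beta_hat[1])
    z = beta / se
    return GeneAssociation(
        gene=gene, exposure=exposure_label, beta=beta, se=se, z=z,
        p=float(2.0 * stats.norm.sf(abs(z))), cohort=cohort, n=n,
    )


def fit_all_genes(expression, exposure, covariates=None, factors=None,
                  genes=None, exposure_label: str = "exposure",
                  cohort: str = "cohort") -> pd.DataFrame:
    """Vectorized gene-wise OLS sharing one design matrix across genes.

    ``expression`` is gene x sample.  Returns a DataFrame with columns
    gene, exposure, cohort, beta, se, z, p, n — identical to running
    :func:`fit_gene_model` per row, but in a single pass.
    """
    E = np.asarray(expression, dtype=float)
    if genes is None:
        genes = (list(expression.index) if isinstance(expression, pd.DataFrame)
                 else [f"g{i}" for i in range(E.shape[0])])
    n = E.shape[1]
    X = _design(n, exposure=exposure, covariates=covariates, factors=factors)
    _check_full_rank(X)
    p = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ E.T)            # p x genes
    resid = E.T - X @ B
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    beta = B[1]
    z = beta / se
    return pd.DataFrame({
        "gene": genes,
        "exposure": exposure_label,
        "cohort": cohort,
        "beta": beta,
        "se": se,
        "z": z,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
        "n": n,
    })


def correct_inflation(z_scores, central: float = 0.90):
    """Empirical-null recalibration of a vector of z-scores.

    Bias and inflation are estimated robustly — median and scaled median
    absolute deviation (x 1.4826) — on the central ``central`` fraction of
    the distribution, so that a modest share of true signals in the tails
    does not distort the null.  Returns ``(corrected, (bias, inflation))``
    with ``corrected = (z - bias) / inflation``.
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size < 100:
        raise ValueError("need >= 100 z-scores for empirical-null estimation")
    tail = (1.0 - central) / 2.0
    lo, hi = np.quantile(z, [tail, 1.0 - tail])
    core = z[(z >= lo) & (z <= hi)]
    bias = float(np.median(core))
    # consistency constant for the median absolute deviation of a normal
    # sample truncated to its central `central` fraction (0.6745 at 100%)
    scale_const = stats.norm.ppf(0.5 + 0.25 * central)
    inflation = float(np.median(np.abs(core - bias)) / scale_const)
    if inflation <= 0:
        raise ValueError("non-positive inflation estimate")
    return (z - bias) / inflation, (bias, inflation)


def meta_fixed_effect(assocs) -> GeneAssociation:
    """Inverse-variance fixed-effect meta-analysis of per-cohort associations.

    Weights are 1/se^2; the pooled beta is the weighted mean and the pooled
    variance is 1/sum(weights).
    """
    if isinstance(assocs, pd.DataFrame):
        records = assocs.to_dict("records")
        genes = set(assocs["gene"]); exposures = set(assocs["exposure"])
        betas = assocs["beta"].to_numpy(float)
        ses = assocs["se"].to_numpy(float)
        ns = assocs["n"].to_numpy()
        gene = next(iter(genes)); exposure = next(iter(exposures))
    else:
        records = assocs
        genes = {a.gene for a in records}; exposures = {a.exposure for a in records}
        betas = np.array([a.beta for a in records], float)
        ses = np.array([a.se for a in records], float)
        ns = np.array([a.n for a in records])
        gene = records[0].gene; exposure = records[0].exposure
    if len(records) == 0:
        raise ValueError("no associations to meta-analyze")
    if len(genes) > 1 or len(exposures) > 1:
        raise ValueError("all associations must share gene and exposure")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    return GeneAssociation(
        gene=gene, exposure=exposure, beta=beta, se=se, z=z,
        p=float(2.0 * stats.norm.sf(abs(z))), cohort="meta", n=int(ns.sum()),
    )


def meta_fixed_effect_frame(assocs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized fixed-effect meta-analysis, one pooled row per gene."""
    w = 1.0 / assocs["se"] ** 2
    df = assocs.assign(_w=w, _wb=w * assocs["beta"])
    g = df.groupby("gene", sort=False)
    sw = g["_w"].sum()
    beta = g["_wb"].sum() / sw
    se = sw.pow(-0.5)
    z = beta / se
    out = pd.DataFrame({
        "gene": sw.index,
        "exposure": g["exposure"].first().to_numpy(),
        "cohort": "meta",
        "beta": beta.to_numpy(),
        "se": se.to_numpy(),
        "z": z.to_numpy(),
        "p": 2.0 * stats.norm.sf(np.abs(z.to_numpy())),
        "n": g["n"].sum().to_numpy(),
    }).reset_index(drop=True)
    return out


def bonferroni_threshold(alpha: float = 0.05, m: int = 17740) -> float:
    """Family-wise significance threshold alpha/m (default: 17,740 genes)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m
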