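"""One- and two-sample Mendelian randomization with pleiotropy control.

The causal effect of an exposure (lipid level, proxied by a genetic
instrumental variable) on an outcome (gene expression) is estimated by the
Wald ratio — the instrument-outcome association divided by the
instrument-exposure association — with a confidence interval from
Fieller's theorem, which treats the ratio of two normal estimates exactly
via a quadratic.  Pleiotropic instrument variants (those affecting the
outcome through a path other than the exposure) are detected with a
modified Cochran's Q statistic over per-variant Wald ratios and removed
iteratively; Egger regression and multivariable adjustment serve as
sensitivity analyses.  Reverse-direction (expression -> lipid) and
two-sample (summary-statistics) estimates reuse the same ratio machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .twas import CollinearityError, _design, _check_full_rank

__all__ = [
    "MREstimate",
    "PleiotropyReport",
    "EggerResult",
    "wald_ratio_fieller",
    "per_variant_ratios",
    "ivw_estimate",
    "modified_cochran_q",
    "iterative_pleiotropy_prune",
    "egger_regression",
    "multivariable_adjusted_mr",
    "bidirectional_mr",
    "wald_from_summary",
    "bh_fdr",
]


@dataclass
class MREstimate:
    """Wald-ratio causal estimate with a Fieller interval."""

    gene: str
    exposure: str
    wald_beta: float
    fieller_low: float
    fieller_high: float
    robust_se: float
    p: float
    method: str = "wald"
    weak_instrument: bool = False
    pleiotropy: "PleiotropyReport | None" = None


@dataclass
class PleiotropyReport:
    """Modified Cochran's Q decomposition over instrument variants."""

    Q: float
    df: int
    p_Q: float
    q_contributions: np.ndarray
    variant_ids: list
    pooled_beta: float
    pooled_se: float
    removed_variants: list = field(default_factory=list)
    threshold: float | None = None


@dataclass
class EggerResult:
    """Egger regression: intercept estimates average directional pleiotropy."""

    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float


def wald_ratio_fieller(beta_zy, se_zy, beta_zx, se_zx, cov_zxzy: float = 0.0,
                       alpha: float = 0.05, gene: str = "gene",
                       exposure: str = "exposure",
                       method: str = "wald") -> MREstimate:
    """Wald-ratio estimate ``beta_zy / beta_zx`` with Fieller interval.

    The 1-alpha interval is the set of ratios rho for which the linear
    combination ``beta_zy - rho * beta_zx`` is not significantly nonzero,
    i.e. the real roots of

        (bx^2 - z^2 sx^2) rho^2 - 2 (by bx - z^2 c) rho + (by^2 - z^2 sy^2) = 0.

    When the leading coefficient is <= 0 the instrument-exposure
    association is itself indistinguishable from zero (weak instrument);
    the interval is unbounded and the estimate is flagged, with the
    delta-method standard error reported instead of the interval width.
    """
    if se_zy <= 0 or se_zx <= 0:
        raise ValueError("standard errors must be positive")
    if beta_zx == 0:
        raise ZeroDivisionError("instrument-exposure association is exactly zero")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    est = beta_zy / beta_zx
    a = beta_zx ** 2 - z ** 2 * se_zx ** 2
    b = -2.0 * (beta_zy * beta_zx - z ** 2 * cov_zxzy)
    c = beta_zy ** 2 - z ** 2 * se_zy ** 2
    disc = b * b - 4.0 * a * c
    delta_se = float(np.sqrt(
        se_zy ** 2 / beta_zx ** 2
        + beta_zy ** 2 * se_zx ** 2 / beta_zx ** 4
        - 2.0 * beta_zy * cov_zxzy / beta_zx ** 3
    ))
    if a > 0 and disc >= 0:
        r = np.sqrt(disc)
        low = (-b - r) / (2.0 * a)
        high = (-b + r) / (2.0 * a)
        robust_se = float((high - low) / (2.0 * z))
        weak = False
    else:
        # unbounded (a<=0, disc<0: whole line) or exclusive (a<=0, disc>=0)
        low, high = -np.inf, np.inf
        robust_se = delta_se
        weak = True
    zstat = est / robust_se
    return MREstimate(
        gene=gene, exposure=exposure, wald_beta=float(est),
        fieller_low=float(low), fieller_high=float(high),
        robust_se=robust_se, p=float(2.0 * stats.norm.sf(abs(zstat))),
        method=method, weak_instrument=weak,
    )


def per_variant_ratios(gamma, se_gamma, Gamma, se_Gamma) -> pd.DataFrame:
    """First-order delta-method Wald ratios, one per instrument variant.

    For instrument-exposure effect gamma_j and instrument-outcome effect
    Gamma_j, the ratio is Gamma_j / gamma_j with variance
    SE_Gamma^2/gamma^2 + Gamma^2 SE_gamma^2 / gamma^4.
    """
    gamma = np.asarray(gamma, float)
    se_gamma = np.asarray(se_gamma, float)
    Gamma = np.asarray(Gamma, float)
    se_Gamma = np.asarray(se_Gamma, float)
    if np.any(gamma == 0):
        raise ZeroDivisionError("zero instrument-exposure effect")
    beta = Gamma / gamma
    var = se_Gamma ** 2 / gamma ** 2 + Gamma ** 2 * se_gamma ** 2 / gamma ** 4
    return pd.DataFrame({"beta": beta, "se": np.sqrt(var)})


def ivw_estimate(ratios: pd.DataFrame):
    """Inverse-variance-weighted pooling of per-variant ratios -> (beta, se)."""
    w = 1.0 / ratios["se"].to_numpy(float) ** 2
    b = ratios["beta"].to_numpy(float)
    beta = float(np.sum(w * b) / np.sum(w))
    return beta, float(np.sum(w) ** -0.5)


def modified_cochran_q(gamma, se_gamma, Gamma, se_Gamma, variant_ids=None,
                       tol: float = 1e-8, max_iter: int = 100,
                       second_order: bool = False) -> PleiotropyReport:
    """Modified Cochran's Q for heterogeneity among per-variant Wald ratios.

    Weights are evaluated at the pooled estimate rather than at each
    variant's own ratio, w_j = (SE_Gamma^2/gamma^2 +
    beta_pooled^2 SE_gamma^2 / gamma^2)^-1, and the pooled estimate and
    weights are iterated to convergence.  Under no pleiotropy and strong
    instruments, Q is approximately chi-square with J-1 df; individual
    contributions q_j localize outlying (pleiotropic) variants.

    ``second_order=True`` adds the cross term
    2 beta^2 SE_gamma^2 SE_Gamma^2 / gamma^4 to each variance.
    """
    gamma = np.asarray(gamma, float)
    se_gamma = np.asarray(se_gamma, float)
    Gamma = np.asarray(Gamma, float)
    se_Gamma = np.asarray(se_Gamma, float)
    J = gamma.size
    if J < 2:
        raise ValueError("need at least 2 instrument variants")
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(J)]
    beta_j = Gamma / gamma
    w = gamma ** 2 / se_Gamma ** 2  # initial first-stage-only weights
    pooled = float(np.sum(w * beta_j) / np.sum(w))
    for _ in range(max_iter):
        var_j = se_Gamma ** 2 / gamma ** 2 + pooled ** 2 * se_gamma ** 2 / gamma ** 2
        if second_order:
            var_j = var_j + 2.0 * pooled ** 2 * se_gamma ** 2 * se_Gamma ** 2 / gamma ** 4
        w = 1.0 / var_j
        new = float(np.sum(w * beta_j) / np.sum(w))
        if abs(new - pooled) < tol:
            pooled = new
            break
        pooled = new
    else:
        raise RuntimeError("modified Cochran's Q did not converge")
    q_j = w * (beta_j - pooled) ** 2
    Q = float(np.sum(q_j))
    df = J - 1
    return PleiotropyReport(
        Q=Q, df=df, p_Q=float(stats.chi2.sf(Q, df)), q_contributions=q_j,
        variant_ids=list(variant_ids), pooled_beta=pooled,
        pooled_se=float(np.sum(w) ** -0.5),
    )


def iterative_pleiotropy_prune(gamma, se_gamma, Gamma, se_Gamma,
                               variant_ids=None, threshold_p: float = 0.05,
                               second_order: bool = False):
    """Iteratively remove the most heterogeneous variant until no pleiotropy.

    While the Q-test p-value is at or below ``threshold_p`` and more than
    two variants remain, the variant with the largest Q contribution is
    removed (one at a time, order recorded).  Returns the surviving variant
    IDs and the final :class:`PleiotropyReport` including the removal list.

    The default threshold retains variants unless there is nominal evidence
    of pleiotropy (p_Q <= 0.05); a stricter screen (e.g. 0.5) can be
    requested via ``threshold_p``.
    """
    gamma = np.asarray(gamma, float).copy()
    se_gamma = np.asarray(se_gamma, float).copy()
    Gamma = np.asarray(Gamma, float).copy()
    se_Gamma = np.asarray(se_Gamma, float).copy()
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(gamma.size)]
    ids = list(variant_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 variants to allow pruning")
    removed = []
    while True:
        report = modified_cochran_q(gamma, se_gamma, Gamma, se_Gamma,
                                    variant_ids=ids, second_order=second_order)
        if report.p_Q > threshold_p or len(ids) <= 2:
            break
        worst = int(np.argmax(report.q_contributions))
        removed.append(ids[worst])
        keep = np.ones(len(ids), bool)
        keep[worst] = False
        gamma, se_gamma = gamma[keep], se_gamma[keep]
        Gamma, se_Gamma = Gamma[keep], se_Gamma[keep]
        ids = [i for k, i in zip(keep, ids) if k]
    report.removed_variants = removed
    report.threshold = threshold_p
    return ids, report


def egger_regression(gamma, Gamma, se_Gamma) -> EggerResult:
    """Egger regression of outcome betas on exposure betas.

    Variants are oriented so all exposure effects are positive; the
    intercept of the 1/SE^2-weighted regression estimates average
    directional pleiotropy.  Standard errors use multiplicative
    overdispersion scaling (residual variance floored at 1) and the
    intercept test is two-sided on t with J-2 df, the conventional
    random-pleiotropy treatment.
    """
    gamma = np.asarray(gamma, float)
    Gamma = np.asarray(Gamma, float)
    se_Gamma = np.asarray(se_Gamma, float)
    J = gamma.size
    if J < 3:
        raise ValueError("Egger regression needs at least 3 variants")
    sign = np.sign(gamma)
    if np.any(sign == 0):
        raise ZeroDivisionError("zero instrument-exposure effect")
    g = gamma * sign
    G = Gamma * sign
    w = 1.0 / se_Gamma ** 2
    X = np.column_stack([np.ones(J), g])
    WX = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ WX)
    coef = XtWX_inv @ (WX.T @ G)
    resid = G - X @ coef
    phi = float(np.sum(w * resid ** 2) / (J - 2))
    phi = max(phi, 1.0)
    cov = XtWX_inv * phi
    se = np.sqrt(np.diag(cov))
    t = coef[0] / se[0]
    return EggerResult(
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_p=float(2.0 * stats.t.sf(abs(t), J - 2)),
        slope=float(coef[1]), slope_se=float(se[1]),
    )


def _stage_beta(y, x, extra=None, covariates=None, factors=None):
    """OLS coefficient and SE for x in y ~ x + extra + covariates (+factors)."""
    y = np.asarray(y, float)
    n = y.size
    cols = [np.asarray(x, float)]
    if extra is not None:
        cols.append(np.asarray(extra, float))
    Xrest = np.column_stack(cols[1:]) if len(cols) > 1 else None
    X = _design(n, exposure=cols[0], covariates=None, factors=None)
    parts = [X]
    if Xrest is not None:
        parts.append(Xrest)
    if covariates is not None:
        cov = np.asarray(covariates, float)
        parts.append(cov if cov.ndim == 2 else cov[:, None])
    if factors is not None:
        f = getattr(factors, "factors", factors)
        parts.append(np.asarray(f, float))
    Xfull = np.column_stack(parts)
    _check_full_rank(Xfull)
    n, p = Xfull.shape
    XtX_inv = np.linalg.inv(Xfull.T @ Xfull)
    bh = XtX_inv @ (Xfull.T @ y)
    resid = y - Xfull @ bh
    sigma2 = resid @ resid / (n - p)
    return float(bh[1]), float(np.sqrt(sigma2 * XtX_inv[1, 1]))


def multivariable_adjusted_mr(lipid, expression_row, giv, extra_covariate,
                              covariates=None, factors=None, alpha: float = 0.05,
                              gene: str = "gene", exposure: str = "exposure") -> MREstimate:
    """Multivariable MR: both stages refit with an extra covariate.

    The extra covariate is either the dosage of a cis-eQTL variant in the
    instrument (adjusting for direct pleiotropy) or a second, potentially
    pleiotropic instrument score (adjusting for a parallel path).  Raises
    :class:`CollinearityError` when the covariate is nearly collinear with
    the instrument (r^2 >= 0.95).
    """
    g = np.asarray(giv, float)
    e = np.asarray(extra_covariate, float)
    r = float(np.corrcoef(g, e)[0, 1])
    if r * r >= 0.95:
        raise CollinearityError(
            f"extra covariate nearly collinear with instrument (r^2={r*r:.3f})"
        )
    bx, sx = _stage_beta(lipid, g, extra=e, covariates=covariates)
    by, sy = _stage_beta(expression_row, g, extra=e, covariates=covariates,
                         factors=factors)
    est = wald_ratio_fieller(by, sy, bx, sx, alpha=alpha, gene=gene,
                             exposure=exposure, method="multivariable")
    return est


def bidirectional_mr(expression_row, lipid, eqtl_dosage, covariates=None,
                     alpha: float = 0.05, gene: str = "gene",
                     exposure: str = "expression") -> MREstimate:
    """Reverse-direction MR: does transcription affect the lipid level?

    The gene's strongest cis-eQTL dosage proxies its expression: the Wald
    ratio is (variant -> lipid) / (variant -> expression), both adjusted
    for the measured covariates (no latent factors, matching the
    single-variant association model).  Raises when the variant shows no
    expression association to divide by.
    """
    bx, sx = _stage_beta(expression_row, eqtl_dosage, covariates=covariates)
    if bx == 0:
        raise ZeroDivisionError("null eQTL effect on expression")
    by, sy = _stage_beta(lipid, eqtl_dosage, covariates=covariates)
    return wald_ratio_fieller(by, sy, bx, sx, alpha=alpha, gene=gene,
                              exposure=exposure, method="reverse")


def wald_from_summary(eqtl_beta, eqtl_se, outcome_beta, outcome_se,
                      eqtl_alleles=None, outcome_alleles=None,
                      alpha: float = 0.05, gene: str = "gene",
                      exposure: str = "expression") -> MREstimate:
    """Two-sample MR from summary statistics for a single cis-eQTL.

    Harmonizes effect alleles (flipping the outcome beta when the studies
    report opposite alleles), then returns the ratio
    outcome_beta / eqtl_beta with its first-order delta-method standard
    error and a Fieller interval.
    """
    if eqtl_alleles is not None and outcome_alleles is not None:
        ea_x, oa_x = eqtl_alleles
        ea_y, oa_y = outcome_alleles
        if (ea_x, oa_x) == (ea_y, oa_y):
            pass
        elif (ea_x, oa_x) == (oa_y, ea_y):
            outcome_beta = -outcome_beta
        else:
            raise ValueError("unresolvable allele mismatch between studies")
    return wald_ratio_fieller(outcome_beta, outcome_se, eqtl_beta, eqtl_se,
                              alpha=alpha, gene=gene, exposure=exposure,
                              method="two_sample")


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(p_values, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
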