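"""Statistical power for Mendelian randomization with a continuous outcome.

With standardized exposure and outcome, the Wald test of a causal effect
``beta_xy`` using an instrument explaining a fraction ``r2_gx`` of the
exposure variance has non-centrality parameter NCP = n * r2_gx * beta_xy^2;
power is the upper tail of the non-central chi-square(1, NCP) beyond the
central chi-square critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerQuery", "mr_power", "required_sample_size"]

_N_CAP = 2_000_000_000


@dataclass
class PowerQuery:
    n: int
    r2_gx: float
    beta_xy: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.r2_gx < 1:
            raise ValueError("instrument R^2 must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def mr_power(q: PowerQuery) -> float:
    """Power of the MR Wald test for a continuous, standardized outcome."""
    ncp = q.n * q.r2_gx * q.beta_xy ** 2
    crit = stats.chi2.ppf(1.0 - q.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else q.alpha


def required_sample_size(target_power: float, r2_gx: float, beta_xy: float,
                         alpha: float = 0.05) -> int:
    """Smallest n with power >= target (bisection; errors if unreachable)."""
    if beta_xy == 0:
        raise ValueError("power never exceeds alpha for a null effect")
    probe = PowerQuery(n=1, r2_gx=r2_gx, beta_xy=beta_xy, alpha=alpha)
    if not probe.alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")

    def power_at(n):
        return mr_power(PowerQuery(n=n, r2_gx=r2_gx, beta_xy=beta_xy, alpha=alpha))

    lo, hi = 1, 2
    while power_at(hi) < target_power:
        hi *= 2
        if hi > _N_CAP:
            raise ValueError(f"required sample size exceeds {_N_CAP}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi if power_at(lo) < target_power else lo
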