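"""A-priori sample size for the multiple-regression omnibus F test.

The omnibus test of a regression with ``u`` predictors at total sample size
N is a noncentral-F test with numerator df u, denominator df N − u − 1 and
noncentrality λ = f²·N, where f² = R²/(1−R²) is the Cohen effect size.
``required_sample_size`` returns the smallest N whose power reaches the
target; with u = 3, f² = 0.03, α = 0.05 and power 0.80 it returns 368.

The λ = f²·N convention (total sample size) is the default; λ = f²·v
(denominator df) is available via ``noncentrality='error_df'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import InvalidParameterError, NumericalFailureError


@dataclass(frozen=True)
class PowerSpec:
    """Design of the omnibus test: predictors, effect size, alpha, target power."""

    u: int = 3
    f2: float = 0.03
    alpha: float = 0.05
    power: float = 0.80
    noncentrality: str = "total"  # 'total': λ = f²·N; 'error_df': λ = f²·(N−u−1)

    def __post_init__(self):
        if self.u < 1:
            raise InvalidParameterError(f"u must be >= 1, got {self.u}")
        if not (math.isfinite(self.f2) and self.f2 >= 0):
            raise InvalidParameterError(f"f2 must be non-negative, got {self.f2}")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise InvalidParameterError(f"target power must be in (0,1), got {self.power}")
        if self.noncentrality not in {"total", "error_df"}:
            raise InvalidParameterError(f"unknown noncentrality convention {self.noncentrality!r}")


def achieved_power(spec: PowerSpec, n: int) -> float:
    """Power of the omnibus noncentral-F test at total sample size ``n``."""
    if n <= spec.u + 1:
        raise InvalidParameterError(f"need n > u + 1 = {spec.u + 1}, got {n}")
    v = n - spec.u - 1
    lam = spec.f2 * (n if spec.noncentrality == "total" else v)
    crit = stats.f.isf(spec.alpha, spec.u, v)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(crit, spec.u, v, lam))


def required_sample_size(spec: PowerSpec, max_n: int = 1_000_000) -> int:
    """Smallest total N whose omnibus power meets the target.

    Power is monotone increasing in N for fixed spec, so the minimum is
    located by doubling then bisection, with a final downward walk as a
    guard against numerical plateaus.
    """
    if spec.f2 <= 0:
        raise InvalidParameterError("required_sample_size needs f2 > 0")
    lo = spec.u + 2
    if achieved_power(spec, lo) >= spec.power:
        return lo
    hi = lo
    while achieved_power(spec, hi) < spec.power:
        hi *= 2
        if hi > max_n:
            raise NumericalFailureError(
                f"no N <= {max_n} reaches power {spec.power} for f2={spec.f2}"
            )
    while hi - lo > 1:  # invariant: power(lo) < target <= power(hi)
        mid = (lo + hi) // 2
        if achieved_power(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    while hi - 1 > spec.u + 1 and achieved_power(spec, hi - 1) >= spec.power:
        hi -= 1
    return hi


def power_curve(spec: PowerSpec, n_values) -> list[tuple[int, float]]:
    """(N, power) pairs for reporting."""
    return [(int(n), achieved_power(spec, int(n))) for n in n_values]
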