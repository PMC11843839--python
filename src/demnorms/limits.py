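"""Normality gating, non-parametric tolerance limits, equivalent scores
and percentile tables on adjusted scores.

Normative cutoffs follow the Italian equivalent-score tradition: on the
adjusted score, ordered best-to-worst, one-sided non-parametric tolerance
limits bound the population quantile separating normal from abnormal
performance.  For coverage p and confidence γ, with B the exact binomial
CDF of Bin(n, p):

* outer limit (OTL) rank = smallest k with B(k−1) ≥ γ — the observation at
  this rank exceeds the p-quantile with confidence at least γ;
* inner limit (ITL) rank = smallest k with B(k−1) > 1 − γ.

At n = 521 and p = γ = 0.95 these are the 488th and 504th best
observations.  Scores worse than the OTL get equivalent score (ES) 0,
scores better than the median ES 4, with three intermediate rank-based
bands; percentile tables report, for each printed level q, the adjusted
score with q% of the normative sample performing worse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    InsufficientSampleError,
    InvalidParameterError,
)

PERCENTILE_LEVELS = (99, 95, 90, 85, 80, 75, 70, 65, 60, 55, 50,
                     45, 40, 35, 30, 25, 20, 15, 10, 5, 4, 3, 2, 1)

SKEW_THRESHOLD = 1.0
KURTOSIS_THRESHOLD = 3.0  # Fisher excess


@dataclass(frozen=True)
class NormalityResult:
    """Skewness/kurtosis screen used instead of Shapiro-Wilk at large n."""

    skewness: float
    excess_kurtosis: float
    skew_flag: bool
    kurtosis_flag: bool

    @property
    def verdict(self) -> str:
        return "non-normal" if (self.skew_flag or self.kurtosis_flag) else "normal"


def normality_check(values) -> NormalityResult:
    """Flag skewness beyond |1| or excess kurtosis beyond |3|."""
    v = np.asarray(values, float)
    if v.size < 4:
        raise InvalidParameterError(f"normality check needs n >= 4, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateInputError("zero-variance sample: normality undefined")
    skew = float(stats.skew(v))
    kurt = float(stats.kurtosis(v, fisher=True))
    return NormalityResult(
        skewness=skew,
        excess_kurtosis=kurt,
        skew_flag=abs(skew) > SKEW_THRESHOLD,
        kurtosis_flag=abs(kurt) > KURTOSIS_THRESHOLD,
    )


@dataclass(frozen=True)
class ToleranceSpec:
    """Coverage p, confidence γ and the direction of 'worse'."""

    coverage: float = 0.95
    confidence: float = 0.95
    direction: str = "higher_worse"  # all four DEM subtests: lower is better

    def __post_init__(self):
        if not 0 < self.coverage < 1:
            raise InvalidParameterError(f"coverage must be in (0,1), got {self.coverage}")
        if not 0 < self.confidence < 1:
            raise InvalidParameterError(f"confidence must be in (0,1), got {self.confidence}")
        if self.direction not in {"higher_worse", "lower_worse"}:
            raise InvalidParameterError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class ToleranceResult:
    itl_rank: int
    otl_rank: int
    itl_value: float
    otl_value: float


def minimal_n(spec: ToleranceSpec) -> int:
    """Smallest n for which the OTL exists: 1 − p^n ≥ γ."""
    return math.ceil(math.log(1.0 - spec.confidence) / math.log(spec.coverage))


def tolerance_ranks(n: int, spec: ToleranceSpec | None = None) -> tuple[int, int]:
    """(ITL rank, OTL rank), counting from the best observation upward.

    Raises
    ------
    InsufficientSampleError
        When no rank k <= n satisfies the OTL condition; the error reports
        the minimal usable n.
    """
    spec = spec or ToleranceSpec()
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    cdf = stats.binom.cdf(np.arange(n), n, spec.coverage)  # B(k-1) for k = 1..n
    otl_hits = np.nonzero(cdf >= spec.confidence)[0]
    if otl_hits.size == 0:
        raise InsufficientSampleError(
            f"no outer tolerance limit at n={n} for coverage {spec.coverage}, "
            f"confidence {spec.confidence}; need n >= {minimal_n(spec)}",
            min_n=minimal_n(spec),
        )
    itl_hits = np.nonzero(cdf > 1.0 - spec.confidence)[0]
    return int(itl_hits[0]) + 1, int(otl_hits[0]) + 1


def tolerance_limits(adjusted, spec: ToleranceSpec | None = None) -> ToleranceResult:
    """Score values at the ITL/OTL ranks of a sample (stable sort, ties kept)."""
    spec = spec or ToleranceSpec()
    v = np.asarray(adjusted, float)
    itl_rank, otl_rank = tolerance_ranks(v.size, spec)
    ordered = np.sort(v, kind="stable")
    if spec.direction == "lower_worse":
        ordered = ordered[::-1]
    return ToleranceResult(
        itl_rank=itl_rank,
        otl_rank=otl_rank,
        itl_value=float(ordered[itl_rank - 1]),
        otl_value=float(ordered[otl_rank - 1]),
    )


@dataclass(frozen=True)
class NormTable:
    """Cutoffs for one subtest: OTL, ES band bounds, percentile grid.

    ``es_bounds`` holds the four band edges in the *worse* direction,
    ES0..ES3: a score at or beyond ``es_bounds[j]`` (towards worse) earns at
    most ES j.  Scores strictly better than ``es_bounds[3]`` (the median
    bound) earn ES 4.
    """

    subtest: str
    direction: str
    otl_value: float
    itl_value: float | None
    es_bounds: tuple[float, float, float, float]
    percentile_levels: tuple[int, ...] = PERCENTILE_LEVELS
    percentile_values: tuple[float, ...] = ()
    n: int | None = None

    def _worse_or_equal(self, a: float, b: float) -> bool:
        return a >= b if self.direction == "higher_worse" else a <= b

    def assign_es(self, score: float) -> tuple[int, list[str]]:
        """Equivalent score 0-4 plus flags (duplicated-band ambiguity)."""
        flags = []
        es = 4
        for j, bound in enumerate(self.es_bounds):
            if self._worse_or_equal(score, bound):
                es = j
                break
        if (
            self.es_bounds[2] == self.es_bounds[3]
            and es == 2
            and not self._worse_or_equal(score, self.es_bounds[1])
        ):
            flags.append("es_ambiguous")
        return es, flags


def assign_percentile(table: NormTable, score: float) -> tuple[int, bool]:
    """Highest printed level whose table value the score meets or beats.

    Returns ``(level, out_of_range)``; scores better than the 99th-level
    value clamp to 99 and scores worse than the 1st-level value clamp to 1,
    both flagged.
    """
    if not table.percentile_values:
        raise InvalidParameterError(f"norm table for {table.subtest} has no percentile grid")
    levels = table.percentile_levels
    values = table.percentile_values
    better_or_equal = (lambda s, v: s <= v) if table.direction == "higher_worse" else (lambda s, v: s >= v)
    for level, value in zip(levels, values):  # levels printed best-first
        if better_or_equal(score, value):
            strictly_better_than_top = level == levels[0] and score != value and better_or_equal(score, value)
            return level, bool(strictly_better_than_top)
    return levels[-1], True


def _percentile_grid(v: np.ndarray, direction: str, levels) -> tuple[float, ...]:
    # level q = score with q% of the sample performing worse
    q = np.asarray(levels, float) / 100.0
    probs = 1.0 - q if direction == "higher_worse" else q
    return tuple(float(x) for x in np.quantile(v, probs, method="linear"))


def build_norm_table(
    adjusted,
    spec: ToleranceSpec | None = None,
    es_policy: str = "rank_thirds",
) -> NormTable:
    """Derive the full norm table for one subtest from adjusted scores.

    The default ES policy places the ES0 bound at the OTL, the ES4 bound at
    the median order statistic, and the ES1/ES2 bounds at the ranks one and
    two thirds of the way from the median rank to the OTL rank.
    """
    spec = spec or ToleranceSpec()
    v = np.asarray(adjusted, float)
    tol = tolerance_limits(v, spec)
    n = v.size
    ordered = np.sort(v, kind="stable")
    if spec.direction == "lower_worse":
        ordered = ordered[::-1]
    if es_policy != "rank_thirds":
        raise InvalidParameterError(f"unknown ES policy {es_policy!r}")
    median_rank = (n + 1) // 2
    if tol.otl_rank - median_rank < 3:
        raise DegenerateInputError("sample too small for distinct equivalent-score bands")
    r1 = median_rank + round((tol.otl_rank - median_rank) * 2 / 3)  # ES1 bound
    r2 = median_rank + round((tol.otl_rank - median_rank) * 1 / 3)  # ES2 bound
    bounds = (
        float(ordered[tol.otl_rank - 1]),
        float(ordered[r1 - 1]),
        float(ordered[r2 - 1]),
        float(ordered[median_rank - 1]),
    )
    if len(set(bounds)) < 4:
        warnings.warn("tied equivalent-score bounds: bands are not all distinct", stacklevel=2)
    return NormTable(
        subtest="",
        direction=spec.direction,
        otl_value=tol.otl_value,
        itl_value=tol.itl_value,
        es_bounds=bounds,
        percentile_levels=tuple(PERCENTILE_LEVELS),
        percentile_values=_percentile_grid(v, spec.direction, PERCENTILE_LEVELS),
        n=n,
    )
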