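"""Demographic predictor selection for norming regressions.

The norming procedure regresses each DEM raw score on demographic
predictors (age, education, sex).  Two nested searches are involved:

1. *Transform search* — for each continuous predictor, a menu of monotone
   transforms (identity, square, cube, log, sqrt, inverse) is screened by
   bivariate OLS; the transform with the lowest BIC wins.
2. *Subset selection* — all seven non-empty predictor subsets, each in its
   best transform, are fitted; the lowest-BIC model is retained only if its
   omnibus F test is significant (p < 0.05).

BIC here is ``k ln(n) − 2 LL`` with k counting the intercept and the
residual variance along with the slopes, matching the convention of the
published model-comparison table (a two-predictor model has K = 4).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateInputError, InvalidParameterError, NumericalFailureError

logger = logging.getLogger(__name__)

SUBTESTS = ("vt", "aht", "ratio", "errors")
PREDICTORS = ("age", "education", "sex")
DECADES = [(20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79)]

_PRED_LABEL = {"age": "Age", "education": "Edu", "sex": "Sex"}

TRANSFORMS = {
    "identity": lambda x: x,
    "square": lambda x: x**2,
    "cube": lambda x: x**3,
    "log": np.log,
    "sqrt": np.sqrt,
    "inverse": lambda x: 1.0 / x,
}
#: transforms requiring strictly positive input
_POSITIVE_ONLY = {"log", "inverse"}
_NONNEGATIVE_ONLY = {"sqrt"}

DEFAULT_CANDIDATES = {
    "age": ("identity", "square", "cube", "log", "sqrt", "inverse"),
    "education": ("identity", "square", "cube", "log", "sqrt", "inverse"),
    "sex": ("identity",),
}


@dataclass(frozen=True)
class TransformSpec:
    """One predictor together with the transform applied to it."""

    predictor: str
    transform: str = "identity"

    def __post_init__(self):
        if self.predictor not in PREDICTORS:
            raise InvalidParameterError(f"unknown predictor {self.predictor!r}")
        if self.transform not in TRANSFORMS:
            raise InvalidParameterError(f"unknown transform {self.transform!r}")
        if self.predictor == "sex" and self.transform != "identity":
            raise InvalidParameterError("sex admits only the identity transform")

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, float)
        if self.transform in _POSITIVE_ONLY and np.any(v <= 0):
            raise DegenerateInputError(f"{self.transform} undefined for non-positive {self.predictor}")
        if self.transform in _NONNEGATIVE_ONLY and np.any(v < 0):
            raise DegenerateInputError(f"sqrt undefined for negative {self.predictor}")
        return TRANSFORMS[self.transform](v)


@dataclass
class FittedModel:
    """One fitted norming regression and its bookkeeping."""

    subtest: str
    label: str
    transforms: dict  # predictor -> transform name
    intercept: float
    params: dict  # predictor -> coefficient on the transformed predictor
    bse: dict  # predictor -> standard error
    llf: float
    k: int  # slopes + intercept + residual variance
    nobs: int
    pvalue: float  # omnibus F vs intercept-only
    r_squared: float

    @property
    def bic(self) -> float:
        return bic(self.llf, self.k, self.nobs)

    def specs(self) -> list[TransformSpec]:
        return [TransformSpec(p, t) for p, t in self.transforms.items()]


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, ``k ln(n) − 2 LL``."""
    if n < 1:
        raise InvalidParameterError(f"BIC needs n >= 1, got {n}")
    if k < 1:
        raise InvalidParameterError(f"BIC needs k >= 1, got {k}")
    return k * math.log(n) - 2.0 * log_likelihood


def bic_weights(deltas) -> np.ndarray:
    """Model probabilities from BIC differences: exp(−Δ/2), normalised."""
    d = np.asarray(deltas, float)
    if d.size == 0:
        raise InvalidParameterError("empty delta-BIC set")
    lik = np.exp(-d / 2.0)
    return lik / lik.sum()


def compare_models(fits: list[FittedModel], n: int | None = None) -> pd.DataFrame:
    """Rank candidate models by BIC with likelihoods and weights.

    Returns a frame sorted by ascending BIC with columns
    ``model, k, bic, delta_bic, model_lik, bic_wt, log_lik, cum_wt``.
    """
    if not fits:
        raise InvalidParameterError("compare_models needs at least one fitted model")
    if n is None:
        n = fits[0].nobs
    rows = pd.DataFrame(
        {
            "model": [f.label for f in fits],
            "k": [f.k for f in fits],
            "log_lik": [f.llf for f in fits],
            "bic": [bic(f.llf, f.k, n) for f in fits],
        }
    ).sort_values("bic", kind="stable", ignore_index=True)
    rows["delta_bic"] = rows["bic"] - rows["bic"].iloc[0]
    rows["model_lik"] = np.exp(-rows["delta_bic"] / 2.0)
    rows["bic_wt"] = rows["model_lik"] / rows["model_lik"].sum()
    rows["cum_wt"] = rows["bic_wt"].cumsum()
    return rows[["model", "k", "bic", "delta_bic", "model_lik", "bic_wt", "log_lik", "cum_wt"]]


def _frame(cohort) -> pd.DataFrame:
    return cohort.frame if hasattr(cohort, "frame") else cohort


def predictor_values(frame: pd.DataFrame, predictor: str) -> np.ndarray:
    if predictor == "age":
        return frame["age"].to_numpy(float)
    if predictor == "education":
        return frame["education_years"].to_numpy(float)
    if predictor == "sex":
        return (frame["sex"].astype(str).str.upper().str[0] == "M").to_numpy(float)
    raise InvalidParameterError(f"unknown predictor {predictor!r}")


def _ols(y: np.ndarray, cols: dict[str, np.ndarray], subtest: str, label: str) -> FittedModel:
    X = np.column_stack(list(cols.values())) if cols else np.empty((len(y), 0))
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise NumericalFailureError(f"singular design for predictor set {list(cols)} on {subtest}")
    res = sm.OLS(y, exog).fit()
    names = list(cols)
    return FittedModel(
        subtest=subtest,
        label=label,
        transforms={},
        intercept=float(res.params[0]),
        params={p: float(b) for p, b in zip(names, res.params[1:])},
        bse={p: float(s) for p, s in zip(names, res.bse[1:])},
        llf=float(res.llf),
        k=len(names) + 2,
        nobs=int(res.nobs),
        pvalue=float(res.f_pvalue) if names else float("nan"),
        r_squared=float(res.rsquared),
    )


def search_transforms(
    cohort,
    subtest: str,
    candidates: dict[str, tuple] | list[TransformSpec] | None = None,
) -> dict[str, TransformSpec]:
    """Best transform per predictor by bivariate-regression BIC.

    Candidates undefined on the data (log of a non-positive value) or with
    zero variance are skipped with a warning; a predictor whose every
    candidate is skipped is absent from the result.
    """
    frame = _frame(cohort)
    y = frame[subtest].to_numpy(float)
    if candidates is None:
        menu = {p: list(t) for p, t in DEFAULT_CANDIDATES.items()}
    elif isinstance(candidates, dict):
        menu = {p: list(t) for p, t in candidates.items()}
    else:
        menu = {}
        for spec in candidates:
            menu.setdefault(spec.predictor, []).append(spec.transform)
    best: dict[str, TransformSpec] = {}
    for predictor, names in menu.items():
        x = predictor_values(frame, predictor)
        scored = []
        for name in names:
            spec = TransformSpec(predictor, name)
            try:
                t = spec.apply(x)
            except DegenerateInputError as exc:
                warnings.warn(f"skipping {predictor}/{name}: {exc}", stacklevel=2)
                continue
            if np.ptp(t) == 0 or not np.all(np.isfinite(t)):
                warnings.warn(
                    f"skipping {predictor}/{name}: transformed predictor is degenerate",
                    stacklevel=2,
                )
                continue
            fit = _ols(y, {predictor: t}, subtest, f"{_PRED_LABEL[predictor]}[{name}]")
            scored.append((fit.bic, name))
        if scored:
            scored.sort()
            best[predictor] = TransformSpec(predictor, scored[0][1])
            logger.debug("%s: best transform for %s is %s", subtest, predictor, scored[0][1])
    return best


def _subset_label(preds: tuple[str, ...]) -> str:
    order = [p for p in PREDICTORS if p in preds]
    return " + ".join(_PRED_LABEL[p] for p in order)


def fit_all_subsets(
    cohort, subtest: str, transforms: dict[str, TransformSpec]
) -> list[FittedModel]:
    """Fit every non-empty subset of the available predictors."""
    frame = _frame(cohort)
    y = frame[subtest].to_numpy(float)
    if not transforms:
        raise InvalidParameterError("no usable predictors: transform search returned nothing")
    preds = [p for p in PREDICTORS if p in transforms]
    if len(frame) <= len(preds) + 2:
        raise InvalidParameterError("cohort smaller than the largest candidate parameter count")
    fits = []
    for r in range(1, len(preds) + 1):
        for subset in combinations(preds, r):
            cols = {p: transforms[p].apply(predictor_values(frame, p)) for p in subset}
            fit = _ols(y, cols, subtest, _subset_label(subset))
            fit.transforms = {p: transforms[p].transform for p in subset}
            fits.append(fit)
    return fits


def select_best_model(
    cohort,
    subtest: str,
    transforms: dict[str, TransformSpec] | None = None,
) -> FittedModel | None:
    """Lowest-BIC predictor subset, kept only if its omnibus test is significant.

    Returns ``None`` when the winning model's omnibus F has p >= 0.05 —
    the subtest is then normed without demographic correction.
    """
    if transforms is None:
        transforms = search_transforms(cohort, subtest)
    fits = fit_all_subsets(cohort, subtest, transforms)
    best = min(fits, key=lambda f: f.bic)
    if not (best.pvalue < 0.05):
        logger.info("%s: best model %s not significant (p=%.3f)", subtest, best.label, best.pvalue)
        return None
    return best


@dataclass
class Descriptives:
    """Decade-wise descriptives, mixed-method correlations, and one-way ANOVAs."""

    decade_table: pd.DataFrame  # columns: subtest, decade, n, mean, sd
    correlations: pd.DataFrame  # square, variables x variables
    anova: pd.DataFrame  # columns: subtest, F, df_between, df_within, p, eta_sq


def _pairwise_corr(frame: pd.DataFrame) -> pd.DataFrame:
    cols = {
        "age": frame["age"].to_numpy(float),
        "education": frame["education_years"].to_numpy(float),
        "sex": predictor_values(frame, "sex"),
        "vt": frame["vt"].to_numpy(float),
        "aht": frame["aht"].to_numpy(float),
        "ratio": frame["ratio"].to_numpy(float),
        "errors": frame["errors"].to_numpy(float),
    }
    names = list(cols)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        if "errors" in (a, b):
            r = stats.spearmanr(cols[a], cols[b]).statistic
        else:
            # Pearson; with the 0/1 sex coding this is the point-biserial r
            r = stats.pearsonr(cols[a], cols[b]).statistic
        out.loc[a, b] = out.loc[b, a] = r
    return out


def _decade_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def cohort_descriptives(cohort) -> Descriptives:
    """Decade means/SDs, correlation matrix and ANOVA by age decade.

    Correlations use Pearson for continuous pairs, point-biserial for sex
    versus continuous, and Spearman for any pair involving the error count.
    The ANOVA reports partial eta squared ``SSB / (SSB + SSW)``; decades with
    fewer than two members are excluded with a warning.
    """
    frame = _frame(cohort)
    if len(frame) == 0:
        raise InvalidParameterError("empty cohort")
    decade = pd.cut(
        frame["age"],
        bins=[lo for lo, _ in DECADES] + [DECADES[-1][1] + 1],
        right=False,
        labels=[_decade_label(lo, hi) for lo, hi in DECADES],
    )
    rows = []
    for sub in SUBTESTS:
        g = frame[sub].groupby(decade, observed=True)
        for label, vals in g:
            rows.append(
                {"subtest": sub, "decade": str(label), "n": len(vals),
                 "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")}
            )
    decade_table = pd.DataFrame(rows)

    anova_rows = []
    for sub in SUBTESTS:
        groups = []
        for label in decade.cat.categories:
            vals = frame.loc[decade == label, sub].to_numpy(float)
            if len(vals) < 2:
                if len(vals):
                    warnings.warn(f"ANOVA on {sub}: decade {label} has < 2 members, excluded", stacklevel=2)
                continue
            groups.append(vals)
        if len(groups) < 2:
            raise DegenerateInputError(f"ANOVA on {sub}: fewer than two usable decades")
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb = len(groups) - 1
        dfw = sum(len(g) for g in groups) - len(groups)
        if ssw == 0 and ssb == 0:
            f_stat, p = 0.0, 1.0
        elif ssw == 0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat = (ssb / dfb) / (ssw / dfw)
            p = float(stats.f.sf(f_stat, dfb, dfw))
        eta = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
        anova_rows.append(
            {"subtest": sub, "F": float(f_stat), "df_between": dfb, "df_within": dfw,
             "p": p, "eta_sq": float(eta)}
        )
    return Descriptives(
        decade_table=decade_table,
        correlations=_pairwise_corr(frame),
        anova=pd.DataFrame(anova_rows),
    )
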