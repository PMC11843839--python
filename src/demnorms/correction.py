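"""Demographic correction equations, grids, and adjusted scores.

A selected norming regression is turned into a *correction equation* by
mean-centering each transformed predictor and reversing the sign of its
coefficient:

    correction(d) = − Σ_i  β_i · ( t_i(d) − mean t_i )

Adding the correction to the raw score removes the modelled demographic
effect: a participant at the normative-sample means is left untouched,
younger/more-educated participants are penalised, older/less-educated ones
are credited.  Correction *grids* tabulate the equation at round age and
education anchors for hand scoring; exact-equation scoring is the default.

The shipped adult norms use the published coefficients: VT and AHT depend on
age cubed and inverse education, Ratio on age cubed only, and errors on
inverse education and sex (male = 1, female = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import Demographics
from .exceptions import (
    ConfigurationError,
    DomainError,
    InvalidParameterError,
    NumericalFailureError,
)
from .scoring import RawScores
from .selection import FittedModel, TransformSpec, predictor_values

AGE_RANGE = (20.0, 79.0)  # normative age span; outside it we extrapolate
DEFAULT_AGE_ANCHORS = tuple(range(20, 80, 5))
DEFAULT_EDU_ANCHORS = (8, 13, 16, 18, 21)
DEFAULT_SEX_CODING = {"M": 1.0, "F": 0.0}


class ExtrapolationWarning(UserWarning):
    """A correction was evaluated outside the normative demographic range."""


def round_half_up(x: float, decimals: int) -> float:
    """Round to `decimals` places with ties away from zero (grid convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CorrectionTerm:
    """One centered, reversed regression term of a correction equation."""

    predictor: str
    transform: str
    coef: float  # original regression slope on the transformed predictor
    center: float  # normative-sample mean of the transformed predictor

    def spec(self) -> TransformSpec:
        return TransformSpec(self.predictor, self.transform)


@dataclass(frozen=True)
class CorrectionEquation:
    """Reversed-coefficient correction for one subtest."""

    subtest: str
    terms: tuple[CorrectionTerm, ...]
    sex_coding: dict = None

    def __post_init__(self):
        if self.sex_coding is None:
            object.__setattr__(self, "sex_coding", dict(DEFAULT_SEX_CODING))

    def _predictor_array(self, predictor, age, education, sex_code):
        if predictor == "age":
            return age
        if predictor == "education":
            return education
        return sex_code

    def values(self, age, education, sex) -> np.ndarray:
        """Vectorised correction over parallel arrays of demographics."""
        age = np.asarray(age, float)
        education = np.asarray(education, float)
        if np.any(education < 1):
            raise DomainError("education must be >= 1 year")
        sex_code = np.array([self.sex_coding[str(s).upper()[0]] for s in np.atleast_1d(sex)], float)
        if np.any((age < AGE_RANGE[0]) | (age > AGE_RANGE[1])):
            warnings.warn(
                f"{self.subtest}: age outside the normative range {AGE_RANGE}; extrapolating",
                ExtrapolationWarning,
                stacklevel=2,
            )
        total = np.zeros(np.broadcast(age, education, sex_code).shape, float)
        for term in self.terms:
            x = self._predictor_array(term.predictor, age, education, sex_code)
            t = term.spec().apply(x) if term.predictor != "sex" else x
            total -= term.coef * (t - term.center)
        return total


def correction_value(eq: CorrectionEquation, demo: Demographics) -> float:
    """The additive correction for one participant's demographics."""
    return float(eq.values([demo.age], [demo.education], [demo.sex])[0])


def derive_correction(cohort, model: FittedModel) -> CorrectionEquation:
    """Build the correction equation implied by a selected norming model.

    The model is refitted on mean-centered transformed predictors (slopes
    are unchanged by centering; the refit is a numerical cross-check) and
    the slopes are stored with reversed sign convention together with the
    centering constants.
    """
    import statsmodels.api as sm

    frame = cohort.frame if hasattr(cohort, "frame") else cohort
    y = frame[model.subtest].to_numpy(float)
    terms = []
    centered_cols = []
    for predictor, transform in model.transforms.items():
        spec = TransformSpec(predictor, transform)
        t = spec.apply(predictor_values(frame, predictor))
        if np.ptp(t) == 0:
            raise NumericalFailureError(
                f"zero-variance transformed predictor {predictor}/{transform}"
            )
        center = float(t.mean())
        centered_cols.append(t - center)
        terms.append((predictor, transform, center))
    exog = sm.add_constant(np.column_stack(centered_cols), has_constant="add")
    res = sm.OLS(y, exog).fit()
    eq_terms = tuple(
        CorrectionTerm(predictor=p, transform=tr, coef=float(b), center=c)
        for (p, tr, c), b in zip(terms, res.params[1:])
    )
    return CorrectionEquation(subtest=model.subtest, terms=eq_terms)


@dataclass(frozen=True)
class CorrectionGrid:
    """A rounded lookup table of corrections at demographic anchors."""

    subtest: str
    table: pd.DataFrame  # index: row anchors, columns: column anchors
    row_var: str
    col_var: str
    precision: int

    def nearest(self, row_value, col_value) -> float:
        """Grid cell at the anchors nearest to the requested demographics."""
        def _closest(anchors, v):
            arr = list(anchors)
            if isinstance(v, str) or isinstance(arr[0], str):
                return v
            return min(arr, key=lambda a: (abs(float(a) - float(v)), float(a)))

        r = _closest(self.table.index, row_value)
        c = _closest(self.table.columns, col_value)
        return float(self.table.loc[r, c])


def emit_grid(
    eq: CorrectionEquation,
    row_anchors,
    col_anchors,
    precision: int = 2,
    row_var: str = "education",
    col_var: str = "age",
) -> CorrectionGrid:
    """Tabulate a correction equation at anchor demographics.

    Cells are rounded half-away-from-zero to ``precision`` decimals; the
    default anchors (ages 20-75 by 5, educations 8/13/16/18/21) reproduce
    the published grids.
    """
    row_anchors = list(row_anchors)
    col_anchors = list(col_anchors)
    if not row_anchors or not col_anchors:
        raise InvalidParameterError("anchor sets must be non-empty")
    defaults = {"age": 50.0, "education": 13.0, "sex": "F"}
    cells = np.empty((len(row_anchors), len(col_anchors)))
    for i, r in enumerate(row_anchors):
        for j, c in enumerate(col_anchors):
            demo = dict(defaults)
            demo[row_var] = r
            demo[col_var] = c
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                v = eq.values([demo["age"]], [demo["education"]], [demo["sex"]])[0]
            cells[i, j] = round_half_up(v, precision)
    table = pd.DataFrame(cells, index=row_anchors, columns=col_anchors)
    return CorrectionGrid(eq.subtest, table, row_var, col_var, precision)


def default_grid(eq: CorrectionEquation) -> CorrectionGrid:
    """The published grid layout appropriate to a subtest's predictors."""
    preds = {t.predictor for t in eq.terms}
    if preds == {"age"}:
        return emit_grid(eq, ["ratio"], DEFAULT_AGE_ANCHORS, 2, row_var="_label", col_var="age")
    if "sex" in preds:
        return emit_grid(eq, DEFAULT_EDU_ANCHORS, ["M", "F"], 1, row_var="education", col_var="sex")
    return emit_grid(eq, DEFAULT_EDU_ANCHORS, DEFAULT_AGE_ANCHORS, 2)


@dataclass(frozen=True)
class AdjustedScores:
    """Raw scores plus corrections; may be negative (errors especially)."""

    vt: float | None = None
    aht: float | None = None
    ratio: float | None = None
    errors: float | None = None


def adjust_scores(
    raw: RawScores,
    demo: Demographics,
    equations: dict[str, CorrectionEquation],
) -> AdjustedScores:
    """Adjusted score = raw score + correction, per subtest."""
    out = {}
    for sub in ("vt", "aht", "ratio", "errors"):
        r = getattr(raw, sub)
        if r is None:
            out[sub] = None
            continue
        if sub not in equations:
            raise ConfigurationError(f"no correction equation for subtest {sub!r}")
        out[sub] = r + correction_value(equations[sub], demo)
    return AdjustedScores(**out)


def adjust_cohort(cohort, equations: dict[str, CorrectionEquation]) -> pd.DataFrame:
    """Vectorised adjustment of a whole cohort frame."""
    frame = cohort.frame if hasattr(cohort, "frame") else cohort
    out = {}
    for sub, eq in equations.items():
        out[sub] = frame[sub].to_numpy(float) + eq.values(
            frame["age"], frame["education_years"], frame["sex"].to_numpy()
        )
    return pd.DataFrame(out, index=frame.index)
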