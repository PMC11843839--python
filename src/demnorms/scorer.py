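"""Scoring individual adults against a norms asset.

Mirrors the study's companion web scorer: demographics and raw scores in;
demographically adjusted scores, equivalent scores (ES 0-4), percentile
levels and interpretation flags out.  Correction uses the exact equations
by default; ``mode='grid'`` reproduces hand scoring from the printed grids
(nearest age/education anchors), which can differ from the exact equations
by up to about a quarter of a score unit at mid-anchor demographics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Demographics
from .correction import (
    CorrectionGrid,
    ExtrapolationWarning,
    correction_value,
    default_grid,
    round_half_up,
)
from .exceptions import CohortParseError, ConfigurationError, DomainError
from .limits import assign_percentile
from .norms import NormsAsset
from .scoring import RawScores
from .selection import SUBTESTS

EDUCATION_RANGE = (5.0, 27.0)  # normative education span
AGE_RANGE = (20.0, 79.0)


@dataclass
class ScoreReport:
    """Per-subtest adjusted scores, ES, percentile levels and flags."""

    demographics: Demographics
    adjusted: dict = field(default_factory=dict)  # subtest -> rounded adjusted score
    es: dict = field(default_factory=dict)  # subtest -> 0..4
    percentile: dict = field(default_factory=dict)  # subtest -> printed level
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        row = {
            "age": self.demographics.age,
            "education_years": self.demographics.education,
            "sex": self.demographics.sex,
        }
        for sub in SUBTESTS:
            row[f"{sub}_adjusted"] = self.adjusted.get(sub)
            row[f"{sub}_es"] = self.es.get(sub)
            row[f"{sub}_percentile"] = self.percentile.get(sub)
        row["flags"] = ";".join(self.flags)
        return row


def _grids(norms: NormsAsset) -> dict[str, CorrectionGrid]:
    return {sub: default_grid(eq) for sub, eq in norms.equations.items()}


def score_participant(
    demo: Demographics,
    raw: RawScores,
    norms: NormsAsset,
    mode: str = "equation",
) -> ScoreReport:
    """Score one adult against a norms asset.

    Subtests absent from ``raw`` yield a partial report with a
    ``missing:<subtest>`` flag.  Demographics outside the normative span
    are scored with an extrapolation flag; education below 1 year is a
    domain error.
    """
    if mode not in {"equation", "grid"}:
        raise ConfigurationError(f"unknown scoring mode {mode!r}")
    if demo.education < 1:
        raise DomainError("education must be >= 1 year")
    report = ScoreReport(demographics=demo)
    if not AGE_RANGE[0] <= demo.age <= AGE_RANGE[1]:
        report.flags.append("extrapolated_age")
    if not EDUCATION_RANGE[0] <= demo.education <= EDUCATION_RANGE[1]:
        report.flags.append("extrapolated_education")
    grids = _grids(norms) if mode == "grid" else None
    for sub in SUBTESTS:
        value = getattr(raw, sub)
        if value is None:
            report.flags.append(f"missing:{sub}")
            continue
        eq = norms.equations[sub]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)  # already flagged above
            if mode == "grid":
                grid = grids[sub]
                lookup = {
                    "age": demo.age,
                    "education": demo.education,
                    "sex": demo.sex,
                    "_label": None,
                }
                row_value = lookup.get(grid.row_var)
                if row_value is None:
                    row_value = grid.table.index[0]
                corr = grid.nearest(row_value, lookup[grid.col_var])
            else:
                corr = correction_value(eq, demo)
        adjusted = value + corr
        table = norms.tables[sub]
        es, es_flags = table.assign_es(adjusted)
        level, clamped = assign_percentile(table, adjusted)
        report.adjusted[sub] = round_half_up(adjusted, 2)
        report.es[sub] = es
        report.percentile[sub] = level
        report.flags.extend(f"{sub}:{f}" for f in es_flags)
        if clamped:
            report.flags.append(f"{sub}:clamped_percentile")
    return report


_SCORE_COLUMNS = ("vt", "aht", "ratio", "errors")


def _row_to_inputs(rec: pd.Series) -> tuple[Demographics, RawScores]:
    demo = Demographics(
        age=float(rec["age"]),
        education=float(rec["education_years"] if "education_years" in rec else rec["education"]),
        sex=rec["sex"],
    )
    scores = {}
    for sub in _SCORE_COLUMNS:
        v = rec.get(sub)
        scores[sub] = None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
    return demo, RawScores(**scores)


def batch_score(
    table: pd.DataFrame | str,
    norms: NormsAsset,
    mode: str = "equation",
) -> pd.DataFrame:
    """Score a cohort table row-wise; row count is preserved.

    Invalid rows are not dropped: their output row carries an ``error``
    message and empty scores.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        try:
            table = pd.read_csv(table)
        except Exception as exc:
            raise CohortParseError(f"could not parse CSV: {exc}") from exc
    required = {"age", "sex"}
    if not required <= set(table.columns):
        raise CohortParseError(f"batch table must have columns {sorted(required)} plus scores")
    rows = []
    for i, rec in table.iterrows():
        try:
            demo, raw = _row_to_inputs(rec)
            report = score_participant(demo, raw, norms, mode=mode)
            row = report.to_dict()
            row["error"] = ""
        except Exception as exc:  # channel the failure, keep the row
            row = {c: None for c in ScoreReport(Demographics(50, 13, "F")).to_dict()}
            row["error"] = f"row {i}: {exc}"
        row["row"] = i
        rows.append(row)
    if not rows:
        cols = list(ScoreReport(Demographics(50, 13, "F")).to_dict()) + ["error"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows).set_index("row")
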