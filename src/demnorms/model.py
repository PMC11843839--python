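"""Model/Results interface to the full norming pipeline.

`DEMNormingModel` is constructed from a cohort (a DataFrame, a
:class:`~demnorms.cohort.Cohort`, or a CSV) and `fit()` runs the whole
regression-based norming procedure per subtest:

1. descriptives (decade means, correlations, ANOVA by decade);
2. transform search and BIC subset selection with significance gating;
3. reversed-coefficient correction equation and adjusted scores;
4. skewness/kurtosis normality screen;
5. non-parametric tolerance limits, equivalent-score bands, percentiles.

The returned `DEMNormingResults` carries every intermediate table, a
``summary()`` in the spirit of statsmodels results, and serialises its
norms to the same JSON schema as the shipped published asset — so a freshly
derived norm set is immediately usable by the scorer and the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import Cohort, Demographics, GenerativeParams, simulate_cohort
from .correction import CorrectionEquation, adjust_cohort, default_grid, derive_correction
from .exceptions import InvalidParameterError
from .limits import (
    NormTable,
    ToleranceSpec,
    build_norm_table,
    normality_check,
)
from .norms import NormsAsset, parse_norms
from .scorer import score_participant
from .scoring import RawScores
from .selection import (
    SUBTESTS,
    Descriptives,
    FittedModel,
    cohort_descriptives,
    compare_models,
    fit_all_subsets,
    search_transforms,
)

REQUIRED_COLUMNS = ("age", "education_years", "sex", "vt", "aht", "ratio", "errors")


class DEMNormingModel:
    """Regression-based norming of the four DEM subtests on a cohort.

    Parameters
    ----------
    data
        Cohort data: a DataFrame with columns ``age, education_years, sex,
        vt, aht, ratio, errors`` (an ``id`` column is optional), or a
        :class:`Cohort`.
    subtests
        Which scores to norm (default: all four).
    candidates
        Transform menu per predictor; default is
        identity/square/cube/log/sqrt/inverse for age and education.
    tolerance
        Coverage/confidence/direction of the tolerance limits
        (default 95%/95%, higher adjusted score = worse).
    es_policy
        Rule for the intermediate equivalent-score bounds (default
        ``rank_thirds``).
    """

    def __init__(
        self,
        data,
        subtests=SUBTESTS,
        candidates=None,
        tolerance: ToleranceSpec | None = None,
        es_policy: str = "rank_thirds",
    ):
        frame = data.frame if isinstance(data, Cohort) else pd.DataFrame(data)
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise InvalidParameterError(f"cohort data missing column(s): {missing}")
        self.data = frame.reset_index(drop=True)
        self.subtests = tuple(subtests)
        self.candidates = candidates
        self.tolerance = tolerance or ToleranceSpec()
        self.es_policy = es_policy

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DEMNormingModel":
        from .pipeline import read_cohort_csv

        return cls(read_cohort_csv(path), **kwargs)

    @classmethod
    def from_simulation(
        cls, n: int = 521, params: GenerativeParams | None = None, seed: int | None = None, **kwargs
    ) -> "DEMNormingModel":
        return cls(simulate_cohort(n=n, params=params, seed=seed), **kwargs)

    def fit(self) -> "DEMNormingResults":
        """Run the full norming pipeline and return the results object."""
        transforms: dict[str, dict] = {}
        comparisons: dict[str, pd.DataFrame] = {}
        selected: dict[str, FittedModel | None] = {}
        equations: dict[str, CorrectionEquation] = {}
        for sub in self.subtests:
            tr = search_transforms(self.data, sub, self.candidates)
            fits = fit_all_subsets(self.data, sub, tr)
            comp = compare_models(fits, len(self.data))
            best = min(fits, key=lambda f: f.bic)
            if not (best.pvalue < 0.05):
                best = None
            transforms[sub] = tr
            comparisons[sub] = comp
            selected[sub] = best
            if best is not None:
                equations[sub] = derive_correction(self.data, best)
            else:
                # no significant demographic effect: identity correction
                equations[sub] = CorrectionEquation(subtest=sub, terms=())
        adjusted = adjust_cohort(self.data, equations)
        normality = {sub: normality_check(adjusted[sub]) for sub in self.subtests}
        tables = {}
        for sub in self.subtests:
            t = build_norm_table(adjusted[sub], self.tolerance, self.es_policy)
            tables[sub] = NormTable(
                subtest=sub,
                direction=t.direction,
                otl_value=t.otl_value,
                itl_value=t.itl_value,
                es_bounds=t.es_bounds,
                percentile_levels=t.percentile_levels,
                percentile_values=t.percentile_values,
                n=t.n,
            )
        return DEMNormingResults(
            model=self,
            descriptives=cohort_descriptives(self.data),
            transforms=transforms,
            comparisons=comparisons,
            selected=selected,
            corrections=equations,
            adjusted=adjusted,
            normality=normality,
            norm_tables=tables,
        )


@dataclass
class DEMNormingResults:
    """Everything the norming pipeline produced, with reporting helpers."""

    model: DEMNormingModel
    descriptives: Descriptives
    transforms: dict
    comparisons: dict
    selected: dict
    corrections: dict
    adjusted: pd.DataFrame
    normality: dict
    norm_tables: dict

    @property
    def nobs(self) -> int:
        return len(self.model.data)

    def correction_grid(self, subtest: str):
        return default_grid(self.corrections[subtest])

    def norms_asset(self) -> NormsAsset:
        """Bundle the derived equations and cutoffs as a norms asset."""
        return parse_norms(self.norms_document())

    def norms_document(self) -> dict:
        doc = {
            "name": "demnorms-derived",
            "version": "1",
            "direction": self.model.tolerance.direction,
            "n": self.nobs,
            "sex_coding": {"M": 1, "F": 0},
            "equations": {},
            "tolerance": {},
            "es_bands": {},
            "percentiles": {"levels": []},
        }
        for sub in self.model.subtests:
            eq = self.corrections[sub]
            doc["equations"][sub] = {
                "terms": [
                    {
                        "predictor": t.predictor,
                        "transform": t.transform,
                        "coef": t.coef,
                        "center": t.center,
                    }
                    for t in eq.terms
                ]
            }
            table = self.norm_tables[sub]
            doc["tolerance"][sub] = {"itl": table.itl_value, "otl": table.otl_value}
            doc["es_bands"][sub] = list(table.es_bounds)
            doc["percentiles"]["levels"] = list(table.percentile_levels)
            doc["percentiles"][sub] = list(table.percentile_values)
        return doc

    def save_norms(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.norms_document(), indent=1))
        return path

    def score(self, demo: Demographics, raw: RawScores, mode: str = "equation"):
        """Score a participant against *these* (freshly derived) norms."""
        return score_participant(demo, raw, self.norms_asset(), mode=mode)

    def summary(self) -> str:
        """Human-readable account of the fitted norming models and cutoffs."""
        lines = [
            "DEM regression-based norming results",
            "=" * 68,
            f"n = {self.nobs} participants",
            "",
        ]
        for sub in self.model.subtests:
            best = self.selected[sub]
            lines.append(f"[{sub.upper()}]")
            if best is None:
                lines.append("  no significant demographic model (p >= 0.05): raw == adjusted")
            else:
                terms = ", ".join(
                    f"{p}({best.transforms[p]}) = {best.params[p]:.6g} (se {best.bse[p]:.3g})"
                    for p in best.params
                )
                lines.append(
                    f"  model {best.label}: K={best.k}, BIC={best.bic:.1f}, "
                    f"R^2={best.r_squared:.3f}, p={best.pvalue:.2e}"
                )
                lines.append(f"  coefficients: {terms}")
            nr = self.normality[sub]
            lines.append(
                f"  adjusted scores: skew={nr.skewness:.2f}, excess kurtosis="
                f"{nr.excess_kurtosis:.2f} -> {nr.verdict}"
            )
            t = self.norm_tables[sub]
            lines.append(
                f"  tolerance limits: ITL={t.itl_value:.3g}, OTL={t.otl_value:.3g}; "
                f"ES bounds (ES0..ES3): "
                + ", ".join(f"{b:.3g}" for b in t.es_bounds)
            )
            lines.append("")
        return "\n".join(lines)
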