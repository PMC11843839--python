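"""Shared I/O, configuration and the end-to-end pipeline driver.

The pipeline wires the stages ``simulate -> build-norms -> report``:
read or simulate a cohort, run the norming model, and write every artifact
(descriptives, model-comparison table, correction grids, norms asset,
norm tables) as CSV/JSON with provenance.  All randomness flows from the
single configured seed; re-running with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cohort import Cohort, parse_sex, simulate_cohort
from .exceptions import CohortParseError, DemNormsError
from .limits import ToleranceSpec
from .model import DEMNormingModel
from .selection import SUBTESTS

logger = logging.getLogger("demnorms.pipeline")

COHORT_COLUMNS = ["id", "age", "education_years", "sex", "vt", "aht", "ratio", "errors"]


class PipelineConfig(BaseModel):
    """Validated configuration for one pipeline run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    input_csv: str | None = None  # if None, simulate a cohort
    output_dir: str = "demnorms_out"
    seed: int = 0
    n: int = 521
    coverage: float = 0.95
    confidence: float = 0.95
    es_policy: str = "rank_thirds"
    candidates: dict[str, list[str]] | None = None
    subtests: list[str] = Field(default_factory=lambda: list(SUBTESTS))

    def hash(self) -> str:
        # provenance over everything that affects the *results*; the output
        # location does not, so identical runs into different directories
        # produce byte-identical artifacts
        payload = self.model_dump(exclude={"output_dir"})
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def read_cohort_csv(path) -> Cohort:
    """Read and validate a cohort CSV (row-indexed errors on bad fields)."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise CohortParseError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns and c != "id"]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}")
    if "id" not in frame.columns:
        frame.insert(0, "id", np.arange(1, len(frame) + 1))
    for i, rec in frame.iterrows():
        for col in ("age", "education_years", "vt", "aht", "ratio", "errors"):
            try:
                float(rec[col])
            except (TypeError, ValueError):
                raise CohortParseError(f"row {i}: non-numeric {col}={rec[col]!r}", row=i)
        if float(rec["education_years"]) < 1:
            raise CohortParseError(
                f"row {i}: education {rec['education_years']!r} < 1 year", row=i
            )
        try:
            parse_sex(rec["sex"])
        except DemNormsError as exc:
            raise CohortParseError(f"row {i}: {exc}", row=i)
    frame["sex"] = frame["sex"].map(parse_sex)
    for col in ("age", "education_years", "vt", "aht", "ratio", "errors"):
        frame[col] = frame[col].astype(float)
    return Cohort(frame=frame[COHORT_COLUMNS])


def write_cohort_csv(cohort: Cohort, path) -> Path:
    path = Path(path)
    cohort.frame.to_csv(path, index=False)
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write artifacts; returns artifact paths.

    Stage failures abort with the stage name in the raised error message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    provenance = {"seed": config.seed, "config_hash": config.hash()}

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    stage = _stage("load-cohort")
    try:
        if config.input_csv is not None:
            cohort = read_cohort_csv(config.input_csv)
        else:
            cohort = simulate_cohort(n=config.n, seed=config.seed)
            artifacts["cohort"] = write_cohort_csv(cohort, out / "cohort.csv")

        stage = _stage("fit-norming-model")
        model = DEMNormingModel(
            cohort,
            subtests=tuple(config.subtests),
            candidates=config.candidates,
            tolerance=ToleranceSpec(coverage=config.coverage, confidence=config.confidence),
            es_policy=config.es_policy,
        )
        results = model.fit()

        stage = _stage("write-descriptives")
        d = results.descriptives
        d.decade_table.to_csv(out / "descriptives_decades.csv", index=False)
        d.correlations.to_csv(out / "correlations.csv")
        d.anova.to_csv(out / "anova.csv", index=False)
        artifacts["descriptives"] = out / "descriptives_decades.csv"
        artifacts["correlations"] = out / "correlations.csv"
        artifacts["anova"] = out / "anova.csv"

        stage = _stage("write-model-comparison")
        comp = pd.concat(
            [df.assign(subtest=sub) for sub, df in results.comparisons.items()],
            ignore_index=True,
        )
        comp = comp[["subtest"] + [c for c in comp.columns if c != "subtest"]]
        comp.to_csv(out / "model_comparison.csv", index=False)
        artifacts["model_comparison"] = out / "model_comparison.csv"

        stage = _stage("write-grids")
        for sub in config.subtests:
            grid = results.correction_grid(sub)
            p = out / f"correction_grid_{sub}.csv"
            grid.table.to_csv(p)
            artifacts[f"grid_{sub}"] = p

        stage = _stage("write-norms")
        artifacts["norms"] = results.save_norms(out / "norms.json")
        tables = []
        for sub in config.subtests:
            t = results.norm_tables[sub]
            for level, value in zip(t.percentile_levels, t.percentile_values):
                tables.append({"subtest": sub, "percentile": level, "value": value})
        pd.DataFrame(tables).to_csv(out / "percentile_tables.csv", index=False)
        artifacts["percentiles"] = out / "percentile_tables.csv"

        stage = _stage("write-run-log")
        log = dict(provenance)
        log["stages"] = {
            sub: {
                "transforms": {p: s.transform for p, s in results.transforms[sub].items()},
                "selected_model": results.selected[sub].label if results.selected[sub] else None,
                "normality": results.normality[sub].verdict,
                "otl": results.norm_tables[sub].otl_value,
            }
            for sub in config.subtests
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
        artifacts["run_log"] = out / "run_log.json"
    except DemNormsError as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc
    return artifacts
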