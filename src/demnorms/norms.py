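"""Loading and validation of norms assets.

A norms asset is a JSON document bundling, per subtest, the correction
equation (reversed centered coefficients) and the normative cutoffs (outer
tolerance limit, equivalent-score band bounds, percentile grid).  The
package ships the published adult norms as a versioned, read-only asset;
`demnorms` pipelines can write freshly derived assets in the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .correction import CorrectionEquation, CorrectionTerm
from .exceptions import ConfigurationError
from .limits import NormTable
from .selection import SUBTESTS

_PACKAGED_ASSET = "adult_norms.json"


@dataclass(frozen=True)
class NormsAsset:
    """Parsed norms: correction equations plus norm tables, per subtest."""

    name: str
    version: str
    equations: dict  # subtest -> CorrectionEquation
    tables: dict  # subtest -> NormTable
    raw: dict  # the underlying JSON document


def _parse_equation(subtest: str, doc: dict, sex_coding: dict) -> CorrectionEquation:
    try:
        terms = tuple(
            CorrectionTerm(
                predictor=t["predictor"],
                transform=t["transform"],
                coef=float(t["coef"]),
                center=float(t["center"]),
            )
            for t in doc["terms"]
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed equation for {subtest!r}: {exc}") from exc
    return CorrectionEquation(subtest=subtest, terms=terms, sex_coding=dict(sex_coding))


def parse_norms(doc: dict) -> NormsAsset:
    """Validate a norms JSON document and build the runtime objects."""
    for key in ("equations", "es_bands", "percentiles", "direction"):
        if key not in doc:
            raise ConfigurationError(f"norms asset missing {key!r}")
    sex_coding = {k.upper(): float(v) for k, v in doc.get("sex_coding", {"M": 1, "F": 0}).items()}
    direction = doc["direction"]
    levels = tuple(int(x) for x in doc["percentiles"]["levels"])
    equations, tables = {}, {}
    for sub in SUBTESTS:
        if sub not in doc["equations"]:
            raise ConfigurationError(f"norms asset missing equation for {sub!r}")
        equations[sub] = _parse_equation(sub, doc["equations"][sub], sex_coding)
        bands = doc["es_bands"].get(sub)
        pcts = doc["percentiles"].get(sub)
        if bands is None or len(bands) != 4:
            raise ConfigurationError(f"norms asset needs 4 ES band bounds for {sub!r}")
        if pcts is None or len(pcts) != len(levels):
            raise ConfigurationError(f"percentile grid for {sub!r} does not match the level list")
        tol = doc.get("tolerance", {}).get(sub, {})
        tables[sub] = NormTable(
            subtest=sub,
            direction=direction,
            otl_value=float(bands[0]),
            itl_value=float(tol["itl"]) if "itl" in tol else None,
            es_bounds=tuple(float(b) for b in bands),
            percentile_levels=levels,
            percentile_values=tuple(float(v) for v in pcts),
            n=doc.get("n"),
        )
    return NormsAsset(
        name=str(doc.get("name", "unnamed")),
        version=str(doc.get("version", "0")),
        equations=equations,
        tables=tables,
        raw=doc,
    )


def load_norms(path: str | Path | None = None) -> NormsAsset:
    """Load a norms asset from ``path``, or the packaged published norms."""
    if path is None:
        text = resources.files("demnorms.data").joinpath(_PACKAGED_ASSET).read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"norms asset is not valid JSON: {exc}") from exc
    return parse_norms(doc)


def load_published_norms() -> NormsAsset:
    """The published adult norms shipped with the package."""
    return load_norms(None)
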