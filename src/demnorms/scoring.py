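"""Raw DEM scores from card-level recordings.

The DEM test has three timed cards: two with numbers in vertical columns
(A and B) and one with the same 80 numbers in horizontal, reading-like rows
(C).  Four raw scores summarise a session:

* ``VT`` (vertical time) — time for A plus time for B, in seconds;
* ``AHT`` (adjusted horizontal time) — the card-C time rescaled for the
  number of items actually attempted, ``C × 80 / (80 − omissions + additions)``;
* ``Ratio`` — AHT / VT, an oculomotor-efficiency index that factors naming
  speed out of the horizontal time;
* ``errors`` — omissions + additions + substitutions + transpositions on C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import CohortParseError, DegenerateInputError, InvalidParameterError

N_ITEMS = 80  # numbers per card

CARD_COLUMNS = ["time_a", "time_b", "time_c", "om", "add", "sub", "trans"]


@dataclass(frozen=True)
class CardRecord:
    """Times (seconds) and card-C error counts for one administration."""

    time_a: float
    time_b: float
    time_c: float
    omissions: int = 0
    additions: int = 0
    substitutions: int = 0
    transpositions: int = 0

    def __post_init__(self):
        for name in ("time_a", "time_b", "time_c"):
            t = getattr(self, name)
            if not (math.isfinite(t) and t > 0):
                raise InvalidParameterError(f"{name} must be a positive finite time, got {t!r}")
        for name in ("omissions", "additions", "substitutions", "transpositions"):
            c = getattr(self, name)
            if c < 0 or c != int(c):
                raise InvalidParameterError(f"{name} must be a non-negative integer, got {c!r}")
        if self.omissions > N_ITEMS:
            raise InvalidParameterError(f"omissions cannot exceed {N_ITEMS}")


@dataclass(frozen=True)
class RawScores:
    """The four DEM raw scores; any field may be None for partial records."""

    vt: float | None = None
    aht: float | None = None
    ratio: float | None = None
    errors: float | None = None

    def __post_init__(self):
        for name in ("vt", "aht"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be positive and finite, got {v!r}")
        if self.errors is not None and self.errors < 0:
            raise InvalidParameterError(f"errors must be non-negative, got {self.errors!r}")


def compute_raw_scores(card: CardRecord) -> RawScores:
    """Score one card-level record.

    Raises
    ------
    DegenerateInputError
        If ``80 − omissions + additions`` is not positive, which would make
        the horizontal-time adjustment undefined.
    """
    denom = N_ITEMS - card.omissions + card.additions
    if denom <= 0:
        raise DegenerateInputError(
            f"AHT adjustment denominator 80 - {card.omissions} + {card.additions} <= 0"
        )
    vt = card.time_a + card.time_b
    aht = card.time_c * N_ITEMS / denom
    errors = card.omissions + card.additions + card.substitutions + card.transpositions
    return RawScores(vt=vt, aht=aht, ratio=aht / vt, errors=errors)


def score_cards_frame(cards: pd.DataFrame) -> pd.DataFrame:
    """Score a card-level table into a raw-score table.

    Expects columns ``time_a, time_b, time_c, om, add, sub, trans``; returns a
    frame with columns ``vt, aht, ratio, errors`` (index preserved).
    """
    missing = [c for c in CARD_COLUMNS if c not in cards.columns]
    if missing:
        raise CohortParseError(f"card table missing column(s): {missing}")
    rows = []
    for i, rec in cards.iterrows():
        try:
            scores = compute_raw_scores(
                CardRecord(
                    time_a=float(rec["time_a"]),
                    time_b=float(rec["time_b"]),
                    time_c=float(rec["time_c"]),
                    omissions=int(rec["om"]),
                    additions=int(rec["add"]),
                    substitutions=int(rec["sub"]),
                    transpositions=int(rec["trans"]),
                )
            )
        except (InvalidParameterError, DegenerateInputError, ValueError) as exc:
            raise CohortParseError(f"row {i}: {exc}", row=i) from exc
        rows.append({"vt": scores.vt, "aht": scores.aht, "ratio": scores.ratio, "errors": scores.errors})
    return pd.DataFrame(rows, index=cards.index)


def read_cards_csv(path) -> pd.DataFrame:
    """Read a card-level CSV and return the scored raw-score frame."""
    return score_cards_frame(pd.read_csv(path))
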