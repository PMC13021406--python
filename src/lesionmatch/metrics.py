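"""Questionnaire scoring for the usability / cognitive-load evaluation study.

Implements the scoring formulas only:

* **SUS** — 10 items on a 5-point scale, standard Brooke keying (odd items
  positively keyed, even items negatively keyed), score 0-100, higher is
  better usability.
* **Paas** — single 9-point mental-effort rating.
* **Naiive** — cognitive-load subscales: intrinsic (2 items) and extraneous
  (3 items), each on a 7-point scale, reported as subscale means.

Descriptive summaries (n, mean, sample SD, min, max) mirror the layout the
study reports its aggregate values in. Raw study responses are not part of
this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SusResponse",
    "PaasResponse",
    "NaiiveResponse",
    "sus_score",
    "naiive_subscales",
    "summarize",
    "score_responses",
    "summary_table",
]


def _check_range(name: str, value: int, lo: int, hi: int) -> None:
    if not isinstance(value, (int, np.integer)) or not lo <= value <= hi:
        raise ValueError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")


@dataclass(frozen=True)
class SusResponse:
    """One respondent's 10 SUS item ratings, each 1-5, items indexed 1-10."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError("SUS requires exactly 10 items")
        for i, v in enumerate(self.items, start=1):
            _check_range(f"SUS item {i}", v, 1, 5)


@dataclass(frozen=True)
class PaasResponse:
    """Single mental-effort rating on the 9-point scale."""

    rating: int

    def __post_init__(self) -> None:
        _check_range("Paas rating", self.rating, 1, 9)


@dataclass(frozen=True)
class NaiiveResponse:
    """Two intrinsic-load and three extraneous-load items, each 1-7."""

    intrinsic: tuple[int, int]
    extraneous: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.intrinsic) != 2 or len(self.extraneous) != 3:
            raise ValueError("Naiive requires 2 intrinsic + 3 extraneous items")
        for i, v in enumerate(self.intrinsic, start=1):
            _check_range(f"intrinsic item {i}", v, 1, 7)
        for i, v in enumerate(self.extraneous, start=1):
            _check_range(f"extraneous item {i}", v, 1, 7)


def sus_score(response: SusResponse) -> float:
    """Standard SUS scoring.

    Odd (positively keyed) items contribute ``rating - 1``, even (negatively
    keyed) items ``5 - rating``; the sum is scaled by 2.5 onto 0-100.
    """
    total = 0
    for i, rating in enumerate(response.items, start=1):
        total += (rating - 1) if i % 2 == 1 else (5 - rating)
    return total * 2.5


def naiive_subscales(response: NaiiveResponse) -> tuple[float, float]:
    """(intrinsic mean, extraneous mean), each in [1, 7]."""
    return (
        float(np.mean(response.intrinsic)),
        float(np.mean(response.extraneous)),
    )


def summarize(scores: Sequence[float]) -> dict[str, float]:
    """Descriptive summary: n, mean, sample SD (n-1), min, max.

    A singleton's SD is reported as 0 by convention (stable CSV output).
    """
    if len(scores) == 0:
        raise ValueError("cannot summarize an empty score list")
    arr = np.asarray(scores, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": sd,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


SUS_COLUMNS = [f"sus_{i}" for i in range(1, 11)]
NAIIVE_COLUMNS = ["naiive_int_1", "naiive_int_2", "naiive_ext_1", "naiive_ext_2", "naiive_ext_3"]
RESPONSE_COLUMNS = SUS_COLUMNS + ["paas"] + NAIIVE_COLUMNS


def score_responses(df: pd.DataFrame) -> pd.DataFrame:
    """Score a respondent-per-row table (columns sus_1..sus_10, paas, naiive_*).

    Returns one row per respondent with columns sus, paas, naiive_intrinsic,
    naiive_extraneous.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing response columns: {missing}")
    rows = []
    for _, row in df.iterrows():
        sus = sus_score(SusResponse(tuple(int(row[c]) for c in SUS_COLUMNS)))
        paas = PaasResponse(int(row["paas"])).rating
        intrinsic, extraneous = naiive_subscales(
            NaiiveResponse(
                intrinsic=(int(row["naiive_int_1"]), int(row["naiive_int_2"])),
                extraneous=(
                    int(row["naiive_ext_1"]),
                    int(row["naiive_ext_2"]),
                    int(row["naiive_ext_3"]),
                ),
            )
        )
        rows.append(
            {
                "sus": sus,
                "paas": paas,
                "naiive_intrinsic": intrinsic,
                "naiive_extraneous": extraneous,
            }
        )
    return pd.DataFrame(rows)


def summary_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table (rows N/Mean/SD/Min/Max) over the scored measures."""
    out = {}
    for column in scored.columns:
        s = summarize(scored[column].tolist())
        out[column] = [s["n"], s["mean"], s["sd"], s["min"], s["max"]]
    return pd.DataFrame(out, index=["N", "Mean", "SD", "Min", "Max"])
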