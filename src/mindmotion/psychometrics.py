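"""Questionnaire scoring and group aggregation.

Three instruments are supported:

* **SWLS** — Satisfaction With Life Scale: five items scored 1–7, total
  5–35 by summation, with named satisfaction bands (31–35 extremely
  satisfied … 5–9 extremely dissatisfied).
* **MAAS** — Mindful Attention Awareness Scale: fifteen items scored 1–6
  (anchors already oriented so higher = more mindful; no reverse-scored
  items), score = the item mean reported to one decimal.
* **MMSE** — Mini-Mental State Examination: a 0–30 total classified as
  normal (25–30), mild (21–24), moderate (10–20) or severe (<10).

Group statistics use the sample standard deviation (n−1 divisor) and
half-away-from-zero rounding at the reporting precision — the conventions
under which printed study tables are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleResponse",
    "ScaleScore",
    "GroupSummary",
    "score_swls",
    "score_maas",
    "classify_mmse",
    "score_response",
    "summarize_group",
    "longitudinal_report",
    "round_half_away",
    "SWLS_BANDS",
]

GROUPS = ("patient", "employee")
TIMEPOINTS = ("before", "midterm", "after")
SCALES = ("SWLS", "MAAS", "MMSE")

#: (low, high, label) — inclusive bands partitioning the 5–35 SWLS range.
SWLS_BANDS = (
    (31, 35, "extremely satisfied"),
    (26, 30, "satisfied"),
    (21, 25, "slightly satisfied"),
    (20, 20, "neutral"),
    (15, 19, "slightly dissatisfied"),
    (10, 14, "dissatisfied"),
    (5, 9, "extremely dissatisfied"),
)

MMSE_BANDS = (
    (25, 30, "normal"),
    (21, 24, "mild"),
    (10, 20, "moderate"),
    (0, 9, "severe"),
)

_ITEM_SPEC = {"SWLS": (5, 1, 7), "MAAS": (15, 1, 6), "MMSE": (1, 0, 30)}


@dataclass(frozen=True)
class ScaleResponse:
    """One participant's raw item responses for one scale at one timepoint."""

    participant: str
    group: str
    timepoint: str
    scale: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        _validate_items(self.scale, self.items)


@dataclass(frozen=True)
class ScaleScore:
    value: float
    category: str | None = None


@dataclass(frozen=True)
class GroupSummary:
    group: str
    scale: str
    timepoint: str
    n: int
    mean: float
    sd: float | None
    mean_rounded: float
    sd_rounded: float | None


def _validate_items(scale: str, items: Sequence[int]) -> None:
    count, lo, hi = _ITEM_SPEC[scale]
    if len(items) != count:
        raise ValueError(f"{scale} takes exactly {count} item(s), got {len(items)}")
    for i, v in enumerate(items, start=1):
        if v != int(v) or not lo <= v <= hi:
            raise ValueError(f"{scale} item {i} must be an integer in {lo}–{hi}, got {v!r}")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (27.25 → 27.3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def score_swls(items: Sequence[int]) -> ScaleScore:
    """Sum of the 5 items plus the named satisfaction band."""
    _validate_items("SWLS", items)
    total = int(sum(items))
    for lo, hi, label in SWLS_BANDS:
        if lo <= total <= hi:
            return ScaleScore(value=float(total), category=label)
    raise AssertionError("unreachable: bands cover 5–35")


def score_maas(items: Sequence[int]) -> ScaleScore:
    """Mean of the 15 items, reported to one decimal; no category bands."""
    _validate_items("MAAS", items)
    return ScaleScore(value=round_half_away(float(np.mean(items)), 1))


def classify_mmse(total: int) -> str:
    """Cognitive-impairment band for an MMSE total."""
    if total != int(total) or not 0 <= total <= 30:
        raise ValueError(f"MMSE total must be an integer in 0–30, got {total!r}")
    for lo, hi, label in MMSE_BANDS:
        if lo <= total <= hi:
            return label
    raise AssertionError("unreachable")


def score_response(resp: ScaleResponse) -> ScaleScore:
    if resp.scale == "SWLS":
        return score_swls(resp.items)
    if resp.scale == "MAAS":
        return score_maas(resp.items)
    total = resp.items[0]
    return ScaleScore(value=float(total), category=classify_mmse(total))


def summarize_group(
    scores: Sequence[float],
    precision: int = 1,
    group: str = "",
    scale: str = "",
    timepoint: str = "",
) -> GroupSummary:
    """Mean and sample SD (n−1) with half-away-from-zero rounding.

    ``precision`` is the reporting precision in decimals (0 where a table
    prints integers).  SD is undefined for a single score.
    """
    if len(scores) == 0:
        raise ValueError("cannot summarize an empty score list")
    arr = np.asarray(scores, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else None
    return GroupSummary(
        group=group,
        scale=scale,
        timepoint=timepoint,
        n=len(arr),
        mean=mean,
        sd=sd,
        mean_rounded=round_half_away(mean, precision),
        sd_rounded=None if sd is None else round_half_away(sd, precision),
    )


def longitudinal_report(
    responses: Iterable[ScaleResponse], precision: int = 1
) -> pd.DataFrame:
    """One summary row per (group, scale, timepoint) present in the input.

    Rows are ordered group → scale → timepoint with the study's canonical
    orderings (patients before employees; SWLS, MAAS, MMSE; before, midterm,
    after).
    """
    cells: dict[tuple[str, str, str], list[float]] = {}
    for resp in responses:
        key = (resp.group, resp.scale, resp.timepoint)
        cells.setdefault(key, []).append(score_response(resp).value)

    order = {
        "group": {g: i for i, g in enumerate(GROUPS)},
        "scale": {s: i for i, s in enumerate(SCALES)},
        "timepoint": {t: i for i, t in enumerate(TIMEPOINTS)},
    }
    rows = []
    for key in sorted(
        cells,
        key=lambda k: (order["group"][k[0]], order["scale"][k[1]], order["timepoint"][k[2]]),
    ):
        group, scale, timepoint = key
        s = summarize_group(
            cells[key], precision=precision, group=group, scale=scale, timepoint=timepoint
        )
        rows.append(
            {
                "group": s.group,
                "scale": s.scale,
                "timepoint": s.timepoint,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "mean_rounded": s.mean_rounded,
                "sd_rounded": s.sd_rounded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "scale", "timepoint", "n", "mean", "sd", "mean_rounded", "sd_rounded"],
    )
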