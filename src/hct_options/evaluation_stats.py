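"""Questionnaire scoring and proportion reporting conventions.

The decision-support tool was evaluated by physicians through two
instruments: an acceptability survey adapted from the Ottawa Decision Support
Framework (mixed 3/4-point Likert and dichotomous scales) and the 18-item
mHealth App Usability Questionnaire (1-7 Likert). This module reproduces the
reporting conventions used for such data: per-item means with sample standard
deviations, an overall summary over per-participant means, and integer
percentages by round-half-up for "k of n (p%)" tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LikertItem:
    label: str
    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if self.min_value >= self.max_value:
            raise ValueError(f"item {self.label!r}: invalid scale bounds")


class LikertMatrix:
    """Participants-by-items response matrix with per-item scale bounds.

    Missing responses are NaN. The CSV form encodes bounds in the header as
    ``label|min-max``, e.g. ``The app was easy to use.|1-7``.
    """

    def __init__(self, items: Sequence[LikertItem], responses: pd.DataFrame):
        labels = [it.label for it in items]
        if len(set(labels)) != len(labels):
            raise ValueError("item labels must be unique")
        if list(responses.columns) != labels:
            raise ValueError("response columns must match item labels in order")
        self.items = list(items)
        self.responses = responses.astype(float)
        for it in self.items:
            col = self.responses[it.label]
            bad = col[(~col.isna()) & ((col < it.min_value) | (col > it.max_value))]
            if len(bad):
                raise ValueError(
                    f"item {it.label!r}: response {bad.iloc[0]} outside "
                    f"[{it.min_value:g}, {it.max_value:g}]"
                )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "LikertMatrix":
        raw = pd.read_csv(path)
        items = []
        for col in raw.columns:
            label, sep, bounds = col.rpartition("|")
            if not sep or "-" not in bounds:
                raise ValueError(
                    f"column {col!r}: expected header 'label|min-max'"
                )
            lo, _, hi = bounds.partition("-")
            items.append(LikertItem(label=label, min_value=float(lo), max_value=float(hi)))
        raw.columns = [it.label for it in items]
        return cls(items, raw)


@dataclass
class ItemStats:
    """Per-item and overall questionnaire statistics.

    ``per_item`` is indexed by item label with columns mean, sd, min, max, n;
    items with zero responses are absent, and sd is NaN for a single
    respondent. ``overall`` summarizes per-participant means across answered
    items (mean, sd, min, max, n).
    """

    per_item: pd.DataFrame
    overall: dict[str, float]


def score_likert(m: LikertMatrix) -> ItemStats:
    """Mean and sample SD (n-1 denominator) per item, plus an overall summary
    computed over per-participant means."""
    rows = {}
    for it in m.items:
        col = m.responses[it.label].dropna()
        if len(col) == 0:
            continue  # reported as absent, not zero
        rows[it.label] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if len(col) > 1 else math.nan,
            "min": float(col.min()),
            "max": float(col.max()),
            "n": int(len(col)),
        }
    if not rows:
        raise ValueError("no item has any responses")
    per_item = pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd", "min", "max", "n"]]
    participant_means = m.responses.mean(axis=1, skipna=True).dropna()
    overall = {
        "mean": float(participant_means.mean()),
        "sd": (float(participant_means.std(ddof=1))
               if len(participant_means) > 1 else math.nan),
        "min": float(participant_means.min()),
        "max": float(participant_means.max()),
        "n": int(len(participant_means)),
    }
    return ItemStats(per_item=per_item, overall=overall)


def proportion_percent(k: int, n: int) -> int:
    """``round_half_up(100 * k / n)`` as an integer percent, in exact integer
    arithmetic (no floating-point round-to-even surprises)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} must satisfy 0 <= k <= n={n}")
    return (200 * k + n) // (2 * n)


def tally_report(tallies: Iterable[tuple[str, int, int]]) -> str:
    """Render "label: k/n (p%)" lines in input order (deterministic)."""
    lines = [
        f"{label}: {k}/{n} ({proportion_percent(k, n)}%)"
        for label, k, n in tallies
    ]
    return "\n".join(lines)
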