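"""Instrument scoring and the bounded-measure registry.

Each instrument has a :class:`MeasureSpec` describing its item structure and
total-score bounds; the bounds drive the successes/trials rescaling in the
analysis pipeline.  Missing items are rejected outright — no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "MeasureSpec",
    "REGISTRY",
    "LONGITUDINAL_MEASURES",
    "ENDPOINT_MEASURES",
    "score_sus",
    "score_scale",
    "score_tars",
    "score_vp_eval",
    "score_responses_frame",
]


@dataclass(frozen=True)
class MeasureSpec:
    """Item structure and total-score bounds for one instrument."""

    name: str
    n_items: int
    item_min: int
    item_max: int
    total_min: float
    total_max: float
    scoring: str  # one of: sum, percent_correct, sus, subscale_means

    def __post_init__(self) -> None:
        if self.total_min >= self.total_max:
            raise ValueError(f"{self.name}: total_min must be < total_max")
        if self.item_min >= self.item_max:
            raise ValueError(f"{self.name}: item_min must be < item_max")

    @property
    def trials(self) -> float:
        """Score range, used as the binomial trial count by the analysis."""
        return self.total_max - self.total_min


REGISTRY: dict[str, MeasureSpec] = {
    # knowledge: 12 multiple-choice items, reported as percent correct
    "knowledge": MeasureSpec("knowledge", 12, 0, 1, 0, 100, "percent_correct"),
    # confidence in delivering exposure: 27 items on 1..5, summed
    "self_efficacy": MeasureSpec("self_efficacy", 27, 1, 5, 27, 135, "sum"),
    # negative beliefs about exposure: 21 items on 0..4, summed
    "tbes": MeasureSpec("tbes", 21, 0, 4, 0, 84, "sum"),
    # usability: 10 alternating-polarity items on 1..5 -> 0..100
    "sus": MeasureSpec("sus", 10, 1, 5, 0, 100, "sus"),
    # virtual-patient evaluation: 12 items on 1..5, summed for the bounded total
    "vp_eval": MeasureSpec("vp_eval", 12, 1, 5, 12, 60, "sum"),
    # training acceptability: 6 items on 1..6, summed for the bounded total
    "tars_acceptability": MeasureSpec("tars_acceptability", 6, 1, 6, 6, 36, "sum"),
    # training utility: 9 items on 1..4, summed for the bounded total
    "tars_utility": MeasureSpec("tars_utility", 9, 1, 4, 9, 36, "sum"),
}

LONGITUDINAL_MEASURES = ("knowledge", "self_efficacy", "tbes")
ENDPOINT_MEASURES = ("sus", "vp_eval", "tars_acceptability", "tars_utility")


def _check_items(
    responses: Sequence[int], n: int, lo: int, hi: int, what: str
) -> list[int]:
    items = list(responses)
    if len(items) != n:
        raise ValueError(f"{what}: expected {n} responses, got {len(items)}")
    for i, r in enumerate(items, start=1):
        if r is None or (isinstance(r, float) and r != r):
            raise ValueError(f"{what}: item {i} is missing (no imputation)")
        if not float(r).is_integer() or not lo <= int(r) <= hi:
            raise ValueError(f"{what}: item {i}={r!r} outside {lo}..{hi}")
    return [int(r) for r in items]


def score_sus(responses: Sequence[int]) -> float:
    """Standard usability conversion of 10 items (1..5) to a 0..100 score.

    Odd-numbered items contribute ``r - 1``, even-numbered items ``5 - r``;
    the total of the ten contributions is multiplied by 2.5.
    """
    items = _check_items(responses, 10, 1, 5, "sus")
    total = sum(
        (r - 1) if i % 2 == 1 else (5 - r) for i, r in enumerate(items, start=1)
    )
    return total * 2.5


def score_scale(spec: MeasureSpec, responses: Sequence[int]) -> float:
    """Score a summed or percent-correct instrument from item responses."""
    items = _check_items(
        responses, spec.n_items, spec.item_min, spec.item_max, spec.name
    )
    if spec.scoring == "sum":
        return float(sum(items))
    if spec.scoring == "percent_correct":
        return 100.0 * sum(items) / spec.n_items
    if spec.scoring == "sus":
        return score_sus(items)
    raise ValueError(f"{spec.name}: scorer {spec.scoring!r} not item-based")


def score_tars(
    acceptability: Sequence[int], utility: Sequence[int]
) -> tuple[float, float]:
    """Acceptability (6 items, 1..6) and utility (9 items, 1..4) item means."""
    acc = _check_items(acceptability, 6, 1, 6, "tars acceptability")
    uti = _check_items(utility, 9, 1, 4, "tars utility")
    return sum(acc) / 6.0, sum(uti) / 9.0


def score_vp_eval(responses: Sequence[int]) -> tuple[float, float]:
    """Authenticity mean (items 1-6) and training-utility mean (items 7-12)."""
    items = _check_items(responses, 12, 1, 5, "vp_eval")
    return sum(items[:6]) / 6.0, sum(items[6:]) / 6.0


def score_responses_frame(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Score an item-level response table (one row per respondent).

    Expects columns ``item1..itemN`` (plus any id columns, which are kept)
    and returns a frame with one ``score`` column appended, suitable for the
    long-format trial table after melting.
    """
    spec = REGISTRY[measure]
    item_cols = [f"item{i}" for i in range(1, spec.n_items + 1)]
    missing = [c for c in item_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{measure}: response table missing columns {missing}")
    scores = [
        score_scale(spec, row) for row in df[item_cols].itertuples(index=False)
    ]
    out = df.drop(columns=item_cols).copy()
    out["measure"] = measure
    out["score"] = scores
    return out
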