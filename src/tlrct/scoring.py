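"""The 0–1 label-healthiness score of a traffic-light-labelled product.

Each of the four lights contributes points by colour — 0.25 per green, 0.15
per amber, 0 per red under the canonical weights — so the score runs from 0
(four red lights) to 1 (four green lights).  The canonical weights come from a
discrete-choice experiment on how shoppers trade off label colours; they are
injectable so alternative weightings can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .labeling import LABEL_NUTRIENTS, Color, TrafficLightLabel

__all__ = [
    "ScoreWeights",
    "CANONICAL_WEIGHTS",
    "score_label",
    "score_colors",
    "score_catalog",
    "summarize_catalog",
    "CatalogScoreSummary",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Per-light points by colour (dimensionless)."""

    green_points: float = 0.25
    amber_points: float = 0.15
    red_points: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.red_points <= self.amber_points <= self.green_points):
            raise ValueError(
                "weights must satisfy 0 <= red_points <= amber_points <= green_points"
            )

    def points(self, color: Color) -> float:
        return {
            Color.GREEN: self.green_points,
            Color.AMBER: self.amber_points,
            Color.RED: self.red_points,
        }[color]


CANONICAL_WEIGHTS = ScoreWeights()


def score_colors(colors: Iterable[Color], weights: ScoreWeights = CANONICAL_WEIGHTS) -> float:
    """Sum the per-light points of an arbitrary colour sequence."""
    return float(sum(weights.points(Color(c)) for c in colors))


def score_label(label: TrafficLightLabel, weights: ScoreWeights = CANONICAL_WEIGHTS) -> float:
    """Score one four-light label; in [0, 1] under the canonical weights."""
    return score_colors(label.colors(), weights)


def score_catalog(
    labeled_catalog: pd.DataFrame, weights: ScoreWeights = CANONICAL_WEIGHTS
) -> pd.DataFrame:
    """Append a ``score`` column to a catalog labelled by ``label_catalog``.

    Products that could not be labelled get a missing score.
    """
    out = labeled_catalog.copy()
    by_name = {c.name.lower(): weights.points(c) for c in Color}
    score = np.zeros(len(out))
    valid = np.ones(len(out), dtype=bool)
    for n in LABEL_NUTRIENTS:
        col = out[f"{n}_color"]
        valid &= col.notna().to_numpy()
        score += col.map(by_name).fillna(0.0).to_numpy(dtype=float)
    out["score"] = np.where(valid, score, np.nan)
    return out


@dataclass(frozen=True)
class CatalogScoreSummary:
    """Moments and extremes of per-product scores over a catalog."""

    n_products: int
    mean_score: float
    sd_score: float
    min_score: float
    max_score: float


def summarize_catalog(scores: Sequence[float]) -> CatalogScoreSummary:
    """Summarize per-product scores (sample SD, n−1 denominator; sd=0 at n=1)."""
    arr = np.asarray(list(scores), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarize an empty catalog")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return CatalogScoreSummary(
        n_products=int(arr.size),
        mean_score=float(arr.mean()),
        sd_score=sd,
        min_score=float(arr.min()),
        max_score=float(arr.max()),
    )
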