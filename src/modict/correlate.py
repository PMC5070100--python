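"""Validation against experimental residual enzyme activity.

Workflow: each scored mutation (or compound-heterozygous pair, whose two
scores are averaged upstream) carries an experimentally measured residual
activity in percent of wildtype.  Points more than k standard deviations
(default 2) from the panel mean in either coordinate are excluded in a single
pass; Pearson's r with a one-tailed t p-value quantifies the expected negative
score/activity relationship; an ordinary least-squares trendline of activity
on score then predicts the activity of unscored mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, FormatError

__all__ = [
    "ActivityPoint",
    "CorrelationResult",
    "Trendline",
    "PredictionSummary",
    "read_activity_table",
    "exclude_outliers",
    "pearson",
    "fit_trendline",
    "predict_activity",
    "prediction_error",
]


@dataclass(frozen=True)
class ActivityPoint:
    """One (mutation, residual activity %, score) record."""

    label: str
    activity: float
    score: float

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ContractError(f"{self.label}: activity must be >= 0")
        if not math.isfinite(self.score):
            raise ContractError(f"{self.label}: score must be finite")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_used: int
    p_one_tailed: float
    excluded: tuple[ActivityPoint, ...]


@dataclass(frozen=True)
class Trendline:
    slope: float
    intercept: float

    def predict(self, score: float) -> float:
        return max(0.0, self.slope * score + self.intercept)


@dataclass(frozen=True)
class PredictionSummary:
    """Mean absolute error (activity %) and the derived accuracy 100·(1 − MAE/mean)."""

    mae: float
    accuracy_pct: float
    n: int


def read_activity_table(source: str | Path | IO[str]) -> list[ActivityPoint]:
    """Read a (label, activity, score) TSV with '#' comments and a header row."""
    try:
        frame = pd.read_csv(source, sep="\t", comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse activity table: {exc}") from exc
    cols = {c.lower(): c for c in frame.columns}
    try:
        label_c = cols.get("label") or cols.get("mutation") or frame.columns[0]
        act_c = cols["activity"]
        score_c = cols["score"]
    except KeyError as exc:
        raise FormatError("activity table needs 'activity' and 'score' columns") from exc
    return [
        ActivityPoint(str(row[label_c]), float(row[act_c]), float(row[score_c]))
        for _, row in frame.iterrows()
    ]


def exclude_outliers(
    points: Sequence[ActivityPoint], k: float = 2.0
) -> tuple[list[ActivityPoint], list[ActivityPoint]]:
    """Single-pass k-SD exclusion in either coordinate.

    Means and sample SDs (n−1) are taken over ALL input points; a point is
    excluded iff it lies strictly more than k·SD from the mean in activity or
    in score.  No re-iteration.
    """
    if len(points) < 3:
        raise ContractError("outlier exclusion needs >= 3 points")
    act = np.array([p.activity for p in points])
    sc = np.array([p.score for p in points])
    mean_a, sd_a = act.mean(), act.std(ddof=1)
    mean_s, sd_s = sc.mean(), sc.std(ddof=1)
    kept, excluded = [], []
    for p in points:
        if abs(p.activity - mean_a) > k * sd_a or abs(p.score - mean_s) > k * sd_s:
            excluded.append(p)
        else:
            kept.append(p)
    return kept, excluded


def pearson(points: Sequence[ActivityPoint]) -> CorrelationResult:
    """Product-moment r of (score, activity) with a one-tailed t p-value.

    p is the tail of t = r·sqrt((n−2)/(1−r²)) with n−2 degrees of freedom on
    the side of the observed sign; r = 0 gives p = 0.5 exactly.
    """
    if len(points) < 3:
        raise ContractError("pearson needs >= 3 points")
    act = np.array([p.activity for p in points])
    sc = np.array([p.score for p in points])
    if act.std() == 0 or sc.std() == 0:
        raise ContractError("degenerate correlation: zero variance in a coordinate")
    r = float(stats.pearsonr(sc, act).statistic)
    n = len(points)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n_used=n, p_one_tailed=p, excluded=())


def fit_trendline(points: Sequence[ActivityPoint]) -> Trendline:
    """OLS of activity on score (activity is the predicted quantity)."""
    if len(points) < 2:
        raise ContractError("trendline needs >= 2 points")
    sc = np.array([p.score for p in points])
    act = np.array([p.activity for p in points])
    if np.all(sc == sc[0]):
        raise ContractError("singular fit: all scores equal")
    slope, intercept = np.polyfit(sc, act, 1)
    return Trendline(slope=float(slope), intercept=float(intercept))


def predict_activity(score: float, trendline: Trendline) -> float:
    """Point prediction slope·score + intercept, clamped at 0."""
    return trendline.predict(score)


def prediction_error(
    predicted: Sequence[float], observed: Sequence[float]
) -> PredictionSummary:
    """MAE in activity percent, plus accuracy = 100·(1 − MAE/mean(observed))."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.size != obs.size or pred.size == 0:
        raise ContractError("predicted and observed must be equal-length, non-empty")
    mae = float(np.mean(np.abs(pred - obs)))
    mean_obs = float(np.mean(obs))
    accuracy = 100.0 * (1.0 - mae / mean_obs) if mean_obs > 0 else float("nan")
    return PredictionSummary(mae=mae, accuracy_pct=accuracy, n=pred.size)
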