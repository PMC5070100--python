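"""Ordinal classification of scores and the stringency/accuracy sweep.

Score interpretation is relative: a negative-control score S_C (wildtype vs a
refined or re-modelled wildtype, or a known benign variant) anchors the benign
end of the scale and a known-variant score S_K the other.  A stringency
parameter K (0–100, default 55 — distinct from the κ coefficient inside the
score itself) scales the width of the classification bracket; from the anchor
and the control spread a threshold T1 is derived above which a test score is
called deleterious, with two intermediate categories below it.

The printed form of the threshold expression is ambiguous (a literal product
reading collapses when the control spread is zero and does not reproduce the
printed worked value under any reading); the default here is the additive
reading T1 = M + 3·(K/100)·σ, with ``threshold_mode="product"`` kept as the
literal alternative.  Both are exposed and recorded in run manifests.

``roc_sweep`` recomputes per-trio thresholds for a descending grid of
stringencies and reports accuracy against known outcomes plus a one-sided
binomial tail p-value under a 50% guessing null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binom

from .errors import ContractError

__all__ = [
    "CATEGORIES",
    "ControlSet",
    "ThresholdBracket",
    "compute_threshold",
    "classify",
    "roc_sweep",
]

CATEGORIES = (
    "benign",
    "partially deleterious or benign",
    "partially deleterious",
    "deleterious",
)


@dataclass(frozen=True)
class ControlSet:
    """Control scores and stringency for threshold construction.

    When ``s_intermediate`` is absent and the known control is benign, S_I is
    substituted directly by S_K.
    """

    s_negative: float  # S_C
    s_known: float  # S_K
    s_intermediate: float | None = None  # S_I
    stringency_K: float = 55.0
    known_is_benign: bool = False

    def __post_init__(self) -> None:
        for name in ("s_negative", "s_known"):
            if not math.isfinite(getattr(self, name)):
                raise ContractError(f"{name} must be finite")
        if not (0.0 <= self.stringency_K <= 100.0):
            raise ContractError("stringency_K must be in [0, 100]")

    def resolved_intermediate(self) -> float:
        if self.s_intermediate is not None:
            return self.s_intermediate
        if self.known_is_benign:
            return self.s_known
        raise ContractError(
            "s_intermediate unresolved: supply it, or mark the known control benign"
        )


@dataclass(frozen=True)
class ThresholdBracket:
    """Score cutpoints for ordinal classification.

    Boundaries are ``(t1 − 2·band, t1 − band, t1)``; scores strictly above the
    k-th boundary move up k categories, so a score above ``t1`` is deleterious
    and boundary equality resolves downward.
    """

    t1: float
    band_halfwidth: float = 0.0
    labels: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        if self.band_halfwidth < 0:
            raise ContractError("band_halfwidth must be >= 0")
        if len(self.labels) < 2:
            raise ContractError("need at least two categories")

    @property
    def boundaries(self) -> tuple[float, ...]:
        b = self.band_halfwidth
        k = len(self.labels) - 1
        return tuple(self.t1 - b * (k - 1 - i) for i in range(k))


def _two_value_sd(a: float, b: float) -> float:
    """Sample SD of two values: |a − b| / sqrt(2)."""
    return abs(a - b) / math.sqrt(2.0)


def compute_threshold(
    controls: ControlSet,
    mode: str = "additive",
    sigma_pair: tuple[float, float] | None = None,
) -> ThresholdBracket:
    """Build the classification bracket from control scores.

    The anchor is M = (S_C + (2·S_K + 3.24·S_C)/5.24)/2 and the spread σ the
    two-value sample SD of ``sigma_pair`` (default: resolved (S_I, S_K)).
    ``mode="additive"`` (default) sets T1 = M + 3·(K/100)·σ; ``mode="product"``
    is the literal product M · 3 · (K/100) · σ.
    """
    s_c = controls.s_negative
    s_k = controls.s_known
    s_i = controls.resolved_intermediate()
    anchor = (s_c + (2.0 * s_k + 3.24 * s_c) / 5.24) / 2.0
    if sigma_pair is None:
        sigma_pair = (s_i, s_k)
    sigma = _two_value_sd(*sigma_pair)
    band = 3.0 * (controls.stringency_K / 100.0) * sigma
    if mode == "additive":
        t1 = anchor + band
    elif mode == "product":
        t1 = anchor * band
    else:
        raise ContractError(f"unknown threshold mode {mode!r}")
    return ThresholdBracket(t1=t1, band_halfwidth=band)


def classify(score: float, bracket: ThresholdBracket) -> str:
    """Category of ``score`` under ``bracket``; monotone, ties resolve downward."""
    index = sum(1 for boundary in bracket.boundaries if score > boundary)
    return bracket.labels[index]


def roc_sweep(
    trios: Sequence[tuple[float, float, float, str]],
    stringencies: Iterable[float],
    mode: str = "additive",
) -> list[tuple[float, float, float]]:
    """Accuracy/p-value curve over a descending stringency grid.

    Each trio is ``(negative_score, test_score, positive_score, truth)`` with
    a binary truth label (``"deleterious"`` / ``"benign"``).  For every
    stringency the per-trio threshold is recomputed with the trio's own
    controls — spread taken between negative and positive control — and the
    test score is called deleterious iff it exceeds T1.  The p-value is the
    one-sided binomial tail probability of at least that many correct calls
    under random guessing.
    """
    trios = list(trios)
    if len(trios) < 5:
        raise ContractError("roc_sweep needs at least 5 trios")
    for trio in trios:
        if trio[3] not in ("deleterious", "benign"):
            raise ContractError(f"truth label must be binary, got {trio[3]!r}")
    curve = []
    n = len(trios)
    for k_str in stringencies:
        correct = 0
        for s_neg, s_test, s_pos, truth in trios:
            controls = ControlSet(
                s_negative=s_neg, s_known=s_pos, s_intermediate=s_pos, stringency_K=k_str
            )
            bracket = compute_threshold(controls, mode=mode, sigma_pair=(s_neg, s_pos))
            predicted = "deleterious" if s_test > bracket.t1 else "benign"
            correct += predicted == truth
        accuracy = correct / n
        p_value = float(binom.sf(correct - 1, n, 0.5))
        curve.append((float(k_str), accuracy, p_value))
    return curve
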