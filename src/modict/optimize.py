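"""Weight training and per-pair contribution profiling.

``train_weights`` searches for a shared per-residue weight vector that makes
the scores of a panel of mutant profiles correlate as negatively as possible
with their measured residual activities (higher score should mean less
activity).  The search is a seeded greedy hill-climb over random proposals:
either perturbing a random subset of coordinates (default) or resampling the
whole vector, accepting a proposal only when the Pearson correlation improves
(becomes more negative).  The trace of best-so-far correlations is therefore
monotone and the whole run bit-reproducible for a fixed seed.

``iterate_contributions`` asks the complementary question — which residue
pairs of a single profile drive its score — by taking each pair's observed
term minus its background term (floored at zero) and rescaling the result to
an attained weight in [0, 10].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractError
from .scoring import DomainSet, final_score
from .structio import RmsdProfile

__all__ = [
    "TrainingConfig",
    "TrainingResult",
    "IterationProfile",
    "train_weights",
    "iterate_contributions",
    "compare_models",
]


@dataclass(frozen=True)
class TrainingConfig:
    rounds: int = 2000
    seed: int = 0
    weight_min: float = 0.0
    weight_max: float = 10.0
    proposal: str = "coordinate-perturb"  # or "full-resample"
    perturb_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ContractError("rounds must be >= 1")
        if not self.weight_min < self.weight_max:
            raise ContractError("weight_min must be < weight_max")
        if self.proposal not in ("coordinate-perturb", "full-resample"):
            raise ContractError(f"unknown proposal mode {self.proposal!r}")


@dataclass(frozen=True)
class TrainingResult:
    best_weights: np.ndarray
    best_r: float
    r_trace: tuple[float, ...]
    seed: int


@dataclass(frozen=True)
class IterationProfile:
    """(pair_start, contribution, attained_weight in [0,10]) per pair."""

    pair_scores: tuple[tuple[int, float, float], ...]


class _PanelEvaluator:
    """Vectorised panel scoring for the training loop.

    Rescoring every profile each round dominates training cost, so the parts
    of the score that do not depend on the candidate weights (pair deviation
    sums, background multiplicities, per-profile conservation and Σγ) are
    precomputed once; a candidate then costs one matrix product per panel.
    Agreement with :func:`modict.scoring.final_score` is exact and covered by
    a unit test.
    """

    def __init__(
        self,
        profiles: Sequence[RmsdProfile],
        activities: Sequence[float],
        domains: DomainSet,
    ) -> None:
        from .scoring import gamma_sum

        n = profiles[0].n
        domains.validate_for(n)
        i_idx: list[int] = []
        j_idx: list[int] = []
        mult: list[float] = []
        for start, end in domains.intervals:
            i = np.arange(start, end + 1, 2)
            j = np.minimum(i + 1, end)
            i_idx.extend(i.tolist())
            j_idx.extend(j.tolist())
            mult.extend(np.where(j > i, 2.0, 1.0).tolist())
        self.i0 = np.asarray(i_idx) - 1
        self.j0 = np.asarray(j_idx) - 1
        self.mult = np.asarray(mult)
        self.n = n
        self.mask = domains.residue_mask(n)
        a = np.stack([p.deviations for p in profiles])
        self.pair_dev = (a[:, self.i0] + a[:, self.j0]) / n  # K x P
        self.rmsd = np.array([p.overall_rmsd for p in profiles])
        cons = np.stack([p.conservation for p in profiles])
        c_mean = cons[:, self.mask].mean(axis=1)
        c_mean = np.where(c_mean > 0, c_mean, 1.0)
        cons = cons / c_mean[:, None]
        self.cp = 0.5 * (cons[:, self.i0] + cons[:, self.j0])  # K x P
        self.gamma = np.array([gamma_sum(p, domains) for p in profiles])
        act = np.asarray(activities, dtype=float)
        self.act_centered = act - act.mean()
        self.act_norm = float(np.linalg.norm(self.act_centered))

    def pearson_r(self, weights: np.ndarray) -> float | None:
        """r(score, activity) under shared ``weights``; None for degenerate candidates."""
        w_mean = weights[self.mask].mean()
        if w_mean <= 0:
            return None
        wn = weights / w_mean
        wp = 0.5 * (wn[self.i0] + wn[self.j0])
        wc = wp[None, :] * self.cp
        isf = (self.pair_dev * wc).sum(axis=1)
        b = ((self.mult[None, :] * self.rmsd[:, None]) / self.n * wc).sum(axis=1)
        total = isf + b
        if np.any(total == 0):
            return None
        fi = isf / total
        fb = b / total
        gamma_raw = total * fi / np.hypot(fi, fb) * 0.5
        delta = isf - b
        denom = np.abs(delta) + np.abs(self.gamma)
        kap = np.where(
            denom > 0, np.clip((1.0 + (delta - self.gamma) / np.where(denom > 0, denom, 1.0)) / 2.0, 0.0, 1.0), 0.5
        )
        scores = gamma_raw * kap
        centered = scores - scores.mean()
        norm = np.linalg.norm(centered)
        if norm == 0:
            return None
        return float(centered @ self.act_centered / (norm * self.act_norm))


def train_weights(
    profiles: Sequence[RmsdProfile],
    activities: Sequence[float],
    domains: DomainSet,
    config: TrainingConfig = TrainingConfig(),
) -> TrainingResult:
    """Greedy random-search for the weight vector minimising Pearson r.

    All profiles are rescored each round with the shared candidate vector;
    a candidate is kept iff r(score, activity) strictly decreases.
    """
    if len(profiles) != len(activities):
        raise ContractError("profiles and activities must be equal length")
    if len(profiles) < 3:
        raise ContractError("training needs >= 3 (profile, activity) pairs")
    n = profiles[0].n
    if any(p.n != n for p in profiles):
        raise ContractError("profiles must share length N")
    if np.std(np.asarray(activities, dtype=float)) == 0:
        raise ContractError("degenerate activities: zero variance")

    evaluator = _PanelEvaluator(profiles, activities, domains)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.weight_min, config.weight_max
    best = profiles[0].weights.copy()
    best_r = evaluator.pearson_r(best)
    if best_r is None:
        raise ContractError("baseline weights give a degenerate panel score")
    trace = [best_r]
    n_perturb = max(1, int(round(config.perturb_fraction * n)))
    for _ in range(config.rounds):
        if config.proposal == "full-resample":
            candidate = rng.uniform(lo, hi, size=n)
        else:
            candidate = best.copy()
            idx = rng.choice(n, size=n_perturb, replace=False)
            candidate[idx] = rng.uniform(lo, hi, size=n_perturb)
        r = evaluator.pearson_r(candidate)
        # a proposal can zero out every scored residue's weight: reject it
        if r is not None and r < best_r:
            best, best_r = candidate, r
        trace.append(best_r)
    return TrainingResult(
        best_weights=best, best_r=best_r, r_trace=tuple(trace), seed=config.seed
    )


def iterate_contributions(profile: RmsdProfile, domains: DomainSet) -> IterationProfile:
    """Per-pair contribution (observed minus background, floored at 0) and
    attained weight 10·contribution/max(contribution)."""
    breakdown = final_score(profile, domains)
    contributions = [(p, max(0.0, i - b)) for p, i, b in breakdown.pair_terms]
    peak = max((c for _, c in contributions), default=0.0)
    if peak > 0:
        scored = [(p, c, 10.0 * c / peak) for p, c in contributions]
    else:
        scored = [(p, c, 0.0) for p, c in contributions]
    return IterationProfile(pair_scores=tuple(scored))


def compare_models(
    profiles: dict[str, RmsdProfile], domains: DomainSet
) -> "pd.DataFrame":
    """Contribution matrix across named models on the shared pair grid.

    Rows are pair starts, one contribution column and one attained-weight
    column per model.
    """
    import pandas as pd

    if len(profiles) < 2:
        raise ContractError("compare_models needs >= 2 profiles")
    lengths = {p.n for p in profiles.values()}
    if len(lengths) != 1:
        raise ContractError("profiles must share length N")
    columns: dict[str, list[float]] = {}
    index = None
    for name, profile in profiles.items():
        result = iterate_contributions(profile, domains)
        starts = [p for p, _, _ in result.pair_scores]
        if index is None:
            index = starts
        columns[f"{name}:contribution"] = [c for _, c, _ in result.pair_scores]
        columns[f"{name}:attained_weight"] = [w for _, _, w in result.pair_scores]
    frame = pd.DataFrame(columns, index=pd.Index(index, name="pair_start"))
    return frame
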