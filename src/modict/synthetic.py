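"""Synthetic structures and activity panels with known ground truth.

Real inputs to the pipeline are server-generated homology models of a
wildtype and a mutant; what scoring sees after superposition is a localized
displacement field on a common backbone.  This module emulates exactly that:
an ideal alpha-helical CA trace (rise 1.5 Å/residue, radius 2.3 Å, 100°/turn
step) as the wildtype, and mutants derived from it by perturbing a residue
window with controlled mean displacement, either as isotropic Gaussian jitter
or as a rigid hinge rotation of the window.  Activity panels couple planted
displacement magnitude to residual enzyme activity on a 0–100% scale
(activity = 100 − 20·magnitude + noise, floored at 0), mirroring the semantics
of experimentally measured mutant panels.

What the generator does NOT emulate: compaction/secondary-structure change,
server-to-server model variability, or global refolding — so passing tests
certify the arithmetic chain and its statistical behaviour on localized
perturbations, not accuracy on real modelling-server output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .structio import CaTrace

__all__ = [
    "PerturbationSpec",
    "make_backbone",
    "perturb",
    "make_activity_panel",
    "make_training_panel",
]

HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_STEP_DEG = 100.0  # rotation per residue
ACTIVITY_SLOPE = 20.0  # percent activity lost per Å of planted displacement


@dataclass(frozen=True)
class PerturbationSpec:
    """Localized displacement: window (1-based, inclusive), target mean magnitude (Å)."""

    window: tuple[int, int]
    magnitude: float
    mode: str = "gaussian-jitter"  # or "rigid-hinge"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ContractError("magnitude must be >= 0")
        if self.mode not in ("gaussian-jitter", "rigid-hinge"):
            raise ContractError(f"unknown perturbation mode {self.mode!r}")
        start, end = self.window
        if start < 1 or end < start:
            raise ContractError(f"bad window {self.window}")


def make_backbone(n: int, geometry: str = "helix") -> CaTrace:
    """Ideal CA backbone of n residues; deterministic."""
    if n < 3:
        raise ContractError("backbone needs n >= 3")
    if geometry != "helix":
        raise ContractError(f"unknown geometry {geometry!r}")
    step = math.radians(HELIX_STEP_DEG)
    residues = []
    for i in range(n):
        theta = i * step
        residues.append(
            (
                i + 1,
                "ALA",
                (HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta), HELIX_RISE * i),
            )
        )
    return CaTrace(tuple(residues))


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def perturb(trace: CaTrace, spec: PerturbationSpec) -> CaTrace:
    """Displace the window residues only; coordinates elsewhere are bit-identical.

    gaussian-jitter: isotropic noise, per-coordinate SD = magnitude/sqrt(3), so
    the mean 3D displacement is ~0.92·magnitude (chi-3 mean).  rigid-hinge:
    rotate the window about an axis through its first residue, angle chosen so
    the realized mean displacement equals the requested magnitude.
    """
    start, end = spec.window
    if end > len(trace):
        raise ContractError(f"window {spec.window} out of bounds for N={len(trace)}")
    coords = trace.coords
    if spec.magnitude == 0:
        return trace
    rng = np.random.default_rng(spec.seed)
    sl = slice(start - 1, end)
    if spec.mode == "gaussian-jitter":
        sd = spec.magnitude / math.sqrt(3.0)
        coords[sl] = coords[sl] + rng.normal(0.0, sd, size=coords[sl].shape)
    else:
        pivot = coords[start - 1].copy()
        rel = coords[sl] - pivot
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        # small-angle displacement of point p is angle * distance-to-axis;
        # solve for the angle that realizes the requested mean, then rotate exactly
        dist = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
        mean_dist = dist.mean()
        if mean_dist == 0:
            return trace
        angle = min(spec.magnitude / mean_dist, math.pi)
        rot = _rotation_about_axis(axis, angle)
        # exact chord displacement is 2·sin(angle/2)·dist; rescale the angle once
        realized = 2.0 * math.sin(angle / 2.0) * mean_dist
        if realized > 0:
            angle = min(angle * spec.magnitude / realized, math.pi)
            rot = _rotation_about_axis(axis, angle)
        coords[sl] = rel @ rot.T + pivot
    return trace.with_coords(coords)


def make_activity_panel(
    n_mutants: int,
    window: tuple[int, int],
    magnitudes: "np.ndarray | list[float]",
    noise_sd: float = 5.0,
    seed: int = 0,
    n_residues: int = 100,
    mode: str = "gaussian-jitter",
) -> tuple[CaTrace, list[CaTrace], list[float]]:
    """Wildtype trace, n_mutants perturbed traces, and noisy activities.

    activity_k = max(0, 100 − 20·magnitude_k + N(0, noise_sd)); magnitudes are
    recycled over the panel when shorter than n_mutants.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if np.any(mags < 0):
        raise ContractError("magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    wildtype = make_backbone(n_residues)
    mutants, activities = [], []
    for k in range(n_mutants):
        magnitude = float(mags[k % mags.size])
        spec = PerturbationSpec(
            window=window,
            magnitude=magnitude,
            mode=mode,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mutants.append(perturb(wildtype, spec))
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        activities.append(max(0.0, 100.0 - ACTIVITY_SLOPE * magnitude + noise))
    return wildtype, mutants, activities


def make_training_panel(
    n_profiles: int = 400,
    n_residues: int = 120,
    window: tuple[int, int] = (40, 60),
    distractor: tuple[int, int] = (80, 100),
    noise_sd: float = 0.4,
    activity_noise_sd: float = 2.0,
    seed: int = 0,
):
    """Deviation profiles whose activity is driven ONLY by displacement in ``window``.

    Each profile carries baseline model noise everywhere (half-normal,
    ``noise_sd``), a planted signal of per-profile amplitude s_k inside
    ``window`` (activity = 100 − 30·s_k + measurement noise) and an
    uncorrelated distractor displacement in ``distractor``.  Weight training
    should learn to discount the distractor and the noise; ground truth for
    that is the window itself.

    The default panel is deliberately larger than the number of free weights:
    with fewer profiles than weights the training objective is unidentifiable
    (any activity vector can be interpolated exactly) and recovering the
    planted window is not a well-posed expectation.  Returns
    (profiles, activities).
    """
    from .structio import RmsdProfile

    rng = np.random.default_rng(seed)
    profiles, activities = [], []
    w_sl = slice(window[0] - 1, window[1])
    d_sl = slice(distractor[0] - 1, distractor[1])
    for k in range(n_profiles):
        signal = rng.uniform(0.2, 2.0)
        dev = np.abs(rng.normal(0.0, noise_sd, size=n_residues))
        dev[w_sl] += signal
        dev[d_sl] += rng.uniform(0.0, 2.0)
        profiles.append(RmsdProfile.from_deviations(dev))
        noise = rng.normal(0.0, activity_noise_sd) if activity_noise_sd > 0 else 0.0
        activities.append(100.0 - 30.0 * signal + noise)
    return profiles, activities
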