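"""Optomotor performance scoring: quadrant occupancy, correct-quadrant
percentage per motion phase, walking velocity, and group comparisons.

The tube is divided into four equal lengthwise quadrants, Q1 leftmost to
Q4 rightmost.  Flies walk against the stimulus, so a leftward sweep
(direction −1) makes Q4 the target and a rightward sweep makes Q1 the
target.  Chance-level occupancy of any quadrant is 25 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import OutOfRangeError, StampedeError, StatisticalInputError
from .protocol import StimulusTimeline
from .simulate import ArenaGeometry, TrajectorySet

__all__ = [
    "QuadrantOccupancy",
    "PhaseScore",
    "GroupComparison",
    "assign_quadrant",
    "occupancy_fractions",
    "correct_quadrant_score",
    "velocity_series",
    "mean_velocity",
    "compare_groups",
]


@dataclass(frozen=True)
class QuadrantOccupancy:
    """Time fractions spent in quadrants 1–4 over a window."""

    fractions: tuple[float, float, float, float]
    window: tuple[float, float]
    n_samples: int


@dataclass(frozen=True)
class PhaseScore:
    """Per-motion-phase performance: % of samples in the target quadrant."""

    phase: int
    target_quadrant: int
    pct_correct: float
    window: tuple[float, float]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a group test with Bonferroni-corrected pairwise p-values."""

    test: str
    statistic: float
    pvalue: float
    groups: tuple[str, ...]
    # (group_a, group_b, t, raw_p, corrected_p)
    pairwise: tuple[tuple[str, str, float, float, float], ...]
    correction_factor: int


def assign_quadrant(x_mm: float, arena: "ArenaGeometry | None" = None) -> int:
    """Quadrant index 1–4 of a position: half-open bins
    ``[0, L/4) -> 1`` … with ``x = L`` clamped into Q4."""
    arena = arena if arena is not None else ArenaGeometry()
    L = arena.length_mm
    if not (0 <= x_mm <= L):
        raise OutOfRangeError(f"x_mm={x_mm} outside arena [0, {L}]")
    return min(4, 1 + int(math.floor(4.0 * x_mm / L)))


def _fly_series(traj: TrajectorySet, fly: int) -> np.ndarray:
    if fly not in traj.fly_ids:
        raise StampedeError(f"fly id {fly} not in trajectory set {traj.fly_ids}")
    x, _ = traj.fly(fly)
    return x


def _window_index(traj: TrajectorySet, window: tuple[float, float]) -> np.ndarray:
    start, end = window
    if end <= start:
        raise StampedeError(f"empty window {window}")
    t = traj.t_s
    if start < t[0] - 0.5 / traj.fps or end > t[-1] + 1.5 / traj.fps:
        raise OutOfRangeError(
            f"window {window} outside trajectory span [{t[0]}, {t[-1]}]"
        )
    idx = np.flatnonzero((t >= start) & (t < end))
    if idx.size == 0:
        raise StampedeError(f"window {window} contains no samples")
    return idx


def occupancy_fractions(
    traj: TrajectorySet,
    window: tuple[float, float],
    arena: "ArenaGeometry | None" = None,
    fly: int = 0,
) -> QuadrantOccupancy:
    """Fraction of samples in each quadrant over ``window`` (half-open,
    seconds).  Fractions are per frame sample and sum to 1."""
    arena = arena if arena is not None else traj.arena
    x = _fly_series(traj, fly)
    idx = _window_index(traj, window)
    xs = x[idx]
    xs = xs[np.isfinite(xs)]
    if xs.size == 0:
        raise StampedeError(f"window {window} has no finite positions")
    q = np.minimum(3, np.floor(4.0 * xs / arena.length_mm).astype(int))
    if q.min() < 0:
        raise OutOfRangeError("positions below 0 in occupancy window")
    counts = np.bincount(q, minlength=4)
    frac = counts / counts.sum()
    return QuadrantOccupancy(
        fractions=tuple(float(f) for f in frac),
        window=(float(window[0]), float(window[1])),
        n_samples=int(xs.size),
    )


def correct_quadrant_score(
    traj: TrajectorySet,
    timeline: StimulusTimeline,
    arena: "ArenaGeometry | None" = None,
    fly: int = 0,
) -> list[PhaseScore]:
    """Percent time in the target quadrant for each directed motion block.

    Target is Q4 for a leftward sweep (direction −1) and Q1 for a
    rightward sweep — flies walk opposite the stimulus motion.  Returns an
    empty list for a timeline without directed motion blocks."""
    arena = arena if arena is not None else traj.arena
    scores: list[PhaseScore] = []
    for phase, (start, block) in enumerate(timeline.motion_blocks(), start=1):
        target = 4 if block.direction == -1 else 1
        window = (start, start + block.duration_s)
        occ = occupancy_fractions(traj, window, arena=arena, fly=fly)
        scores.append(
            PhaseScore(
                phase=phase,
                target_quadrant=target,
                pct_correct=100.0 * occ.fractions[target - 1],
                window=window,
            )
        )
    return scores


def velocity_series(
    traj: TrajectorySet,
    smooth_frames: int = 1,
    fly: int = 0,
    use_2d: bool = False,
) -> np.ndarray:
    """Per-step speed in mm/s after boxcar-smoothing the positions over
    ``smooth_frames``; length ``n_frames - 1``.  1-D (|dx|) by default —
    the narrow tube confines motion to x — with an optional 2-D flag."""
    if smooth_frames < 1:
        raise StampedeError(f"smooth_frames must be >= 1, got {smooth_frames}")
    x = _fly_series(traj, fly).astype(float)
    i = traj.fly_ids.index(fly)
    y = traj.y_mm[i].astype(float)
    if smooth_frames > 1:
        x = ndimage.uniform_filter1d(x, smooth_frames, mode="nearest")
        y = ndimage.uniform_filter1d(y, smooth_frames, mode="nearest")
    dx = np.diff(x)
    if use_2d:
        return np.hypot(dx, np.diff(y)) * traj.fps
    return np.abs(dx) * traj.fps


def mean_velocity(
    traj: TrajectorySet,
    window: tuple[float, float],
    smooth_frames: int = 1,
    fly: int = 0,
    use_2d: bool = False,
) -> float:
    """Mean speed (mm/s) over a window; needs >= 2 samples in the window."""
    idx = _window_index(traj, window)
    if idx.size < 2:
        raise StampedeError(f"window {window} has fewer than 2 samples")
    v = velocity_series(traj, smooth_frames=smooth_frames, fly=fly, use_2d=use_2d)
    steps = idx[:-1]  # speed of step i spans samples i -> i+1
    vals = v[steps]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise StampedeError(f"window {window} has no finite speeds")
    return float(vals.mean())


def _check_group(name: str, values: np.ndarray) -> None:
    if values.size < 2:
        raise StatisticalInputError(f"group {name!r} has n < 2")
    if not np.all(np.isfinite(values)):
        raise StatisticalInputError(f"group {name!r} contains non-finite scores")


def compare_groups(
    scores_by_group: Mapping[str, Sequence[float]],
    design: str = "independent",
) -> GroupComparison:
    """Compare per-fly scores between groups.

    ``independent``: one-way ANOVA across >= 2 groups plus pairwise
    Welch-free two-sample t-tests with Bonferroni correction (factor =
    number of pairwise comparisons).  ``paired``: exactly two equal-length
    groups, paired t-test.  Degenerate input (n < 2 per group, or zero
    variance everywhere) raises :class:`StatisticalInputError`.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in scores_by_group.items()}
    for name, vals in groups.items():
        _check_group(name, vals)
    names = tuple(groups)
    if design == "paired":
        if len(groups) != 2:
            raise StatisticalInputError("paired design needs exactly 2 groups")
        a, b = (groups[n] for n in names)
        if a.size != b.size:
            raise StatisticalInputError("paired design needs equal-length groups")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            if np.allclose(diffs, 0.0):
                raise StatisticalInputError("paired differences are all zero")
            raise StatisticalInputError("paired differences have zero variance")
        t, p = stats.ttest_rel(a, b)
        return GroupComparison(
            test="paired t-test",
            statistic=float(t),
            pvalue=float(p),
            groups=names,
            pairwise=((names[0], names[1], float(t), float(p), float(p)),),
            correction_factor=1,
        )
    if design != "independent":
        raise StatisticalInputError(f"unknown design {design!r}")
    if len(groups) < 2:
        raise StatisticalInputError("independent design needs >= 2 groups")
    if all(np.allclose(v.std(ddof=1), 0.0) for v in groups.values()):
        raise StatisticalInputError("all groups have zero variance")
    f, p = stats.f_oneway(*groups.values())
    pairs = []
    m = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, rp = stats.ttest_ind(groups[names[i]], groups[names[j]])
            pairs.append(
                (names[i], names[j], float(t), float(rp), float(min(1.0, m * rp)))
            )
    return GroupComparison(
        test="one-way ANOVA + Bonferroni pairwise t",
        statistic=float(f),
        pvalue=float(p),
        groups=names,
        pairwise=tuple(pairs),
        correction_factor=m,
    )
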