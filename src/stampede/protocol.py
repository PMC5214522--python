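"""Stimulus protocol engine for the tube optomotor ("stampede") assay.

A trial is an ordered, contiguous sequence of timed blocks: mechanical
startle (brief vibration-motor buzzes), visual motion (a bright vertical
stripe sweeping across flanking LED panels), and rest.  The standard assay
is::

    startle (3 s) > motion left (60 s) > startle (3 s)
    > motion right (60 s) > startle (3 s) > rest (60 s)

This module builds such timelines, answers point queries ("what stimulus is
active at t = 37.2 s?"), and renders the LED panel pattern for any instant.

Conventions
-----------
* Time is continuous seconds from trial start; block membership uses
  half-open intervals ``[start, end)``.
* Motion direction −1 sweeps toward decreasing arena x (leftward), +1
  toward increasing x.  Flies walk *against* the stimulus, so the
  behavioural target is the opposite tube end.
* ``rate_hz`` counts discrete stripe advances (one LED column) per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import OutOfRangeError, ProtocolError

__all__ = [
    "StartleBlock",
    "MotionBlock",
    "RestBlock",
    "StimulusTimeline",
    "StimulusState",
    "PanelGeometry",
    "PanelPattern",
    "AssayConfig",
    "make_startle_block",
    "build_standard_timeline",
    "stimulus_at",
    "render_panel_pattern",
]


@dataclass(frozen=True)
class StartleBlock:
    """A burst of discrete vibration-motor activations.

    ``n_events`` activations of ``event_s`` seconds each, separated by
    ``gap_s`` seconds of silence.  Total span is
    ``n_events * event_s + max(0, n_events - 1) * gap_s``.
    """

    n_events: int = 2
    event_s: float = 1.0
    gap_s: float = 1.0

    def __post_init__(self):
        if self.n_events < 0:
            raise ProtocolError(f"n_events must be >= 0, got {self.n_events}")
        if self.event_s <= 0:
            raise ProtocolError(f"event_s must be > 0, got {self.event_s}")
        if self.gap_s < 0:
            raise ProtocolError(f"gap_s must be >= 0, got {self.gap_s}")

    @property
    def span_s(self) -> float:
        return self.n_events * self.event_s + max(0, self.n_events - 1) * self.gap_s

    def onsets(self) -> tuple[float, ...]:
        """Event onset times relative to block start."""
        period = self.event_s + self.gap_s
        return tuple(i * period for i in range(self.n_events))

    def active_at(self, t_rel: float) -> bool:
        """True iff ``t_rel`` (seconds from block start) lies inside an event."""
        if t_rel < 0 or t_rel >= self.span_s:
            return False
        period = self.event_s + self.gap_s
        return (t_rel % period) < self.event_s if period > 0 else True


@dataclass(frozen=True)
class MotionBlock:
    """Visual-motion block: a stripe sweeping in one direction.

    ``direction`` is −1 (leftward), +1 (rightward) or 0 (static/off);
    ``rate_hz`` is zero iff the pattern is static.
    """

    direction: int
    duration_s: float = 60.0
    rate_hz: float = 25.0

    def __post_init__(self):
        if self.direction not in (-1, 0, 1):
            raise ProtocolError(f"direction must be -1, 0 or +1, got {self.direction}")
        if self.duration_s <= 0:
            raise ProtocolError(f"duration_s must be > 0, got {self.duration_s}")
        if self.rate_hz < 0:
            raise ProtocolError(f"rate_hz must be >= 0, got {self.rate_hz}")
        if (self.rate_hz == 0) != (self.direction == 0):
            raise ProtocolError(
                "rate_hz must be 0 iff the pattern is static (direction 0); "
                f"got direction={self.direction}, rate_hz={self.rate_hz}"
            )

    @property
    def span_s(self) -> float:
        return self.duration_s


@dataclass(frozen=True)
class RestBlock:
    """No stimulus at all."""

    duration_s: float = 60.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ProtocolError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def span_s(self) -> float:
        return self.duration_s


Block = Union[StartleBlock, MotionBlock, RestBlock]


@dataclass(frozen=True)
class StimulusState:
    """The stimulus active at one instant of the trial."""

    t_s: float
    motion_dir: int
    rate_hz: float
    startle_active: bool
    block_start_s: float = 0.0


@dataclass(frozen=True)
class PanelGeometry:
    """LED panel dimensions (columns span the tube's long axis)."""

    n_rows: int = 16
    n_cols: int = 32
    stripe_cols: int = 2

    def __post_init__(self):
        if self.n_cols < self.stripe_cols or self.stripe_cols < 1:
            raise ProtocolError(
                f"need n_cols >= stripe_cols >= 1, got {self.n_cols}, {self.stripe_cols}"
            )


@dataclass(frozen=True)
class PanelPattern:
    """Binary on/off LED grid at one instant."""

    grid: np.ndarray  # (n_rows, n_cols) bool
    stripe_cols: int

    def lit_columns(self) -> np.ndarray:
        return np.flatnonzero(self.grid.any(axis=0))


@dataclass(frozen=True)
class StimulusTimeline:
    """Ordered, contiguous blocks covering ``[0, total_s)``.

    Zero-span blocks (a startle with ``n_events = 0``) are retained for
    bookkeeping but never contain any query time.
    """

    blocks: tuple[tuple[float, Block], ...]
    total_s: float

    @classmethod
    def from_blocks(cls, blocks: "list[Block] | tuple[Block, ...]") -> "StimulusTimeline":
        t = 0.0
        placed = []
        for b in blocks:
            placed.append((t, b))
            t += b.span_s
        return cls(blocks=tuple(placed), total_s=t)

    def block_at(self, t_s: float) -> tuple[float, Block]:
        if not (0 <= t_s < self.total_s):
            raise OutOfRangeError(
                f"t_s={t_s} outside trial interval [0, {self.total_s})"
            )
        for start, b in self.blocks:
            if start <= t_s < start + b.span_s:
                return start, b
        raise OutOfRangeError(f"no block contains t_s={t_s}")  # pragma: no cover

    def startle_onsets(self) -> tuple[float, ...]:
        """Absolute onset times of every startle event in the trial."""
        out: list[float] = []
        for start, b in self.blocks:
            if isinstance(b, StartleBlock):
                out.extend(start + o for o in b.onsets())
        return tuple(out)

    def motion_blocks(self) -> tuple[tuple[float, MotionBlock], ...]:
        """Directed motion blocks (direction != 0) with their start times."""
        return tuple(
            (start, b)
            for start, b in self.blocks
            if isinstance(b, MotionBlock) and b.direction != 0
        )

    def mirrored(self) -> "StimulusTimeline":
        """Swap every leftward sweep for rightward and vice versa."""
        flipped = []
        for _, b in self.blocks:
            if isinstance(b, MotionBlock) and b.direction != 0:
                b = MotionBlock(-b.direction, b.duration_s, b.rate_hz)
            flipped.append(b)
        return StimulusTimeline.from_blocks(flipped)


@dataclass(frozen=True)
class AssayConfig:
    """Parameters of the standard assay timeline and panel geometry."""

    startle: StartleBlock = field(default_factory=StartleBlock)
    motion_rate_hz: float = 25.0
    motion_s: float = 60.0
    rest_s: float = 60.0
    panel: PanelGeometry = field(default_factory=PanelGeometry)


def make_startle_block(n_events: int, event_s: float, gap_s: float) -> StartleBlock:
    """Build a startle block of ``n_events`` buzzes of ``event_s`` s with
    ``gap_s`` s intervals; (2, 1, 1) spans 3 s with onsets at 0 s and 2 s."""
    return StartleBlock(n_events=n_events, event_s=event_s, gap_s=gap_s)


def build_standard_timeline(config: AssayConfig | None = None) -> StimulusTimeline:
    """Standard six-block trial: startle, motion left, startle, motion
    right, startle, rest.  Defaults give a 189-s timeline (3 × 3 s startle,
    2 × 60 s motion at 25 Hz, 60 s rest)."""
    cfg = config if config is not None else AssayConfig()
    return StimulusTimeline.from_blocks(
        [
            cfg.startle,
            MotionBlock(-1, cfg.motion_s, cfg.motion_rate_hz),
            cfg.startle,
            MotionBlock(+1, cfg.motion_s, cfg.motion_rate_hz),
            cfg.startle,
            RestBlock(cfg.rest_s),
        ]
    )


def stimulus_at(timeline: StimulusTimeline, t_s: float) -> StimulusState:
    """The stimulus state at time ``t_s`` of the trial.

    During a startle block, ``startle_active`` is true only inside an event
    window (not during the inter-event gaps)."""
    start, b = timeline.block_at(t_s)
    if isinstance(b, StartleBlock):
        return StimulusState(
            t_s=t_s,
            motion_dir=0,
            rate_hz=0.0,
            startle_active=b.active_at(t_s - start),
            block_start_s=start,
        )
    if isinstance(b, MotionBlock):
        return StimulusState(
            t_s=t_s,
            motion_dir=b.direction,
            rate_hz=b.rate_hz,
            startle_active=False,
            block_start_s=start,
        )
    return StimulusState(
        t_s=t_s, motion_dir=0, rate_hz=0.0, startle_active=False, block_start_s=start
    )


def render_panel_pattern(
    state: StimulusState,
    geometry: PanelGeometry | None = None,
    t_s: float | None = None,
) -> PanelPattern:
    """LED pattern at time ``t_s`` (default: the state's own time).

    For a rightward sweep the stripe's left edge sits at column
    ``floor(rate_hz * t_block) mod n_cols`` counting from block start; the
    leftward sweep is defined as the exact mirror image of the rightward
    pattern at the same instant, so left/right trials are symmetric down to
    the LED.  All LEDs are off when there is no motion."""
    geom = geometry if geometry is not None else PanelGeometry()
    grid = np.zeros((geom.n_rows, geom.n_cols), dtype=bool)
    if state.motion_dir == 0 or state.rate_hz == 0:
        return PanelPattern(grid=grid, stripe_cols=geom.stripe_cols)
    t_query = state.t_s if t_s is None else t_s
    t_block = t_query - state.block_start_s
    if t_block < 0:
        raise OutOfRangeError(f"query time {t_query} precedes block start")
    k = math.floor(state.rate_hz * t_block)
    cols = (k + np.arange(geom.stripe_cols)) % geom.n_cols
    if state.motion_dir < 0:
        cols = (geom.n_cols - 1) - cols
    grid[:, cols] = True
    return PanelPattern(grid=grid, stripe_cols=geom.stripe_cols)
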