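"""Agent-based simulator of single flies walking in a tube under the
stampede stimulus timeline, plus a silhouette renderer for tracker testing.

Behavioural model
-----------------
Each fly is a run-and-reverse walker on the tube's long axis.  Per time
step ``dt``:

* the heading reverses with probability ``1 - exp(-reversal_rate_hz * dt)``;
* walking speed is ``base_speed_mm_s``, multiplied by ``motion_speed_boost``
  while a moving stripe is displayed (visually evoked hyperactivity);
* visual motion adds a drift *against* the stimulus direction with speed
  ``optomotor_gain(arousal, rate_hz)``;
* tube ends reflect: position is clipped into [0, L] and the heading flips
  on contact.

The optomotor gain factorises into an inverted-U (Yerkes–Dodson) Gaussian
in arousal and a log-Gaussian tuning curve in stripe rate::

    g(a, f) = g_max * exp(-(a - a_opt)^2 / (2 a_sigma^2))
                    * exp(-ln(f / f_peak_hz)^2 / (2 f_sigma^2)),   g(a, 0) = 0

Arousal is a dimensionless scalar that decays exponentially with time
constant ``tau_a_s`` and jumps by ``a_incr`` at each startle-event onset.
Startle therefore shapes performance only through arousal; it never pushes
the fly directly.

Genotype presets (``get_preset``): ``wildtype`` (responsive, peak gain near
30 Hz), ``null`` (zero gain — scores at the 25 % chance level), and
``hyperactive-low-gain`` (strong motion-evoked speed-up, near-zero gain),
emulating the hyperactive dopamine-receptor mutant phenotype.  Preset
values are calibration targets for those behavioural contrasts, not
measured constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RenderError, StampedeError
from .protocol import StimulusState, StimulusTimeline, stimulus_at
from .video import FrameStack

__all__ = [
    "ArenaGeometry",
    "AgentParams",
    "AgentState",
    "TrajectorySet",
    "ImagingParams",
    "optomotor_gain",
    "update_arousal",
    "step_agent",
    "run_trial",
    "render_frames",
    "get_preset",
    "preset_names",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """A single-fly walking tube; quadrant bounds at L/4, L/2, 3L/4."""

    length_mm: float = 152.0
    width_mm: float = 5.0
    n_quadrants: int = 4

    def __post_init__(self):
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise StampedeError("arena dimensions must be positive")
        if self.n_quadrants != 4:
            raise StampedeError("the assay scores exactly 4 quadrants")


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one simulated genotype.

    Speeds in mm/s, rates in Hz, arousal dimensionless; ``f_sigma`` is the
    width of the rate-tuning curve on a natural-log axis.
    """

    base_speed_mm_s: float = 10.0
    reversal_rate_hz: float = 0.1
    g_max: float = 16.0
    a_incr: float = 0.5
    tau_a_s: float = 60.0
    a_opt: float = 1.0
    a_sigma: float = 0.6
    f_peak_hz: float = 30.0
    f_sigma: float = 0.8
    motion_speed_boost: float = 1.2

    def __post_init__(self):
        for name in (
            "base_speed_mm_s",
            "reversal_rate_hz",
            "g_max",
            "a_incr",
            "tau_a_s",
            "motion_speed_boost",
        ):
            if getattr(self, name) < 0:
                raise StampedeError(f"{name} must be >= 0")
        if self.a_sigma <= 0 or self.f_sigma <= 0:
            raise StampedeError("a_sigma and f_sigma must be > 0")


@dataclass(frozen=True)
class AgentState:
    """Instantaneous state of one fly."""

    x_mm: float
    heading: int  # -1 or +1
    arousal: float = 0.0


def _load_presets() -> dict:
    with resources.files("stampede.data").joinpath("presets.json").open() as fh:
        raw = json.load(fh)
    return {name: AgentParams(**fields) for name, fields in raw.items()}


_PRESETS: "dict[str, AgentParams] | None" = None


def preset_names() -> tuple[str, ...]:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    return tuple(_PRESETS)


def get_preset(name: str) -> AgentParams:
    """Return the shipped genotype preset ``name``."""
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    try:
        return _PRESETS[name]
    except KeyError:
        raise StampedeError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        ) from None


def optomotor_gain(params: AgentParams, arousal: float, rate_hz: float) -> float:
    """Drift speed (mm/s) opposing the stimulus, for a given arousal and
    stripe rate.  Zero when there is no motion (``rate_hz == 0``)."""
    if rate_hz <= 0 or params.g_max == 0:
        return 0.0
    ga = math.exp(-((arousal - params.a_opt) ** 2) / (2 * params.a_sigma**2))
    lf = math.log(rate_hz / params.f_peak_hz)
    gf = math.exp(-(lf**2) / (2 * params.f_sigma**2))
    return params.g_max * ga * gf


def update_arousal(
    arousal: float, dt_s: float, startle_onset: bool, params: AgentParams
) -> float:
    """One Euler step of the arousal dynamics: exponential decay plus an
    ``a_incr`` jump if a startle event begins during this step."""
    if dt_s <= 0:
        raise StampedeError(f"dt_s must be > 0, got {dt_s}")
    a = arousal * math.exp(-dt_s / params.tau_a_s) if params.tau_a_s > 0 else 0.0
    if startle_onset:
        a += params.a_incr
    return a


def step_agent(
    state: AgentState,
    stim: StimulusState,
    params: AgentParams,
    arena: ArenaGeometry,
    dt_s: float,
    rng: np.random.Generator,
) -> AgentState:
    """Advance one fly by ``dt_s`` under the given stimulus.

    Consumes exactly one uniform variate from ``rng`` (the reversal draw);
    arousal is left untouched — update it separately with
    :func:`update_arousal`."""
    if dt_s <= 0:
        raise StampedeError(f"dt_s must be > 0, got {dt_s}")
    heading = state.heading
    p_rev = 1.0 - math.exp(-params.reversal_rate_hz * dt_s)
    if rng.random() < p_rev:
        heading = -heading
    speed = params.base_speed_mm_s * (
        params.motion_speed_boost if stim.rate_hz > 0 else 1.0
    )
    g = optomotor_gain(params, state.arousal, stim.rate_hz)
    x = state.x_mm + heading * speed * dt_s - stim.motion_dir * g * dt_s
    if x <= 0.0:
        x, heading = 0.0, +1
    elif x >= arena.length_mm:
        x, heading = arena.length_mm, -1
    return AgentState(x_mm=x, heading=heading, arousal=state.arousal)


@dataclass
class TrajectorySet:
    """Per-fly (t, x, y) series on a uniform time base.

    ``x_mm`` and ``y_mm`` are ``(n_flies, n_frames)``; NaN marks frames
    where a (tracked) fly has no position.
    """

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    fps: float
    fly_ids: tuple[int, ...]
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.atleast_2d(np.asarray(self.x_mm, dtype=float))
        self.y_mm = np.atleast_2d(np.asarray(self.y_mm, dtype=float))
        if self.x_mm.shape != self.y_mm.shape or self.x_mm.shape[1] != len(self.t_s):
            raise StampedeError("inconsistent trajectory array shapes")
        if len(self.fly_ids) != self.x_mm.shape[0]:
            raise StampedeError("fly_ids length must match number of flies")

    @property
    def n_flies(self) -> int:
        return self.x_mm.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x_mm.shape[1]

    def fly(self, fly_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) series of one fly by id."""
        i = self.fly_ids.index(fly_id)
        return self.x_mm[i], self.y_mm[i]

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_frames
        return pd.DataFrame(
            {
                "fly_id": np.repeat(self.fly_ids, n),
                "frame": np.tile(np.arange(n), self.n_flies),
                "t_s": np.tile(self.t_s, self.n_flies),
                "x_mm": self.x_mm.ravel(),
                "y_mm": self.y_mm.ravel(),
            }
        )

    def to_csv(self, path: "str | Path") -> Path:
        """Write the long-format trajectory table (positions to 0.001 mm —
        byte-stable across reruns with the same config and seed)."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.3f")
        return path

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, arena: "ArenaGeometry | None" = None
    ) -> "TrajectorySet":
        fly_ids = tuple(int(i) for i in pd.unique(df["fly_id"]))
        frames = np.sort(pd.unique(df["frame"]))
        n = len(frames)
        t = np.full(n, np.nan)
        x = np.full((len(fly_ids), n), np.nan)
        y = np.full((len(fly_ids), n), np.nan)
        pos = {f: i for i, f in enumerate(frames)}
        for row in df.itertuples(index=False):
            j = pos[row.frame]
            i = fly_ids.index(int(row.fly_id))
            t[j] = row.t_s
            x[i, j] = row.x_mm
            y[i, j] = row.y_mm
        if np.isnan(t).any():
            raise StampedeError("trajectory table has frames with no time stamp")
        dt = np.diff(t)
        fps = 1.0 / np.median(dt) if n > 1 else 25.0
        return cls(
            t_s=t,
            x_mm=x,
            y_mm=y,
            fps=float(fps),
            fly_ids=fly_ids,
            arena=arena if arena is not None else ArenaGeometry(),
        )

    @classmethod
    def from_csv(
        cls, path: "str | Path", arena: "ArenaGeometry | None" = None
    ) -> "TrajectorySet":
        return cls.from_dataframe(pd.read_csv(path), arena=arena)


def _stim_arrays(timeline: StimulusTimeline, n_frames: int, fps: float):
    """Per-frame motion direction, stripe rate, and startle-onset flags."""
    dt = 1.0 / fps
    t = np.arange(n_frames) / fps
    motion_dir = np.zeros(n_frames, dtype=int)
    rate = np.zeros(n_frames)
    for i, ti in enumerate(t):
        s = stimulus_at(timeline, ti)
        motion_dir[i] = s.motion_dir
        rate[i] = s.rate_hz
    onset_flags = np.zeros(n_frames, dtype=bool)
    for o in timeline.startle_onsets():
        i = int(math.floor(o * fps))
        # onset falls in step [t_i, t_i + dt)
        if 0 <= i < n_frames and t[i] <= o < t[i] + dt:
            onset_flags[i] = True
        elif 0 <= i + 1 < n_frames:
            onset_flags[i + 1] = True
    return t, motion_dir, rate, onset_flags


def _arousal_series(
    params: AgentParams, onset_flags: np.ndarray, dt: float
) -> np.ndarray:
    """Arousal sampled at each frame (identical for all flies — the
    dynamics are deterministic given the timeline)."""
    n = len(onset_flags)
    a = np.zeros(n)
    decay = math.exp(-dt / params.tau_a_s) if params.tau_a_s > 0 else 0.0
    cur = 0.0
    for i in range(n):
        a[i] = cur
        cur = cur * decay + (params.a_incr if onset_flags[i] else 0.0)
    return a


def run_trial(
    timeline: StimulusTimeline,
    params: AgentParams,
    arena: "ArenaGeometry | None" = None,
    n_flies: int = 1,
    fps: float = 25.0,
    seed: int = 0,
    y_jitter_mm: float = 0.3,
) -> TrajectorySet:
    """Simulate ``n_flies`` independent flies for the full timeline.

    Deterministic given ``seed``; one sample per frame per fly (the
    standard 189-s timeline at 25 fps yields 4725 samples).  Motion is 1-D
    along the tube; y is tube centre plus clipped Gaussian jitter.  Each
    fly starts at a uniform random position with a random heading and zero
    arousal.
    """
    if fps <= 0:
        raise StampedeError(f"fps must be > 0, got {fps}")
    if n_flies < 1:
        raise StampedeError(f"n_flies must be >= 1, got {n_flies}")
    arena = arena if arena is not None else ArenaGeometry()
    dt = 1.0 / fps
    n_frames = int(round(timeline.total_s * fps))
    t, motion_dir, rate, onsets = _stim_arrays(timeline, n_frames, fps)
    arousal = _arousal_series(params, onsets, dt)
    # per-frame drift (mm) and walk step (mm); shared by all flies
    gain = np.zeros(n_frames)
    moving = rate > 0
    if params.g_max > 0 and moving.any():
        ga = np.exp(-((arousal - params.a_opt) ** 2) / (2 * params.a_sigma**2))
        lf = np.log(np.where(moving, rate, 1.0) / params.f_peak_hz)
        gf = np.exp(-(lf**2) / (2 * params.f_sigma**2))
        gain = np.where(moving, params.g_max * ga * gf, 0.0)
    drift = -motion_dir * gain * dt
    step = params.base_speed_mm_s * np.where(moving, params.motion_speed_boost, 1.0) * dt
    p_rev = 1.0 - math.exp(-params.reversal_rate_hz * dt)

    L = arena.length_mm
    x = np.empty((n_flies, n_frames))
    y = np.empty((n_flies, n_frames))
    children = np.random.SeedSequence(seed).spawn(n_flies)
    for j in range(n_flies):
        rng = np.random.default_rng(children[j])
        x0 = rng.uniform(0.0, L)
        heading = 1 if rng.random() < 0.5 else -1
        revs = rng.random(n_frames) < p_rev
        xj = x[j]
        cur = x0
        for i in range(n_frames):
            xj[i] = cur
            if revs[i]:
                heading = -heading
            cur = cur + heading * step[i] + drift[i]
            if cur <= 0.0:
                cur, heading = 0.0, 1
            elif cur >= L:
                cur, heading = L, -1
        yj = arena.width_mm / 2.0 + rng.normal(0.0, y_jitter_mm, n_frames)
        np.clip(yj, 0.0, arena.width_mm, out=yj)
        y[j] = yj
    return TrajectorySet(
        t_s=t, x_mm=x, y_mm=y, fps=fps, fly_ids=tuple(range(n_flies)), arena=arena
    )


@dataclass(frozen=True)
class ImagingParams:
    """Synthetic camera model: bright IR-backlit field, dark fly blobs.

    ``margin_px`` pads the arena on all sides so silhouettes of flies at
    the tube ends are never truncated by the image border.
    """

    px_per_mm: float = 4.0
    fps: float = 25.0
    bg_level: int = 220
    fly_depth: int = 150
    blob_sigma_px: float = 2.0
    noise_sigma: float = 0.0
    margin_px: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.px_per_mm <= 0:
            raise StampedeError("px_per_mm must be > 0")
        if not (0 < self.fly_depth <= self.bg_level):
            raise StampedeError("need 0 < fly_depth <= bg_level")


def render_frames(
    trajs: TrajectorySet,
    imaging: "ImagingParams | None" = None,
    arena: "ArenaGeometry | None" = None,
) -> FrameStack:
    """Render the trajectories as an 8-bit grayscale video.

    Each fly is a dark Gaussian silhouette of depth ``fly_depth`` on a
    uniform background ``bg_level``, plus optional seeded Gaussian pixel
    noise.  Image size is the arena at ``px_per_mm`` plus ``margin_px`` on
    every side; the arena origin in pixels is recorded on the FrameStack.
    """
    imaging = imaging if imaging is not None else ImagingParams()
    arena = arena if arena is not None else trajs.arena
    m = imaging.margin_px
    W = int(math.ceil(arena.length_mm * imaging.px_per_mm)) + 2 * m
    H = int(math.ceil(arena.width_mm * imaging.px_per_mm)) + 2 * m
    sigma = imaging.blob_sigma_px
    r = int(math.ceil(4 * sigma))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    n_frames = trajs.n_frames
    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    rng = np.random.default_rng(imaging.seed)
    for i in range(n_frames):
        img = np.full((H, W), float(imaging.bg_level))
        for j in range(trajs.n_flies):
            xm, ym = trajs.x_mm[j, i], trajs.y_mm[j, i]
            if np.isnan(xm):
                continue
            if not (0 <= xm <= arena.length_mm and 0 <= ym <= arena.width_mm):
                raise RenderError(
                    f"fly {trajs.fly_ids[j]} outside arena at frame {i}: "
                    f"({xm:.2f}, {ym:.2f}) mm"
                )
            cx = m + xm * imaging.px_per_mm
            cy = m + ym * imaging.px_per_mm
            cxi, cyi = int(round(cx)), int(round(cy))
            blob = imaging.fly_depth * np.exp(
                -((dx + cxi - cx) ** 2 + (dy + cyi - cy) ** 2) / (2 * sigma**2)
            )
            y0, y1 = max(0, cyi - r), min(H, cyi + r + 1)
            x0, x1 = max(0, cxi - r), min(W, cxi + r + 1)
            img[y0:y1, x0:x1] -= blob[
                y0 - (cyi - r) : y1 - (cyi - r), x0 - (cxi - r) : x1 - (cxi - r)
            ]
        if imaging.noise_sigma > 0:
            img += rng.normal(0.0, imaging.noise_sigma, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return FrameStack(
        frames=frames,
        fps=imaging.fps,
        px_per_mm=imaging.px_per_mm,
        origin_px=(float(m), float(m)),
    )
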