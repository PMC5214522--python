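"""Multi-fly video tracking: background estimation, dark-blob detection,
nearest-neighbour identity linking, and the population median-centroid trace.

The pipeline mirrors the classic stages for IR-backlit arena footage:
temporal-median background, background subtraction, thresholding,
connected-component centroids, then greedy nearest-pair frame-to-frame
assignment with a displacement gate and short gap interpolation.
Coordinates are 0-based pixels, centroids at sub-pixel precision, x
increasing left-to-right to match arena x.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import CalibrationWarning, InsufficientDataError, StampedeError
from .simulate import ArenaGeometry, TrajectorySet
from .video import FrameStack

__all__ = [
    "BackgroundImage",
    "Detection",
    "Track",
    "LinkedTracks",
    "estimate_background",
    "detect_flies",
    "detect_stack",
    "link_tracks",
    "median_centroid_trace",
    "tracks_to_mm",
]


@dataclass
class BackgroundImage:
    """Fly-free background estimate (same shape as the frames)."""

    image: np.ndarray  # float
    method: str = "temporal_median"
    n_samples: int = 0


@dataclass(frozen=True)
class Detection:
    """One candidate fly in one frame (intensity-weighted centroid)."""

    x_px: float
    y_px: float
    area_px: int
    mean_depth: float


@dataclass
class Track:
    """One fly identity: frame-indexed positions, with interpolated
    (gap-filled) points flagged."""

    track_id: int
    frames: np.ndarray  # int
    x_px: np.ndarray
    y_px: np.ndarray
    interpolated: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class LinkedTracks:
    tracks: tuple[Track, ...]

    def __len__(self) -> int:
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": tr.frames,
                    "x_px": tr.x_px,
                    "y_px": tr.y_px,
                    "interpolated": tr.interpolated.astype(int),
                }
            )
            for tr in self.tracks
        ]
        if not parts:
            return pd.DataFrame(
                columns=["track_id", "frame", "x_px", "y_px", "interpolated"]
            )
        return pd.concat(parts, ignore_index=True)


def estimate_background(stack: FrameStack, stride: int = 10) -> BackgroundImage:
    """Pixel-wise temporal median over every ``stride``-th frame.

    The median rejects a moving fly as long as it occupies any given pixel
    in fewer than half of the sampled frames.  Requires >= 3 samples.
    """
    if stride < 1:
        raise StampedeError(f"stride must be >= 1, got {stride}")
    sampled = stack.frames[::stride]
    if sampled.shape[0] < 3:
        raise InsufficientDataError(
            f"background estimation needs >= 3 sampled frames, got {sampled.shape[0]} "
            f"(stack of {len(stack)} at stride {stride})"
        )
    med = np.median(sampled.astype(float), axis=0)
    return BackgroundImage(image=med, n_samples=sampled.shape[0])


def detect_flies(
    frame: np.ndarray,
    bg: BackgroundImage,
    threshold: float = 50.0,
    min_area: int = 5,
    max_area: int = 400,
) -> list[Detection]:
    """Dark blobs in one frame: ``d = bg - frame``, threshold, 8-connected
    components, area gate, intensity-weighted centroids."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != bg.image.shape:
        raise StampedeError(
            f"frame shape {frame.shape} != background shape {bg.image.shape}"
        )
    if threshold <= 0:
        raise StampedeError(f"threshold must be > 0, got {threshold}")
    d = bg.image - frame
    mask = d >= threshold
    labels = measure.label(mask, connectivity=2)
    out: list[Detection] = []
    for rp in measure.regionprops(labels, intensity_image=d):
        if not (min_area <= rp.area <= max_area):
            continue
        cy, cx = rp.centroid_weighted
        out.append(
            Detection(
                x_px=float(cx),
                y_px=float(cy),
                area_px=int(rp.area),
                mean_depth=float(rp.intensity_mean),
            )
        )
    out.sort(key=lambda det: (det.x_px, det.y_px))
    return out


def detect_stack(
    stack: FrameStack,
    bg: "BackgroundImage | None" = None,
    threshold: float = 50.0,
    min_area: int = 5,
    max_area: int = 400,
    bg_stride: int = 10,
) -> list[list[Detection]]:
    """Run :func:`detect_flies` over every frame of a stack."""
    if bg is None:
        bg = estimate_background(stack, stride=bg_stride)
    return [
        detect_flies(f, bg, threshold=threshold, min_area=min_area, max_area=max_area)
        for f in stack.frames
    ]


class _OpenTrack:
    __slots__ = ("track_id", "frames", "xs", "ys", "flags", "missed")

    def __init__(self, track_id: int, frame: int, det: Detection):
        self.track_id = track_id
        self.frames = [frame]
        self.xs = [det.x_px]
        self.ys = [det.y_px]
        self.flags = [False]
        self.missed = 0

    def claim(self, frame: int, det: Detection):
        lf, lx, ly = self.frames[-1], self.xs[-1], self.ys[-1]
        gap = frame - lf
        for k in range(1, gap):  # linear gap fill, flagged
            w = k / gap
            self.frames.append(lf + k)
            self.xs.append(lx + w * (det.x_px - lx))
            self.ys.append(ly + w * (det.y_px - ly))
            self.flags.append(True)
        self.frames.append(frame)
        self.xs.append(det.x_px)
        self.ys.append(det.y_px)
        self.flags.append(False)
        self.missed = 0

    def freeze(self) -> Track:
        return Track(
            track_id=self.track_id,
            frames=np.asarray(self.frames, dtype=int),
            x_px=np.asarray(self.xs, dtype=float),
            y_px=np.asarray(self.ys, dtype=float),
            interpolated=np.asarray(self.flags, dtype=bool),
        )


def link_tracks(
    detections: Sequence[Sequence[Detection]],
    gate_px: float = 10.0,
    max_gap: int = 2,
) -> LinkedTracks:
    """Link per-frame detections into identity-preserving tracks.

    Greedy globally-nearest-pair assignment per frame transition: the
    closest unmatched (track, detection) pair is claimed first, distances
    above ``gate_px`` (scaled by the number of missed frames + 1) are never
    assigned.  Unclaimed detections seed new tracks; a track unmatched for
    more than ``max_gap`` consecutive frames is terminated, shorter gaps
    are linearly interpolated and flagged.  Ties in distance break on lower
    track id, then lower detection index — output is deterministic.
    """
    if gate_px <= 0:
        raise StampedeError(f"gate_px must be > 0, got {gate_px}")
    if max_gap < 0:
        raise StampedeError(f"max_gap must be >= 0, got {max_gap}")
    active: list[_OpenTrack] = []
    finished: list[Track] = []
    next_id = 0
    for frame, dets in enumerate(detections):
        cands = []
        for tr in active:
            allowed = gate_px * (tr.missed + 1)
            for di, det in enumerate(dets):
                dist = math.hypot(det.x_px - tr.xs[-1], det.y_px - tr.ys[-1])
                if dist <= allowed:
                    cands.append((dist, tr.track_id, di, tr))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        claimed_tracks: set[int] = set()
        claimed_dets: set[int] = set()
        for dist, tid, di, tr in cands:
            if tid in claimed_tracks or di in claimed_dets:
                continue
            tr.claim(frame, dets[di])
            claimed_tracks.add(tid)
            claimed_dets.add(di)
        still_active: list[_OpenTrack] = []
        for tr in active:
            if tr.track_id in claimed_tracks:
                still_active.append(tr)
            else:
                tr.missed += 1
                if tr.missed > max_gap:
                    finished.append(tr.freeze())
                else:
                    still_active.append(tr)
        active = still_active
        for di, det in enumerate(dets):
            if di not in claimed_dets:
                active.append(_OpenTrack(next_id, frame, det))
                next_id += 1
    finished.extend(tr.freeze() for tr in active)
    finished.sort(key=lambda tr: tr.track_id)
    return LinkedTracks(tracks=tuple(finished))


def median_centroid_trace(
    detections: Sequence[Sequence[Detection]],
) -> np.ndarray:
    """Coordinate-wise median detection position per frame, shape
    ``(n_frames, 2)`` as (x, y); frames with no detections are NaN."""
    n = len(detections)
    out = np.full((n, 2), np.nan)
    for i, dets in enumerate(detections):
        if dets:
            out[i, 0] = np.median([d.x_px for d in dets])
            out[i, 1] = np.median([d.y_px for d in dets])
    return out


def tracks_to_mm(
    tracks: LinkedTracks,
    px_per_mm: float,
    arena_origin_px: "tuple[float, float] | float" = (0.0, 0.0),
    fps: float = 25.0,
    arena: "ArenaGeometry | None" = None,
    tolerance_mm: float = 2.0,
) -> TrajectorySet:
    """Convert pixel tracks to arena millimetres on a uniform time base.

    ``x_mm = (x_px - origin_x) / px_per_mm`` (same for y).  Frames where a
    track has no point are NaN.  Positions outside the arena by more than
    ``tolerance_mm`` raise a :class:`CalibrationWarning`.
    """
    if px_per_mm <= 0:
        raise StampedeError(f"px_per_mm must be > 0, got {px_per_mm}")
    if np.isscalar(arena_origin_px):
        origin = (float(arena_origin_px), float(arena_origin_px))
    else:
        origin = (float(arena_origin_px[0]), float(arena_origin_px[1]))
    arena = arena if arena is not None else ArenaGeometry()
    if not tracks.tracks:
        raise StampedeError("no tracks to convert")
    f0 = min(int(tr.frames.min()) for tr in tracks.tracks)
    f1 = max(int(tr.frames.max()) for tr in tracks.tracks)
    n = f1 - f0 + 1
    x = np.full((len(tracks.tracks), n), np.nan)
    y = np.full((len(tracks.tracks), n), np.nan)
    ids = []
    for i, tr in enumerate(tracks.tracks):
        ids.append(tr.track_id)
        idx = tr.frames - f0
        x[i, idx] = (tr.x_px - origin[0]) / px_per_mm
        y[i, idx] = (tr.y_px - origin[1]) / px_per_mm
    finite = x[np.isfinite(x)]
    if finite.size and (
        finite.min() < -tolerance_mm or finite.max() > arena.length_mm + tolerance_mm
    ):
        warnings.warn(
            "tracked positions fall outside the arena beyond tolerance; "
            "check px_per_mm and arena_origin_px",
            CalibrationWarning,
            stacklevel=2,
        )
    t = (np.arange(n) + f0) / fps
    return TrajectorySet(
        t_s=t, x_mm=x, y_mm=y, fps=fps, fly_ids=tuple(ids), arena=arena
    )
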