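"""The simulate → render → track → score pipeline and its run manifest.

Every artifact of a run lands in one output directory together with a
``manifest.json`` listing the configuration hash and every file written.
Rerunning with the same config and seed reproduces byte-identical
trajectory CSVs.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, config_hash
from .errors import PipelineDependencyError, StampedeError
from .metrics import correct_quadrant_score, mean_velocity, occupancy_fractions
from .protocol import build_standard_timeline
from .simulate import TrajectorySet, render_frames, run_trial
from .track import detect_stack, link_tracks, median_centroid_trace, tracks_to_mm
from .video import read_video, write_video

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "render", "track", "score")

logger = logging.getLogger("stampede")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config_hash: str
    seed: int
    stages: tuple[str, ...]
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    started: str
    finished: str
    log_path: str

    def to_json(self, path: "str | Path") -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=list) + "\n")
        return path


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineDependencyError(
            f"stage '{stage}' needs {path.name}, produced by '{produced_by}' "
            f"(run that stage first or place the file in the output directory)"
        )
    return path


def run_pipeline(
    config: RunConfig,
    out_dir: "str | Path",
    stages: "tuple[str, ...] | list[str]" = STAGES,
) -> RunManifest:
    """Execute a contiguous subset of pipeline stages.

    ``simulate`` writes ground-truth ``trajectories.csv``; ``render``
    writes ``video.tif``; ``track`` recovers ``tracked_trajectories.csv``
    (plus detections and pixel tracks); ``score`` writes per-fly phase
    scores, occupancy and velocities to ``scores.json``/``scores.csv``,
    using tracked trajectories when available and ground truth otherwise.
    """
    stages = tuple(stages)
    if not stages:
        raise StampedeError("no stages requested")
    idx = []
    for s in stages:
        if s not in STAGES:
            raise StampedeError(f"unknown stage {s!r}; valid: {STAGES}")
        idx.append(STAGES.index(s))
    ordered = tuple(STAGES[i] for i in sorted(set(idx)))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    started = datetime.datetime.now().isoformat(timespec="seconds")
    outputs: list[str] = ["run.log"]
    inputs: list[str] = []
    chash = config_hash(config)
    logger.info("run start: stages=%s seed=%d config=%s", ordered, config.seed, chash)

    timeline = build_standard_timeline(config.assay)
    trajs: "TrajectorySet | None" = None
    traj_csv = out / "trajectories.csv"
    video_path = out / "video.tif"
    tracked_csv = out / "tracked_trajectories.csv"

    try:
        for stage in ordered:
            t0 = time.perf_counter()
            if stage == "simulate":
                trajs = run_trial(
                    timeline,
                    config.agent,
                    n_flies=config.n_flies,
                    fps=config.fps,
                    seed=config.seed,
                )
                trajs.to_csv(traj_csv)
                outputs.append(traj_csv.name)
            elif stage == "render":
                if trajs is None:
                    _require(traj_csv, "render", "simulate")
                    inputs.append(traj_csv.name)
                    trajs = TrajectorySet.from_csv(traj_csv)
                stack = render_frames(trajs, config.imaging)
                write_video(stack, video_path)
                outputs.append(video_path.name)
            elif stage == "track":
                _require(video_path, "track", "render")
                if video_path.name not in outputs:
                    inputs.append(video_path.name)
                m = float(config.imaging.margin_px)
                stack = read_video(
                    video_path,
                    fps=config.fps,
                    px_per_mm=config.imaging.px_per_mm,
                    origin_px=(m, m),
                )
                tp = config.tracker
                dets = detect_stack(
                    stack,
                    threshold=tp.threshold,
                    min_area=tp.min_area,
                    max_area=tp.max_area,
                    bg_stride=tp.bg_stride,
                )
                rows = [
                    (f, d.x_px, d.y_px, d.area_px)
                    for f, frame_dets in enumerate(dets)
                    for d in frame_dets
                ]
                det_csv = out / "detections.csv"
                with det_csv.open("w") as fh:
                    fh.write("frame,x_px,y_px,area_px\n")
                    for f, x, y, a in rows:
                        fh.write(f"{f},{x:.1f},{y:.1f},{a}\n")
                outputs.append(det_csv.name)
                med = median_centroid_trace(dets)
                med_csv = out / "median_trace.csv"
                with med_csv.open("w") as fh:
                    fh.write("frame,x_px,y_px\n")
                    for f in range(len(med)):
                        fh.write(f"{f},{med[f, 0]:.1f},{med[f, 1]:.1f}\n")
                outputs.append(med_csv.name)
                linked = link_tracks(dets, gate_px=tp.gate_px, max_gap=tp.max_gap)
                tracks_csv = out / "tracks.csv"
                linked.to_dataframe().to_csv(
                    tracks_csv, index=False, float_format="%.1f"
                )
                outputs.append(tracks_csv.name)
                tracked = tracks_to_mm(
                    linked,
                    px_per_mm=stack.px_per_mm,
                    arena_origin_px=stack.origin_px,
                    fps=stack.fps,
                )
                tracked.to_csv(tracked_csv)
                outputs.append(tracked_csv.name)
            elif stage == "score":
                if tracked_csv.exists():
                    source = tracked_csv
                elif trajs is not None or traj_csv.exists():
                    source = traj_csv
                    if trajs is not None and not traj_csv.exists():
                        trajs.to_csv(traj_csv)
                        outputs.append(traj_csv.name)
                else:
                    raise PipelineDependencyError(
                        "stage 'score' needs trajectories (tracked_trajectories.csv "
                        "or trajectories.csv); run 'simulate' or 'track' first"
                    )
                if source.name not in outputs:
                    inputs.append(source.name)
                scored = TrajectorySet.from_csv(source)
                results = _score(scored, timeline, config, chash)
                scores_json = out / "scores.json"
                scores_json.write_text(json.dumps(results, indent=2) + "\n")
                outputs.append(scores_json.name)
                scores_csv = out / "scores.csv"
                with scores_csv.open("w") as fh:
                    fh.write("fly_id,phase,target_quadrant,pct_correct\n")
                    for fly in results["flies"]:
                        for ps in fly["phase_scores"]:
                            fh.write(
                                f"{fly['fly_id']},{ps['phase']},"
                                f"{ps['target_quadrant']},{ps['pct_correct']:.2f}\n"
                            )
                outputs.append(scores_csv.name)
            logger.info("stage %s done in %.2f s", stage, time.perf_counter() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()

    finished = datetime.datetime.now().isoformat(timespec="seconds")
    outputs.append("manifest.json")
    manifest = RunManifest(
        version=__version__,
        config_hash=chash,
        seed=config.seed,
        stages=ordered,
        inputs=tuple(dict.fromkeys(inputs)),
        outputs=tuple(dict.fromkeys(outputs)),
        started=started,
        finished=finished,
        log_path=str(log_path),
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _score(trajs: TrajectorySet, timeline, config: RunConfig, chash: str) -> dict:
    """Per-fly phase scores, full-trial occupancy and per-condition
    velocities, keyed by config hash and seed."""
    flies = []
    rest_windows = [
        (s, s + b.duration_s)
        for s, b in timeline.blocks
        if type(b).__name__ == "RestBlock"
    ]
    motion_windows = [(s, s + b.duration_s) for s, b in timeline.motion_blocks()]
    for fid in trajs.fly_ids:
        phase_scores = [
            {
                "phase": ps.phase,
                "target_quadrant": ps.target_quadrant,
                "pct_correct": round(ps.pct_correct, 3),
                "window": list(ps.window),
            }
            for ps in correct_quadrant_score(trajs, timeline, fly=fid)
        ]
        occ = occupancy_fractions(trajs, (0.0, timeline.total_s), fly=fid)
        entry = {
            "fly_id": int(fid),
            "phase_scores": phase_scores,
            "occupancy": [round(f, 4) for f in occ.fractions],
        }
        if motion_windows:
            entry["mean_velocity_motion_mm_s"] = round(
                float(
                    np.mean(
                        [mean_velocity(trajs, w, fly=fid) for w in motion_windows]
                    )
                ),
                3,
            )
        if rest_windows:
            entry["mean_velocity_rest_mm_s"] = round(
                float(
                    np.mean([mean_velocity(trajs, w, fly=fid) for w in rest_windows])
                ),
                3,
            )
        flies.append(entry)
    return {"config_hash": chash, "seed": config.seed, "flies": flies}
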