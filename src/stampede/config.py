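"""Run configuration: JSON schema, validation, defaults, hashing.

A run config is a single JSON object::

    {
      "startle": {"n_events": 2, "event_s": 1.0, "gap_s": 1.0},
      "motion":  {"rate_hz": 25.0, "duration_s": 60.0},
      "rest_s":  60.0,
      "panel":   {"n_rows": 16, "n_cols": 32, "stripe_cols": 2},
      "preset":  "wildtype",
      "n_flies": 1,
      "fps":     25.0,
      "seed":    0,
      "imaging": {"px_per_mm": 4.0, ...},
      "tracker": {"threshold": 50.0, ...}
    }

Every key is optional — an empty object reproduces the standard assay
with the wildtype preset.  Unknown keys are rejected with an error naming
the offending key.  Packaged defaults: ``default_assay.json`` (standard
assay), ``no_buzz_assay.json`` (startle disabled) and
``strong_buzz_assay.json`` (three 2-s buzzes with 1-s intervals).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigError, ProtocolError, StampedeError
from .protocol import AssayConfig, PanelGeometry, StartleBlock
from .simulate import AgentParams, ImagingParams, get_preset

__all__ = [
    "TrackerParams",
    "RunConfig",
    "load_config",
    "config_hash",
    "packaged_config_path",
]


@dataclass(frozen=True)
class TrackerParams:
    """Detection and linking parameters (defaults tuned on the renderer)."""

    threshold: float = 50.0
    min_area: int = 5
    max_area: int = 400
    gate_px: float = 10.0
    max_gap: int = 2
    bg_stride: int = 10


@dataclass(frozen=True)
class RunConfig:
    """Fully validated parameters of one pipeline run."""

    assay: AssayConfig = field(default_factory=AssayConfig)
    preset: str = "wildtype"
    agent: AgentParams = field(default_factory=lambda: get_preset("wildtype"))
    n_flies: int = 1
    fps: float = 25.0
    seed: int = 0
    imaging: ImagingParams = field(default_factory=ImagingParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)

    def to_dict(self) -> dict:
        return {
            "startle": {
                "n_events": self.assay.startle.n_events,
                "event_s": self.assay.startle.event_s,
                "gap_s": self.assay.startle.gap_s,
            },
            "motion": {
                "rate_hz": self.assay.motion_rate_hz,
                "duration_s": self.assay.motion_s,
            },
            "rest_s": self.assay.rest_s,
            "panel": asdict(self.assay.panel),
            "preset": self.preset,
            "n_flies": self.n_flies,
            "fps": self.fps,
            "seed": self.seed,
            "imaging": asdict(self.imaging),
            "tracker": asdict(self.tracker),
        }


def _take(section: dict, section_name: str, allowed: dict) -> dict:
    """Pop known keys with defaults; reject unknown keys by name."""
    out = {}
    for key, default in allowed.items():
        out[key] = section.get(key, default)
    for key in section:
        if key not in allowed:
            name = f"{section_name}.{key}" if section_name else key
            raise ConfigError(name, "unknown configuration key")
    return out


def _build(raw: dict, source: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(source, "configuration root must be a JSON object")
    top = {
        "startle": {},
        "motion": {},
        "rest_s": 60.0,
        "panel": {},
        "preset": "wildtype",
        "n_flies": 1,
        "fps": 25.0,
        "seed": 0,
        "imaging": {},
        "tracker": {},
    }
    vals = _take(raw, "", top)
    st = _take(vals["startle"] or {}, "startle", {"n_events": 2, "event_s": 1.0, "gap_s": 1.0})
    mo = _take(vals["motion"] or {}, "motion", {"rate_hz": 25.0, "duration_s": 60.0})
    pa = _take(
        vals["panel"] or {}, "panel", {"n_rows": 16, "n_cols": 32, "stripe_cols": 2}
    )
    im = _take(vals["imaging"] or {}, "imaging", {f: getattr(ImagingParams(), f) for f in ImagingParams.__dataclass_fields__})
    tr = _take(vals["tracker"] or {}, "tracker", {f: getattr(TrackerParams(), f) for f in TrackerParams.__dataclass_fields__})

    try:
        startle = StartleBlock(**st)
    except ProtocolError as e:
        raise ConfigError("startle", str(e)) from None
    if mo["rate_hz"] < 0:
        raise ConfigError("motion.rate_hz", f"must be >= 0, got {mo['rate_hz']}")
    if mo["duration_s"] <= 0:
        raise ConfigError("motion.duration_s", f"must be > 0, got {mo['duration_s']}")
    if vals["rest_s"] <= 0:
        raise ConfigError("rest_s", f"must be > 0, got {vals['rest_s']}")
    try:
        panel = PanelGeometry(**pa)
    except ProtocolError as e:
        raise ConfigError("panel", str(e)) from None
    try:
        agent = get_preset(vals["preset"])
    except StampedeError as e:
        raise ConfigError("preset", str(e)) from None
    if vals["n_flies"] < 1:
        raise ConfigError("n_flies", f"must be >= 1, got {vals['n_flies']}")
    if vals["fps"] <= 0:
        raise ConfigError("fps", f"must be > 0, got {vals['fps']}")
    try:
        imaging = ImagingParams(**im)
    except StampedeError as e:
        raise ConfigError("imaging", str(e)) from None
    if tr["threshold"] <= 0:
        raise ConfigError("tracker.threshold", f"must be > 0, got {tr['threshold']}")
    if tr["gate_px"] <= 0:
        raise ConfigError("tracker.gate_px", f"must be > 0, got {tr['gate_px']}")
    assay = AssayConfig(
        startle=startle,
        motion_rate_hz=float(mo["rate_hz"]),
        motion_s=float(mo["duration_s"]),
        rest_s=float(vals["rest_s"]),
        panel=panel,
    )
    return RunConfig(
        assay=assay,
        preset=str(vals["preset"]),
        agent=agent,
        n_flies=int(vals["n_flies"]),
        fps=float(vals["fps"]),
        seed=int(vals["seed"]),
        imaging=imaging,
        tracker=TrackerParams(**tr),
    )


def load_config(
    path: "str | Path | None" = None, overrides: "dict | None" = None
) -> RunConfig:
    """Load and validate a run config from JSON.

    With no path the packaged standard-assay defaults are used.
    ``overrides`` (e.g. ``{"seed": 7, "preset": "null"}``) are applied on
    top of the file's contents before validation."""
    if path is None:
        raw: dict = {}
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(str(path), "configuration file not found")
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ConfigError(str(path), f"invalid JSON: {e}") from None
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict) and isinstance(raw.get(k), dict):
                raw[k] = {**raw[k], **v}
            else:
                raw[k] = v
    return _build(raw, source=str(path) if path else "<defaults>")


def packaged_config_path(name: str = "default_assay") -> Path:
    """Path to a packaged config (``default_assay``, ``no_buzz_assay``,
    ``strong_buzz_assay``)."""
    p = resources.files("stampede.data").joinpath(f"{name}.json")
    with resources.as_file(p) as fp:
        return Path(fp)


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form — stable under key reordering."""
    blob = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()
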