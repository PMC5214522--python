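"""Grayscale video container and file I/O (multi-page TIFF, AVI).

Frames are 8-bit, dark flies on a bright IR-backlit field, indexed
``(frame, row, col)`` with x increasing left-to-right to match arena x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import StampedeError

__all__ = ["FrameStack", "write_video", "read_video"]


@dataclass
class FrameStack:
    """A stack of same-shape grayscale frames with imaging metadata.

    ``origin_px`` is the pixel coordinate (x, y) of the arena corner
    (x_mm = 0, y_mm = 0); renders with a margin record it here so tracked
    pixel positions can be mapped back to arena millimetres.
    """

    frames: np.ndarray  # (n_frames, n_rows, n_cols) uint8
    fps: float
    px_per_mm: float
    origin_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise StampedeError(
                f"frames must be (n_frames, rows, cols), got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise StampedeError(f"fps must be > 0, got {self.fps}")
        if self.px_per_mm <= 0:
            raise StampedeError(f"px_per_mm must be > 0, got {self.px_per_mm}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def write_video(stack: FrameStack, path: "str | Path") -> Path:
    """Write the stack as a multi-page TIFF (the default interchange
    format; AVI output requires an ffmpeg-backed imageio plugin)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.frames)
    elif path.suffix.lower() == ".avi":
        import imageio.v2 as imageio

        imageio.mimwrite(path, list(stack.frames), fps=stack.fps)
    else:
        raise StampedeError(f"unsupported video format: {path.suffix}")
    return path


def read_video(
    path: "str | Path",
    fps: float,
    px_per_mm: float,
    origin_px: tuple[float, float] = (0.0, 0.0),
) -> FrameStack:
    """Read a multi-page TIFF or AVI into a FrameStack.

    TIFF carries no timing/scale metadata, so ``fps`` and ``px_per_mm``
    must be supplied (the pipeline takes them from the run config)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    else:
        import imageio.v2 as imageio

        frames = np.stack([np.asarray(f) for f in imageio.mimread(path, memtest=False)])
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # RGB -> grayscale
        frames = frames.mean(axis=-1).astype(np.uint8)
    return FrameStack(frames=frames, fps=fps, px_per_mm=px_per_mm, origin_px=origin_px)
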