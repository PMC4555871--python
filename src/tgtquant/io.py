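"""TIFF and sidecar I/O.

Frames and stacks travel as 16-bit TIFF (the native camera format); ground
truth and calibrations as JSON; per-spot tables and manifests as CSV.
Pixel size and frame interval are carried in a sidecar JSON because plain
TIFF has no reliable slot for them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .simulate import ImageFrame, ImageStack

__all__ = ["write_frame", "read_frame", "write_stack", "read_stack"]


def _to_uint16(data: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(data), 0, 65535).astype(np.uint16)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame(frame: ImageFrame, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, _to_uint16(frame.data))
    _sidecar(path).write_text(json.dumps({"pixel_size_um": frame.pixel_size}))


def read_frame(path, pixel_size: float | None = None) -> ImageFrame:
    path = Path(path)
    data = tifffile.imread(path)
    if pixel_size is None:
        meta = json.loads(_sidecar(path).read_text())
        pixel_size = meta["pixel_size_um"]
    return ImageFrame(np.asarray(data, dtype=float), pixel_size)


def write_stack(stack: ImageStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, _to_uint16(stack.data))
    _sidecar(path).write_text(
        json.dumps(
            {"pixel_size_um": stack.pixel_size, "frame_interval_s": stack.frame_interval}
        )
    )


def read_stack(path, pixel_size: float | None = None, frame_interval: float | None = None) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    if pixel_size is None or frame_interval is None:
        meta = json.loads(_sidecar(path).read_text())
        pixel_size = pixel_size or meta["pixel_size_um"]
        frame_interval = frame_interval or meta["frame_interval_s"]
    return ImageStack(np.asarray(data, dtype=float), pixel_size, frame_interval)
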