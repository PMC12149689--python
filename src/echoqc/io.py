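"""Video container and frame-stack reading/writing.

A video is an ordered stack of grayscale frames in [0, 1] with frame-rate
metadata.  On disk the canonical representation is a directory of
numerically ordered PNG (or TIFF) frames, which keeps everything plain and
diffable; common video containers are attempted through imageio when a
suitable plugin is available.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Video", "read_video", "write_video_frames"]

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class Video:
    frames: np.ndarray  # (T, H, W) float in [0, 1]
    fps: float = 30.0
    video_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


def _numeric_key(name: str):
    m = re.search(r"(\d+)", name)
    return (0, int(m.group(1)), name) if m else (1, 0, name)


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) -> luma
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def read_video(path: str | Path, fps: float = 30.0) -> Video:
    """Read a video from a frame directory or a decodable container.

    Directory frames are ordered by the first integer in each filename
    (natural numeric sort); filenames without digits fall back to
    lexicographic order with a warning.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise IOError(f"no image frames found in {path}")
        if any(not re.search(r"\d", p.name) for p in files):
            warnings.warn(
                "frame filenames contain no digits; falling back to lexicographic order"
            )
        else:
            files = sorted(files, key=lambda p: _numeric_key(p.name))
        frames = [_to_gray01(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise IOError(f"mixed frame sizes in {path}: {sorted(shapes)}")
        return Video(frames=np.stack(frames), fps=fps, video_id=path.name)
    if not path.exists():
        raise IOError(f"no such video: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - plugin availability varies
        raise IOError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 4):
        # (T,H,W,C) stack or single RGB image heuristics
        if arr.ndim == 3:
            arr = arr[None]
        arr = np.stack([_to_gray01(f) for f in arr])
    else:
        arr = np.stack([_to_gray01(f) for f in arr])
    return Video(frames=arr, fps=fps, video_id=path.stem)


def write_video_frames(video: Video, out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded 8-bit PNGs; returns the written paths."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(video.n_frames)))
    paths = []
    for t in range(video.n_frames):
        p = out_dir / f"frame_{t:0{width}d}.png"
        iio.imwrite(p, (np.clip(video.frames[t], 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths
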