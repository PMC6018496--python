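"""Frame-sequence and trajectory-table I/O.

Pixel coordinates are ``(u, v) = (column, row)``, 0-based, origin at the image
top-left, everywhere in the package.  Frames are 2-D grayscale arrays; 8-bit
intensities in ``[0, 255]`` are the native on-disk representation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError

#: ITU-R BT.601 luma weights used to collapse colour frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = {".png", ".pgm", ".ppm", ".tif", ".tiff", ".bmp"}

TRACK_STATUSES = ("init", "tracked", "redetected", "lost")


@dataclass
class FrameSequence:
    """Ordered grayscale frames plus acquisition metadata.

    Parameters
    ----------
    frames
        List of 2-D arrays, all the same height x width.
    fps
        Acquisition frame rate (the wind-tunnel rig runs at 60 fps).
    frame_index_origin
        Index assigned to ``frames[0]``; downstream trajectory records use
        ``frame_index_origin + i``.
    value_range
        Either ``"uint8"`` (values in [0, 255]) or ``"unit"`` (values in
        [0, 1]); recorded so feature extraction can normalise consistently.
    """

    frames: list = field(repr=False)
    fps: float = 60.0
    frame_index_origin: int = 0
    value_range: str = "uint8"

    def __post_init__(self):
        if not self.frames:
            raise FormatError("frame sequence is empty")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        shape = np.asarray(self.frames[0]).shape
        for i, f in enumerate(self.frames):
            f = np.asarray(f)
            if f.ndim != 2:
                raise FormatError(f"frame {i} is not 2-D (shape {f.shape})")
            if f.shape != shape:
                raise FormatError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )

    @property
    def frame_shape(self) -> tuple:
        return np.asarray(self.frames[0]).shape

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class TrajectoryRecord:
    """Per-frame 2-D centroid of the tracked target.

    ``status`` is one of ``init`` (manually boxed first frame), ``tracked``
    (correlation-filter detection), ``redetected`` (recovered by background
    subtraction after a loss) or ``lost`` (position held from the previous
    frame).
    """

    frame: int
    u: float
    v: float
    status: str = "tracked"

    def __post_init__(self):
        if self.status not in TRACK_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != "lost" and not (
            np.isfinite(self.u) and np.isfinite(self.v)
        ):
            raise ValueError("centroid must be finite unless status is 'lost'")


def _natural_key(path: Path):
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return (img[..., :3].astype(float) @ _LUMA).astype(img.dtype)
    raise FormatError(f"cannot interpret image of shape {img.shape} as a frame")


def read_frames(path, to_gray: bool = True, fps: float = 60.0) -> FrameSequence:
    """Read a directory/glob of numbered images, or a video file, as frames.

    Image files are ordered by natural (numeric-aware) filename sort, which
    matches acquisition order for zero-padded or plain frame counters.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=_natural_key,
        )
        if not files:
            raise FormatError(f"no decodable image frames in {path}")
        frames = [iio.imread(p) for p in files]
    elif path.exists():
        try:
            frames = [np.asarray(f) for f in iio.imiter(path)]
        except Exception as exc:  # pragma: no cover - codec availability
            raise FormatError(f"could not decode {path}: {exc}") from exc
        if not frames:
            raise FormatError(f"zero decodable frames in {path}")
    else:
        # Treat as a glob pattern relative to the parent directory.
        files = sorted(path.parent.glob(path.name), key=_natural_key)
        if not files:
            raise FileNotFoundError(f"no such file or frame pattern: {path}")
        frames = [iio.imread(p) for p in files]
    if to_gray:
        frames = [_to_gray(f) for f in frames]
    rng = "uint8"
    if frames[0].dtype.kind == "f" and np.nanmax(frames[0]) <= 1.5:
        rng = "unit"
    return FrameSequence(frames=frames, fps=fps, value_range=rng)


def write_frames(seq: FrameSequence, out_dir, prefix: str = "frame",
                 fmt: str = "png") -> list:
    """Write a sequence as zero-padded lossless image files; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(seq))))
    paths = []
    for i, frame in enumerate(seq.frames):
        frame = np.asarray(frame)
        if frame.dtype != np.uint8:
            if seq.value_range == "unit":
                frame = np.clip(np.round(frame * 255.0), 0, 255)
            frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
        p = out_dir / f"{prefix}_{i:0{width}d}.{fmt}"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_trajectory(records: Sequence[TrajectoryRecord], path) -> None:
    """Write per-frame centroids as CSV with header ``frame,u,v,status``."""
    df = pd.DataFrame(
        {
            "frame": [r.frame for r in records],
            "u": [r.u for r in records],
            "v": [r.v for r in records],
            "status": [r.status for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.4f")


def read_trajectory(path) -> list:
    df = pd.read_csv(path)
    return [
        TrajectoryRecord(int(r.frame), float(r.u), float(r.v), str(r.status))
        for r in df.itertuples()
    ]


def write_trajectory3d(frames: Iterable[int], points_mm: np.ndarray,
                       statuses: Iterable[str], path) -> None:
    """Write fused 3-D centroids (mm) as ``frame,x_mm,y_mm,z_mm,status``."""
    points_mm = np.asarray(points_mm, dtype=float)
    df = pd.DataFrame(
        {
            "frame": list(frames),
            "x_mm": points_mm[:, 0],
            "y_mm": points_mm[:, 1],
            "z_mm": points_mm[:, 2],
            "status": list(statuses),
        }
    )
    df.to_csv(path, index=False, float_format="%.4f")


def read_trajectory3d(path):
    df = pd.read_csv(path)
    frames = df["frame"].to_numpy(dtype=int)
    points = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    statuses = [str(s) for s in df["status"]]
    return frames, points, statuses
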