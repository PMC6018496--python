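"""Orthogonal two-view 3-D reconstruction in the wind-tunnel frame.

World coordinates: x along the tunnel length, y along its depth, z along its
height, origin at the tunnel's top-left, all in millimetres.  The top-view
camera images (x, y); the side-view camera images (x, z); each pinhole ray
constrains two world coordinates, and the shared x axis makes the stacked
system over-determined, which is resolved by linear least squares (with
symmetric cameras this coincides with simply averaging the two abscissae).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

from .errors import GeometryError
from .io_formats import TrajectoryRecord

AXES = ("top_down", "side_on")


@dataclass
class CameraModel:
    """Zero-skew pinhole camera looking along one tunnel axis.

    ``standoff_mm`` is the distance from the optical centre to the tunnel
    origin plane along the viewing axis: the imaging depth of a point is
    ``standoff - z`` for the top camera and ``standoff - y`` for the side
    camera, so the standoff must exceed the tunnel extent along that axis.
    """

    f_px: float
    cu: float
    cv: float
    axis: str = "top_down"
    standoff_mm: float = 1500.0

    def __post_init__(self):
        if self.f_px <= 0:
            raise ValueError("f_px must be positive")
        if self.standoff_mm <= 0:
            raise ValueError("standoff_mm must be positive")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")


@dataclass
class TunnelFrame:
    length_mm: float = 1800.0
    width_mm: float = 580.0
    height_mm: float = 580.0

    def __post_init__(self):
        if min(self.length_mm, self.width_mm, self.height_mm) <= 0:
            raise ValueError("tunnel dimensions must be positive")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.length_mm, self.width_mm, self.height_mm])


def project(cam: CameraModel, point_mm: Sequence[float]) -> Tuple[float, float]:
    """Project a world point (mm) to pixel coordinates (u, v)."""
    x, y, z = (float(c) for c in point_mm)
    depth = cam.standoff_mm - (z if cam.axis == "top_down" else y)
    if depth <= 0:
        raise GeometryError("point at or behind the camera plane")
    if cam.axis == "top_down":
        return (cam.cu + cam.f_px * x / depth, cam.cv + cam.f_px * y / depth)
    return (cam.cu + cam.f_px * x / depth, cam.cv + cam.f_px * z / depth)


def _ray_rows(cam: CameraModel, uv: Sequence[float]):
    """Two linear constraints on (x, y, z) from one pixel observation."""
    du = uv[0] - cam.cu
    dv = uv[1] - cam.cv
    f, s = cam.f_px, cam.standoff_mm
    if cam.axis == "top_down":
        # f x + du z = du s ;  f y + dv z = dv s
        return [[f, 0.0, du], [0.0, f, dv]], [du * s, dv * s]
    # f x + du y = du s ;  f z + dv y = dv s
    return [[f, du, 0.0], [0.0, dv, f]], [du * s, dv * s]


def fuse_frame(top_uv: Sequence[float], side_uv: Sequence[float],
               top_cam: CameraModel, side_cam: CameraModel,
               mode: str = "least_squares") -> np.ndarray:
    """Fuse one synchronized pixel pair into a world point (x, y, z) in mm.

    ``least_squares`` solves the stacked 4x3 ray system; ``average_abscissa``
    back-substitutes each view independently and averages the two x
    estimates (the literal matching rule for symmetric cameras).
    """
    if not (np.all(np.isfinite(top_uv)) and np.all(np.isfinite(side_uv))):
        raise ValueError("pixel centroids must be finite")
    if top_cam.axis != "top_down" or side_cam.axis != "side_on":
        raise GeometryError("expected a top_down and a side_on camera")
    if mode == "average_abscissa":
        return _fuse_average(top_uv, side_uv, top_cam, side_cam)
    rows_t, rhs_t = _ray_rows(top_cam, top_uv)
    rows_s, rhs_s = _ray_rows(side_cam, side_uv)
    A = np.array(rows_t + rows_s)
    rhs = np.array(rhs_t + rhs_s)
    if np.linalg.matrix_rank(A) < 3:
        raise GeometryError("degenerate camera geometry (rank-deficient rays)")
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return sol


def _fuse_average(top_uv, side_uv, top_cam, side_cam) -> np.ndarray:
    """Fixed-point iteration on the two back-substituted views.

    The top view yields (x, y) given a depth guess z; the side view yields
    (x, z) given y; the shared abscissa is averaged.  Converges in a few
    iterations because each update is a contraction for standoffs larger
    than the tunnel.
    """
    y = z = 0.0
    x = 0.0
    for _ in range(50):
        dt = top_cam.standoff_mm - z
        ds = side_cam.standoff_mm - y
        if dt <= 0 or ds <= 0:
            raise GeometryError("iteration left the valid depth range")
        x_top = (top_uv[0] - top_cam.cu) * dt / top_cam.f_px
        y_new = (top_uv[1] - top_cam.cv) * dt / top_cam.f_px
        x_side = (side_uv[0] - side_cam.cu) * ds / side_cam.f_px
        z_new = (side_uv[1] - side_cam.cv) * ds / side_cam.f_px
        x_new = 0.5 * (x_top + x_side)
        if (abs(y_new - y) < 1e-12 and abs(z_new - z) < 1e-12
                and abs(x_new - x) < 1e-12):
            x, y, z = x_new, y_new, z_new
            break
        x, y, z = x_new, y_new, z_new
    return np.array([x, y, z])


@dataclass
class Trajectory3D:
    """Per-frame fused world points; lost frames carry NaN coordinates."""

    frames: np.ndarray
    points_mm: np.ndarray
    statuses: List[str] = field(default_factory=list)
    fps: float = 60.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if not self.statuses:
            self.statuses = ["tracked"] * len(self.frames)
        if len(self.frames) != len(self.points_mm) or \
                len(self.frames) != len(self.statuses):
            raise ValueError("frames, points and statuses must align")

    def __len__(self):
        return len(self.frames)


def reconstruct_trajectory(top: Sequence[TrajectoryRecord],
                           side: Sequence[TrajectoryRecord],
                           top_cam: CameraModel, side_cam: CameraModel,
                           gap_fill: int = 0, fps: float = 60.0,
                           mode: str = "least_squares") -> Trajectory3D:
    """Fuse two per-view trajectories frame-by-frame into world coordinates.

    Frames lost in either view are flagged ``lost`` (NaN coordinates);
    ``gap_fill > 0`` linearly interpolates lost gaps of at most that many
    frames between valid neighbours (status ``filled``).
    """
    top_by = {r.frame: r for r in top}
    side_by = {r.frame: r for r in side}
    common = sorted(set(top_by) & set(side_by))
    if not common:
        raise ValueError("the two views share no frame indices")
    points = np.full((len(common), 3), np.nan)
    statuses = []
    for i, f in enumerate(common):
        rt, rs = top_by[f], side_by[f]
        if rt.status == "lost" or rs.status == "lost":
            statuses.append("lost")
            continue
        points[i] = fuse_frame((rt.u, rt.v), (rs.u, rs.v), top_cam, side_cam,
                               mode=mode)
        statuses.append("tracked")
    if gap_fill > 0:
        _fill_gaps(np.asarray(common), points, statuses, gap_fill)
    return Trajectory3D(np.asarray(common), points, statuses, fps=fps)


def _fill_gaps(frames: np.ndarray, points: np.ndarray, statuses: List[str],
               k: int) -> None:
    valid = [i for i, s in enumerate(statuses) if s != "lost"]
    for a, b in zip(valid[:-1], valid[1:]):
        gap = b - a - 1
        if 0 < gap <= k:
            for i in range(a + 1, b):
                t = (frames[i] - frames[a]) / (frames[b] - frames[a])
                points[i] = (1 - t) * points[a] + t * points[b]
                statuses[i] = "filled"


def load_cameras(path) -> Dict[str, CameraModel]:
    """Read the camera YAML (per-camera f_px, cu, cv, axis, standoff_mm)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: CameraModel(**params) for name, params in raw.items()}
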