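"""Ground-truthed synthetic wind-tunnel flights rendered through two cameras.

The generator emulates the measurement situation the tracker is built for: a
small, deforming, dark target (a butterfly seen against a light tunnel floor
and wall) flying smoothly inside a 1.8 m x 0.58 m x 0.58 m box with a gentle
head-on airflow, watched at 60 fps by two orthogonal pinhole cameras (top
view and side view).  Static opaque slabs stand in for occluding plants, and
an optional "similar-colour" zone repaints part of the background with the
target's own intensity to reproduce the low-contrast failure mode.

Everything is driven by one integer seed: the flight's random walk and the
per-frame pixel noise consume independent, documented substreams, so a scene
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import GeometryError
from .features import BoundingBox
from .io_formats import FrameSequence, TrajectoryRecord
from .stereo3d import CameraModel, Trajectory3D, TunnelFrame, project


@dataclass
class Slab:
    """Axis-aligned opaque box (mm) standing in for an occluding plant."""

    x0: float
    x1: float
    y0: float
    y1: float
    z0: float
    z1: float
    intensity: float = 90.0


@dataclass
class TargetParams:
    """Rendered insect: an anti-aliased ellipse that beats its 'wings'.

    ``radius_mm`` is the nominal half-extent (a butterfly's wing half-span is
    roughly 25 mm); the apparent pixel size follows the camera's inverse
    depth.  The two ellipse semi-axes oscillate in antiphase with the wingbeat
    to emulate the shape change of flapping flight.
    """

    radius_mm: float = 25.0
    intensity: float = 60.0
    wingbeat_amp: float = 0.2
    wingbeat_period: float = 8.0


@dataclass
class FlightParams:
    """Second-order random walk with wind drift, reflected at the walls.

    Units are mm per frame at 60 fps.  The default drift of 6.67 mm/frame
    along -x corresponds to the 0.4 m/s tunnel airflow; ``speed_scale`` sets
    the initial air speed and ``accel_sigma`` the per-frame Gaussian
    acceleration of the walk (damped so speeds stay insect-like).
    """

    speed_scale: float = 8.0
    drift: Tuple[float, float, float] = (-400.0 / 60.0, 0.0, 0.0)
    accel_sigma: float = 1.2
    damping: float = 0.97
    margin_mm: float = 100.0
    bounds: TunnelFrame = field(default_factory=TunnelFrame)


@dataclass
class SceneConfig:
    tunnel: TunnelFrame = field(default_factory=TunnelFrame)
    top_cam: CameraModel = None
    side_cam: CameraModel = None
    image_shape: Tuple[int, int] = (360, 480)  # rows, cols
    fps: float = 60.0
    n_frames: int = 200
    target: TargetParams = field(default_factory=TargetParams)
    occluders: List[Slab] = field(default_factory=list)
    similar_zone: Optional[Tuple[float, float]] = None  # x-range, mm
    similar_zone_z: float = 0.0  # flight height the zone is calibrated to, mm
    noise_sigma: float = 2.0
    bg_intensity: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.top_cam is None or self.side_cam is None:
            top, side = default_cameras(self.image_shape)
            self.top_cam = self.top_cam or top
            self.side_cam = self.side_cam or side


def default_cameras(image_shape: Tuple[int, int] = (360, 480)
                    ) -> Tuple[CameraModel, CameraModel]:
    """Orthogonal camera pair whose frusta cover the whole tunnel.

    The focal length scales the physical sensor optics (3.5 mm lens on a
    7.2 mm-wide sensor) to the rendered image width; the 1.5 m standoff keeps
    the full 1.8 m tunnel length inside the field of view.  Each optical axis
    passes through the world origin (the tunnel's top-left corner), so the
    principal point sits near the image corner and the tunnel occupies
    increasing (u, v).
    """
    h, w = image_shape
    f_px = 3.5 / 7.2 * w
    cu, cv = 8.0, h / 6.0
    top = CameraModel(f_px=f_px, cu=cu, cv=cv, axis="top_down",
                      standoff_mm=1500.0)
    side = CameraModel(f_px=f_px, cu=cu, cv=cv, axis="side_on",
                       standoff_mm=1500.0)
    return top, side


def simulate_flight(params: FlightParams, n_frames: int, seed: int = 0,
                    start: Optional[Tuple[float, float, float]] = None,
                    velocity: Optional[Tuple[float, float, float]] = None
                    ) -> Trajectory3D:
    """Simulate a smooth in-tunnel flight path (mm per frame steps).

    position += velocity + drift; velocity is a damped Gaussian random walk.
    The path reflects off the tunnel walls (inset by ``margin_mm``).  The
    random stream is ``default_rng([seed, 0])`` and is consumed only here.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng([int(seed), 0])
    lo = np.full(3, params.margin_mm)
    hi = params.bounds.bounds - params.margin_mm
    if np.any(hi <= lo):
        raise ValueError("margin leaves no interior volume")
    if start is None:
        pos = np.array([hi[0] - 50.0, *((lo[1:] + hi[1:]) / 2.0)])
    else:
        pos = np.asarray(start, dtype=float).copy()
    if velocity is None:
        # Released insects head upwind (toward the odour source), so the
        # initial heading follows the drift direction with a random
        # transverse component; isotropic if there is no wind.
        jitter = rng.normal(size=3)
        drift_norm = np.linalg.norm(params.drift)
        if drift_norm > 0:
            direction = np.asarray(params.drift) / drift_norm + 0.3 * jitter
        else:
            direction = jitter
        vel = params.speed_scale * direction / np.linalg.norm(direction)
    else:
        vel = np.asarray(velocity, dtype=float).copy()
    drift = np.asarray(params.drift, dtype=float)

    points = np.empty((n_frames, 3))
    points[0] = pos
    for t in range(1, n_frames):
        vel = params.damping * vel + rng.normal(scale=params.accel_sigma,
                                                size=3)
        pos = pos + vel + drift
        for ax in range(3):  # reflective walls
            if pos[ax] < lo[ax]:
                pos[ax] = 2 * lo[ax] - pos[ax]
                vel[ax] = -vel[ax]
            elif pos[ax] > hi[ax]:
                pos[ax] = 2 * hi[ax] - pos[ax]
                vel[ax] = -vel[ax]
        points[t] = pos
    return Trajectory3D(np.arange(n_frames), points)


def _draw_ellipse(img: np.ndarray, cu: float, cv: float, au: float,
                  av: float, intensity: float) -> None:
    """Alpha-blend an axis-aligned anti-aliased ellipse into ``img``."""
    h, w = img.shape
    r0 = max(int(np.floor(cv - av - 2)), 0)
    r1 = min(int(np.ceil(cv + av + 2)) + 1, h)
    c0 = max(int(np.floor(cu - au - 2)), 0)
    c1 = min(int(np.ceil(cu + au + 2)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    d = np.sqrt(((cols - cu) / au) ** 2 + ((rows - cv) / av) ** 2)
    edge = 1.0 / min(au, av)  # ~1 px of soft edge in normalised units
    cov = np.clip((1.0 - d) / edge * 0.5 + 0.5, 0.0, 1.0)
    img[r0:r1, c0:c1] = img[r0:r1, c0:c1] * (1 - cov) + intensity * cov


def _slab_rect(cam: CameraModel, slab: Slab) -> Tuple[float, float, float,
                                                      float]:
    """Image-space rectangle of the slab face nearest the camera."""
    if cam.axis == "top_down":
        zc = slab.z1  # nearest face to an overhead camera
        corners = [(slab.x0, slab.y0, zc), (slab.x1, slab.y1, zc)]
    else:
        yc = slab.y1
        corners = [(slab.x0, yc, slab.z0), (slab.x1, yc, slab.z1)]
    (u0, v0), (u1, v1) = (project(cam, c) for c in corners)
    return (min(u0, u1), max(u0, u1), min(v0, v1), max(v0, v1))


def _fill_rect(img: np.ndarray, rect, intensity: float) -> None:
    u0, u1, v0, v1 = rect
    h, w = img.shape
    r0, r1 = int(np.floor(v0)), int(np.ceil(v1)) + 1
    c0, c1 = int(np.floor(u0)), int(np.ceil(u1)) + 1
    img[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] = intensity


def _occludes(cam: CameraModel, slab: Slab, p: np.ndarray) -> bool:
    """Does the slab sit between the camera and the point (centre test)?"""
    x, y, z = p
    if cam.axis == "top_down":
        return (slab.z0 > z and slab.x0 <= x <= slab.x1
                and slab.y0 <= y <= slab.y1)
    return (slab.y0 > y and slab.x0 <= x <= slab.x1
            and slab.z0 <= z <= slab.z1)


def _in_zone(scene: SceneConfig, x: float) -> bool:
    return (scene.similar_zone is not None
            and scene.similar_zone[0] <= x <= scene.similar_zone[1])


def render_views(traj: Trajectory3D, scene: SceneConfig):
    """Render a flight through both cameras.

    Returns ``(top_seq, side_seq, truth)`` where ``truth`` holds the exact
    projected centroids per view (``top``/``side`` lists of records) and the
    per-frame boolean visibility arrays ``visible_top``/``visible_side``
    (False while the target centre is behind an occluder, or — top view —
    inside the similar-colour zone).

    Occluders have binary opacity and are rendered as static scenery; a
    frame whose target centre fails the world-space occlusion test simply
    omits the target, which keeps the rendered visibility exactly consistent
    with the returned flags.  The similar-colour zone is a background band
    repainted with the target's own intensity, sized in image space for the
    flight height it is calibrated to (``similar_zone_z``), so a target
    crossing it blends in seamlessly.  Noise consumes
    ``default_rng([seed, 1])`` for the top view and ``default_rng([seed, 2])``
    for the side view, one frame at a time.
    """
    h, w = scene.image_shape
    n = len(traj)
    bounds = scene.tunnel.bounds
    if np.any(traj.points_mm < -1e-9) or np.any(traj.points_mm > bounds + 1e-9):
        raise GeometryError("trajectory leaves the tunnel volume")

    cams = {"top": scene.top_cam, "side": scene.side_cam}
    bgs = {}
    for view, cam in cams.items():
        bg = np.full((h, w), scene.bg_intensity)
        for s in scene.occluders:
            _fill_rect(bg, _slab_rect(cam, s), s.intensity)
        if view == "top" and scene.similar_zone is not None:
            x0, x1 = scene.similar_zone
            zr = scene.similar_zone_z
            u0, _ = project(cam, (x0, 0, zr))
            u1, _ = project(cam, (x1, 0, zr))
            _fill_rect(bg, (min(u0, u1), max(u0, u1), -1, h + 1),
                       scene.target.intensity)
        bgs[view] = bg

    rngs = {
        "top": np.random.default_rng([int(scene.seed), 1]),
        "side": np.random.default_rng([int(scene.seed), 2]),
    }
    frames = {"top": [], "side": []}
    truth = {"top": [], "side": [],
             "visible_top": np.ones(n, dtype=bool),
             "visible_side": np.ones(n, dtype=bool)}

    for t in range(n):
        p = traj.points_mm[t]
        phase = np.sin(2 * np.pi * t / scene.target.wingbeat_period)
        for view in ("top", "side"):
            cam = cams[view]
            img = bgs[view].copy()
            depth = cam.standoff_mm - (p[2] if cam.axis == "top_down"
                                       else p[1])
            if depth <= 0:
                raise GeometryError("target behind a camera")
            u, v = project(cam, p)
            truth[view].append(TrajectoryRecord(int(traj.frames[t]),
                                                float(u), float(v)))
            occluded = any(_occludes(cam, s, p) for s in scene.occluders)
            if occluded:
                truth[f"visible_{view}"][t] = False
            else:
                r_px = cam.f_px * scene.target.radius_mm / depth
                au = r_px * (1.0 + scene.target.wingbeat_amp * phase)
                av = r_px * (1.0 - scene.target.wingbeat_amp * phase)
                _draw_ellipse(img, u, v, au, av, scene.target.intensity)
            if view == "top" and _in_zone(scene, p[0]):
                truth["visible_top"][t] = False

            if scene.noise_sigma > 0:
                img = img + rngs[view].normal(scale=scene.noise_sigma,
                                              size=img.shape)
            frames[view].append(np.clip(np.round(img), 0, 255)
                                .astype(np.uint8))

    top_seq = FrameSequence(frames["top"], fps=scene.fps)
    side_seq = FrameSequence(frames["side"], fps=scene.fps)
    return top_seq, side_seq, truth


def initial_box(truth_view: List[TrajectoryRecord],
                size_px: float = 24.0) -> BoundingBox:
    """Manual-selection stand-in: a square box centred on the frame-0 truth."""
    r0 = truth_view[0]
    return BoundingBox.from_center(r0.u, r0.v, size_px, size_px)


# ---------------------------------------------------------------------------
# The four benchmark situations: open tunnel centre, occlusion by a plant,
# flight along the tunnel edge, and target-coloured background.
# ---------------------------------------------------------------------------

def open_centre_scene(n_frames: int = 200, seed: int = 0
                      ) -> Tuple[Trajectory3D, SceneConfig]:
    """Unobstructed flight drifting down the tunnel centre line."""
    scene = SceneConfig(n_frames=n_frames, seed=seed)
    traj = simulate_flight(FlightParams(), n_frames, seed=seed)
    return traj, scene


def _ballistic(n_frames: int, speed: float = 8.0,
               start=(1450.0, 290.0, 250.0)) -> Trajectory3D:
    """Deterministic straight flight against the airflow direction."""
    params = FlightParams(accel_sigma=0.0, damping=1.0, drift=(0.0, 0.0, 0.0))
    return simulate_flight(params, n_frames, seed=0, start=start,
                           velocity=(-speed, 0.0, 0.0))


def occlusion_scene(n_frames: int = 110, seed: int = 0
                    ) -> Tuple[Trajectory3D, SceneConfig]:
    """Straight flight passing behind a plant slab (top view occluded).

    The slab hangs above the flight line (between target and top camera) and
    is wider than the correlation filter's search window, so a plain
    correlation filter cannot bridge the gap; its y-extent straddles the
    flight line but its z-extent does not, so the side view stays clear.
    """
    traj = _ballistic(n_frames)
    slab = Slab(x0=870, x1=1190, y0=240, y1=340, z0=330, z1=420,
                intensity=90.0)
    scene = SceneConfig(n_frames=n_frames, seed=seed, occluders=[slab])
    return traj, scene


def edge_scene(n_frames: int = 110, seed: int = 0
               ) -> Tuple[Trajectory3D, SceneConfig]:
    """Straight flight hugging a tunnel wall."""
    traj = _ballistic(n_frames, start=(1450.0, 120.0, 120.0))
    scene = SceneConfig(n_frames=n_frames, seed=seed)
    return traj, scene


def similar_colour_scene(n_frames: int = 110, seed: int = 0
                         ) -> Tuple[Trajectory3D, SceneConfig]:
    """Straight flight crossing a floor zone painted the target's colour."""
    traj = _ballistic(n_frames)
    scene = SceneConfig(n_frames=n_frames, seed=seed,
                        similar_zone=(870.0, 1190.0), similar_zone_z=250.0)
    return traj, scene
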