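"""The KCF-BS tracking loop.

Each frame is processed by the correlation filter; a stuck detection (the
centroid moving less than ``loss_threshold`` pixels between consecutive
frames, the "S < T" rule) is treated as a lost target and handed to
background subtraction, which searches the full frame for the moving target
and, on success, re-centres and re-trains the filter there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import background_subtraction as bs
from . import kcf_core
from .errors import TrackingError
from .features import BoundingBox, FeatureConfig, extract_features, extract_patch
from .io_formats import FrameSequence, TrajectoryRecord
from .kcf_core import KernelSpec

log = logging.getLogger(__name__)

EVENT_TYPES = ("init", "tracked", "loss_detected", "redetected", "bs_failed")


@dataclass
class BSConfig:
    method: str = "median_n"
    n_frames: int = 20
    thresh: float = 25.0
    min_area: int = 20


@dataclass
class TrackerConfig:
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    lam: float = 1e-4
    eta: float = 0.02
    loss_threshold: float = 3.0       # the displacement threshold T, pixels
    response_sigma_factor: float = 0.1
    bs: BSConfig = field(default_factory=BSConfig)
    bs_enabled: bool = True

    def __post_init__(self):
        if self.loss_threshold < 0:
            raise ValueError("loss_threshold must be >= 0")


@dataclass
class TrackEvent:
    frame: int
    type: str

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


def tracker_config_from_dict(cfg: dict) -> TrackerConfig:
    """Build a TrackerConfig from the YAML schema (features/kcf/tracker/bs)."""
    feat = FeatureConfig(**cfg.get("features", {}))
    kcf = dict(cfg.get("kcf", {}))
    kernel = KernelSpec(**kcf.pop("kernel", {}))
    lam = float(kcf.pop("lambda", kcf.pop("lam", 1e-4)))
    eta = float(kcf.pop("eta", 0.02))
    sigma_factor = float(kcf.pop("response_sigma_factor", 0.1))
    if kcf:
        raise ValueError(f"unknown kcf options: {sorted(kcf)}")
    trk = cfg.get("tracker", {})
    return TrackerConfig(
        feature=feat,
        kernel=kernel,
        lam=lam,
        eta=eta,
        response_sigma_factor=sigma_factor,
        loss_threshold=float(trk.get("loss_threshold", 3.0)),
        bs=BSConfig(**cfg.get("bs", {})),
        bs_enabled=bool(trk.get("bs_enabled", True)),
    )


def is_lost(prev: Tuple[float, float], cur: Tuple[float, float],
            T: float) -> bool:
    """The S < T rule: lost iff the centroid moved strictly less than T px.

    A healthy flying target displaces between frames; a stuck tracking box
    barely moves, which is the observable signature of a lost target.
    ``T = 0`` disables the rule (the inequality is strict).
    """
    if not (np.isfinite(prev).all() and np.isfinite(cur).all()):
        raise ValueError("centroids must be finite")
    s = float(np.hypot(cur[0] - prev[0], cur[1] - prev[1]))
    return s < T


def _train_at(frame: np.ndarray, center: Tuple[float, float],
              box_size: Tuple[float, float], cfg: TrackerConfig,
              target_b: Optional[np.ndarray] = None):
    box = BoundingBox.from_center(center[0], center[1], *box_size)
    patch = extract_patch(frame, box, cfg.feature.padding)
    feat = extract_features(patch, cfg.feature)
    if target_b is None:
        h, w = feat.spatial_shape
        target_b = kcf_core.gaussian_response_target(
            h, w, cfg.response_sigma_factor, cfg.feature.padding
        )
    model = kcf_core.train(feat, target_b, cfg.lam, cfg.kernel)
    return model, target_b


def track_sequence(frames: FrameSequence, init_box: BoundingBox,
                   cfg: Optional[TrackerConfig] = None
                   ) -> Tuple[List[TrajectoryRecord], List[TrackEvent]]:
    """Track a single target through a frame sequence.

    Frame 0 is initialised from ``init_box`` (status ``init``).  On every
    later frame the correlation filter proposes a displaced centroid; if the
    S < T rule flags a loss, background subtraction searches the full frame
    and either re-seeds the filter (``redetected``) or, failing that, the
    previous position is held (``lost``) and re-detection is retried on the
    next frame.
    """
    if cfg is None:
        cfg = TrackerConfig()
    H, W = frames.frame_shape
    frame0 = np.asarray(frames[0])
    if not (0 <= init_box.u < W and 0 <= init_box.v < H
            and init_box.u + init_box.w <= W and init_box.v + init_box.h <= H):
        raise TrackingError("initial box must lie inside frame 0")

    box_size = (init_box.w, init_box.h)
    center = init_box.center
    model, target_b = _train_at(frame0, center, box_size, cfg)

    background = None
    if cfg.bs_enabled:
        background = bs.build_background(frames, cfg.bs.method,
                                         cfg.bs.n_frames)

    origin = frames.frame_index_origin
    records = [TrajectoryRecord(origin, center[0], center[1], "init")]
    events = [TrackEvent(origin, "init")]

    for t in range(1, len(frames)):
        frame = np.asarray(frames[t])
        if frame.shape != (H, W):
            raise TrackingError(f"frame {t} changed size mid-stream")
        idx = origin + t

        box = BoundingBox.from_center(center[0], center[1], *box_size)
        patch = extract_patch(frame, box, cfg.feature.padding)
        feat = extract_features(patch, cfg.feature)
        # Cap the admissible displacement at (window - target)/2: beyond
        # that the target would have left the search window.
        max_shift = 0.5 * (cfg.feature.padding - 1.0) * min(box_size)
        det = kcf_core.detect(model, feat, max_shift=max_shift)
        cand = (
            float(np.clip(center[0] + det.peak_offset[0], 0, W - 1)),
            float(np.clip(center[1] + det.peak_offset[1], 0, H - 1)),
        )

        if cfg.bs_enabled and is_lost(center, cand, cfg.loss_threshold):
            events.append(TrackEvent(idx, "loss_detected"))
            mask = bs.subtract_and_mask(frame, background, cfg.bs.thresh)
            found = bs.largest_component_centroid(mask, cfg.bs.min_area)
            if found is not None:
                center = found
                model, target_b = _train_at(frame, center, box_size, cfg,
                                            target_b)
                records.append(
                    TrajectoryRecord(idx, center[0], center[1], "redetected")
                )
                events.append(TrackEvent(idx, "redetected"))
                log.info("frame %d: redetected at (%.1f, %.1f)", idx, *center)
            else:
                events.append(TrackEvent(idx, "bs_failed"))
                records.append(
                    TrajectoryRecord(idx, center[0], center[1], "lost")
                )
                log.info("frame %d: lost (BS found nothing)", idx)
            continue

        center = cand
        fresh, _ = _train_at(frame, center, box_size, cfg, target_b)
        model = kcf_core.update_model(model, fresh, cfg.eta)
        records.append(TrajectoryRecord(idx, center[0], center[1], "tracked"))
        events.append(TrackEvent(idx, "tracked"))

    return records, events
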