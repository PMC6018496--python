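"""Windowed feature extraction for the correlation-filter tracker.

The tracker learns from a padded search window around the target box.  Two
representations are supported: raw grayscale intensities at pixel resolution
(the configuration found most accurate for a small deforming insect) and
per-cell histograms of oriented gradients (HOG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrackingError


@dataclass
class BoundingBox:
    """Axis-aligned pixel box; ``(u, v)`` is the top-left corner (col, row)."""

    u: float
    v: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")

    @property
    def center(self) -> tuple:
        return (self.u + self.w / 2.0, self.v + self.h / 2.0)

    @classmethod
    def from_center(cls, cu: float, cv: float, w: float, h: float):
        return cls(cu - w / 2.0, cv - h / 2.0, w, h)


@dataclass
class FeatureConfig:
    kind: str = "gray"          # {"gray", "hog"}
    padding: float = 2.0        # search window as a multiple of the box size
    hog_cell: int = 4           # pixels per HOG cell
    hog_bins: int = 9           # unsigned orientation bins over 180 degrees
    window: str = "hann"        # {"hann", "none"}

    def __post_init__(self):
        if self.kind not in ("gray", "hog"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.padding < 1:
            raise ValueError("padding must be >= 1")
        if self.hog_cell < 1 or self.hog_bins < 2:
            raise ValueError("hog_cell >= 1 and hog_bins >= 2 required")
        if self.window not in ("hann", "none"):
            raise ValueError(f"unknown window {self.window!r}")


@dataclass
class FeatureMap:
    """Feature array of shape (H, W, C) with a spatial cell size in pixels."""

    values: np.ndarray
    cell_size: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def spatial_shape(self) -> tuple:
        return self.values.shape[:2]


def hann2d(h: int, w: int) -> np.ndarray:
    """Separable 2-D Hann taper; endpoints are exactly zero for n >= 2."""
    return np.outer(np.hanning(h), np.hanning(w))


def extract_patch(frame: np.ndarray, box: BoundingBox,
                  padding: float = 2.0) -> np.ndarray:
    """Cut the padded search window centred on the box centre.

    Out-of-frame pixels are filled by edge replication so the window is always
    exactly ``round(padding * box size)`` pixels.
    """
    frame = np.asarray(frame)
    H, W = frame.shape
    if (box.u + box.w <= 0 or box.u >= W or box.v + box.h <= 0 or box.v >= H):
        raise TrackingError("bounding box lies entirely outside the frame")
    out_h = int(round(padding * box.h))
    out_w = int(round(padding * box.w))
    cu, cv = box.center
    top = int(round(cv - out_h / 2.0))
    left = int(round(cu - out_w / 2.0))
    rows = np.clip(np.arange(top, top + out_h), 0, H - 1)
    cols = np.clip(np.arange(left, left + out_w), 0, W - 1)
    return frame[np.ix_(rows, cols)]


def _to_unit(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch, dtype=float)
    if patch.size and patch.max() > 1.5:  # 8-bit input
        patch = patch / 255.0
    return patch


def gray_features(patch: np.ndarray, window: str = "hann") -> FeatureMap:
    """Zero-mean unit-scaled intensities, optionally Hann tapered.

    Mean subtraction removes the DC response that would otherwise dominate the
    cyclic-shift regression; the Hann taper suppresses the artificial edges
    that cyclic shifts introduce at the window boundary.
    """
    p = _to_unit(patch)
    if p.ndim != 2:
        raise ValueError("gray features expect a 2-D patch")
    p = p - p.mean()
    if window == "hann":
        p = p * hann2d(*p.shape)
    return FeatureMap(p, cell_size=1)


def _cell_histograms(patch: np.ndarray, cell: int, bins: int) -> np.ndarray:
    """Hard-assigned per-cell gradient-orientation histograms (the HOG core).

    Gradients use central differences (one-sided at the borders); orientations
    are unsigned, i.e. folded onto [0, 180) degrees.
    """
    p = _to_unit(patch)
    gy, gx = np.gradient(p)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned orientation
    b = np.floor(ang / (np.pi / bins)).astype(int) % bins
    n_r, n_c = p.shape[0] // cell, p.shape[1] // cell
    hist = np.zeros((n_r, n_c, bins))
    rr = np.arange(n_r * cell)[:, None] // cell
    cc = np.arange(n_c * cell)[None, :] // cell
    crop = np.s_[: n_r * cell, : n_c * cell]
    np.add.at(
        hist,
        (np.broadcast_to(rr, (n_r * cell, n_c * cell)).ravel(),
         np.broadcast_to(cc, (n_r * cell, n_c * cell)).ravel(),
         b[crop].ravel()),
        mag[crop].ravel(),
    )
    return hist


def _block_normalise(hist: np.ndarray, clip: float = 0.2,
                     eps: float = 1e-6) -> np.ndarray:
    """L2-Hys normalisation over 2x2 cell blocks, averaged back onto cells."""
    n_r, n_c, _ = hist.shape
    if n_r < 2 or n_c < 2:
        norm = np.sqrt((hist ** 2).sum()) + eps
        v = np.minimum(hist / norm, clip)
        return v / (np.sqrt((v ** 2).sum()) + eps)
    sq = (hist ** 2).sum(-1)
    energy = sq[:-1, :-1] + sq[:-1, 1:] + sq[1:, :-1] + sq[1:, 1:]
    norm = np.sqrt(energy) + eps  # one norm per 2x2 block
    out = np.zeros_like(hist)
    count = np.zeros((n_r, n_c, 1))
    for br in (0, 1):
        for bc in (0, 1):
            cells = hist[br: br + n_r - 1, bc: bc + n_c - 1]
            v = np.minimum(cells / norm[..., None], clip)
            renorm = np.sqrt((v ** 2).sum(-1, keepdims=True)) + eps
            out[br: br + n_r - 1, bc: bc + n_c - 1] += v / renorm
            count[br: br + n_r - 1, bc: bc + n_c - 1] += 1.0
    return out / np.maximum(count, 1.0)


def hog_features(patch: np.ndarray, cfg: FeatureConfig) -> FeatureMap:
    """Per-cell oriented-gradient histograms with L2-Hys block normalisation."""
    patch = np.asarray(patch)
    if patch.shape[0] < cfg.hog_cell or patch.shape[1] < cfg.hog_cell:
        raise ValueError("patch smaller than one HOG cell")
    hist = _cell_histograms(patch, cfg.hog_cell, cfg.hog_bins)
    feat = _block_normalise(hist)
    if cfg.window == "hann":
        feat = feat * hann2d(*feat.shape[:2])[:, :, None]
    return FeatureMap(feat, cell_size=cfg.hog_cell)


def extract_features(patch: np.ndarray, cfg: FeatureConfig) -> FeatureMap:
    if cfg.kind == "gray":
        return gray_features(patch, window=cfg.window)
    return hog_features(patch, cfg)
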