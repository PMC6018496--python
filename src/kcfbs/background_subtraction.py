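"""Motion detection by frame differencing against a static background.

Used by the tracking loop to re-acquire the target after the correlation
filter loses it: the current frame is differenced against a background
estimate, the difference is thresholded and cleaned by morphological opening,
and the centroid of the largest connected component is the re-detection
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import FormatError
from .io_formats import FrameSequence

# 8-connectivity for component labelling and the 3x3 opening structure
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class BackgroundModel:
    image: np.ndarray
    method: str = "median_n"  # {"first_frame", "median_n"}
    n_frames: int = 1

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("background image must be 2-D")


def build_background(frames: FrameSequence, method: str = "median_n",
                     n: int = 20) -> BackgroundModel:
    """Estimate the static background from the start of the stream.

    ``median_n`` takes the per-pixel median over the first ``n`` frames, which
    removes a moving target provided it covers each pixel in fewer than half
    of those frames; ``first_frame`` simply uses frame 0.
    """
    if len(frames) == 0:
        raise FormatError("cannot build a background from an empty sequence")
    if n < 1:
        raise ValueError("n must be >= 1")
    n = min(n, len(frames))
    if method == "first_frame":
        return BackgroundModel(np.asarray(frames[0], dtype=float),
                               method=method, n_frames=1)
    if method == "median_n":
        stack = np.stack([np.asarray(frames[i], dtype=float)
                          for i in range(n)])
        return BackgroundModel(np.median(stack, axis=0), method=method,
                               n_frames=n)
    raise ValueError(f"unknown background method {method!r}")


def subtract_and_mask(frame: np.ndarray, bg: BackgroundModel,
                      thresh: float = 25.0) -> np.ndarray:
    """Threshold |frame - background| and clean with one 3x3 opening pass.

    The opening removes isolated single-pixel responses (sensor noise) while
    leaving any component that contains a 3x3 neighbourhood intact.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != bg.image.shape:
        raise ValueError("frame and background dims must match")
    mask = np.abs(frame - bg.image) > thresh
    return ndimage.binary_opening(mask, structure=_STRUCT8)


def largest_component_centroid(mask: np.ndarray, min_area: int = 20
                               ) -> Optional[Tuple[float, float]]:
    """Area-weighted centroid (u, v) of the largest 8-connected component.

    Components smaller than ``min_area`` pixels are discarded; returns None
    when nothing survives.  Ties in area resolve to the lowest label (scan
    order), which keeps the result deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]  # drop background count
    areas = np.where(areas >= min_area, areas, 0)
    if areas.max() == 0:
        return None
    best = int(np.argmax(areas)) + 1  # argmax -> first maximal label
    rows, cols = np.nonzero(labels == best)
    return (float(cols.mean()), float(rows.mean()))
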