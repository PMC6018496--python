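"""Tracking-accuracy metrics: error distances, success rates, distance checks.

The accuracy of the full pipeline was historically validated with suspended
ping-pong balls of known pairwise separation; the packaged ball-distance
table ships with the package and its summary statistics (mean/std/min/max of
the absolute distance error) are recomputed rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import TrajectoryRecord
from .stereo3d import Trajectory3D


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ErrorSummary:
    per_frame: np.ndarray
    max: float
    min: float
    mean: float

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "ErrorSummary":
        d = np.asarray(d, dtype=float)
        if d.size == 0:
            raise ValueError("no distances to summarise")
        return cls(per_frame=d, max=float(d.max()), min=float(d.min()),
                   mean=float(d.mean()))


def _match(traj: Sequence[TrajectoryRecord],
           truth: Sequence[TrajectoryRecord]):
    tr = {r.frame: r for r in traj}
    th = {r.frame: r for r in truth}
    common = sorted(set(tr) & set(th))
    if not common:
        raise ValueError("trajectory and truth share no frame indices")
    return [(tr[f], th[f]) for f in common]


def error_distances(traj: Sequence[TrajectoryRecord],
                    truth: Sequence[TrajectoryRecord]) -> ErrorSummary:
    """Per-frame Euclidean pixel distance between tracked and true centroids."""
    pairs = _match(traj, truth)
    d = np.array([np.hypot(a.u - b.u, a.v - b.v) for a, b in pairs])
    return ErrorSummary.from_distances(d)


def success_rate(traj: Sequence[TrajectoryRecord],
                 truth: Sequence[TrajectoryRecord],
                 tol_px: float = 20.0) -> float:
    """Percentage of frames tracked within ``tol_px`` of truth (1 decimal).

    A frame counts as a success when its status is not ``lost`` and its
    centroid error does not exceed the tolerance; the denominator is every
    matched frame, so lost frames count against the tracker.
    """
    pairs = _match(traj, truth)
    ok = sum(
        1
        for a, b in pairs
        if a.status != "lost" and np.hypot(a.u - b.u, a.v - b.v) <= tol_px
    )
    return round_half_away(100.0 * ok / len(pairs), 1)


def error_distances_3d(traj: Trajectory3D, truth: Trajectory3D
                       ) -> ErrorSummary:
    """Euclidean 3-D error (mm) over frames valid in both trajectories."""
    tr = {int(f): p for f, p, s in
          zip(traj.frames, traj.points_mm, traj.statuses) if s != "lost"}
    th = {int(f): p for f, p, s in
          zip(truth.frames, truth.points_mm, truth.statuses) if s != "lost"}
    common = sorted(set(tr) & set(th))
    if not common:
        raise ValueError("no valid common frames")
    d = np.array([np.linalg.norm(tr[f] - th[f]) for f in common])
    return ErrorSummary.from_distances(d)


@dataclass
class PairwiseDistanceTable:
    """Calculated vs tape-measured pairwise distances between markers (mm)."""

    pair_ids: List[str]
    calculated_mm: np.ndarray
    actual_mm: np.ndarray
    printed_relative_error_pct: np.ndarray = None

    def __post_init__(self):
        self.calculated_mm = np.asarray(self.calculated_mm, dtype=float)
        self.actual_mm = np.asarray(self.actual_mm, dtype=float)
        if len(self.pair_ids) != len(self.calculated_mm) or \
                len(self.pair_ids) != len(self.actual_mm):
            raise ValueError("table columns must align")
        if self.printed_relative_error_pct is not None:
            self.printed_relative_error_pct = np.asarray(
                self.printed_relative_error_pct, dtype=float
            )

    def __len__(self):
        return len(self.pair_ids)

    @property
    def error_mm(self) -> np.ndarray:
        return np.abs(self.calculated_mm - self.actual_mm)

    @property
    def relative_error_pct(self) -> np.ndarray:
        return 100.0 * self.error_mm / self.actual_mm

    def inconsistent_rows(self, ndigits: int = 2) -> List[str]:
        """Pairs whose printed relative error disagrees with error/actual.

        Such rows are flagged rather than silently reconciled; they are most
        plausibly transcription artifacts in the printed table.
        """
        if self.printed_relative_error_pct is None:
            return []
        out = []
        for pid, rel, printed in zip(self.pair_ids, self.relative_error_pct,
                                     self.printed_relative_error_pct):
            if abs(round_half_away(rel, ndigits) - printed) > 10.0 ** -ndigits / 2:
                out.append(pid)
        return out


def pairwise_distance_stats(table: PairwiseDistanceTable
                            ) -> Tuple[float, float, float, float]:
    """(mean, population std, min, max) of the absolute distance errors, mm."""
    if len(table) == 0:
        raise ValueError("empty distance table")
    e = table.error_mm
    return (float(e.mean()), float(e.std(ddof=0)), float(e.min()),
            float(e.max()))


def load_ball_distance_table() -> PairwiseDistanceTable:
    """The packaged ball-distance validation table (five suspended markers)."""
    with resources.files("kcfbs.data").joinpath("table4_balls.csv").open() as fh:
        df = pd.read_csv(fh)
    return PairwiseDistanceTable(
        pair_ids=[str(p) for p in df["pair"]],
        calculated_mm=df["calculated_mm"].to_numpy(),
        actual_mm=df["actual_mm"].to_numpy(),
        printed_relative_error_pct=df["printed_relative_error_pct"].to_numpy(),
    )
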