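"""Center-of-pressure trajectory extraction and the 10-value COP feature vector.

The pipeline: per-frame pressure-weighted centroid (the COP), the frame-by-frame
COP line in foot-local coordinates, linear mapping of the foot's bounding box
onto a 30 x 20 standard-foot coordinate frame (so different foot sizes are
comparable), selection of 5 equally spaced key points (10 coordinates), and
per-column max-normalization into [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFeatureError,
    DegenerateFootError,
    EmptyFrameError,
    EmptyTrajectoryError,
    InsufficientDataError,
    UsageError,
)
from .pressure_io import FEATURE_COLUMNS, FeatureTable, PressureFrame, StanceRecording

logger = logging.getLogger(__name__)

MAPPED_EXTENT_X = 30.0  # long (heel->toe) axis of the standard foot frame
MAPPED_EXTENT_Y = 20.0  # medio-lateral axis
N_KEY_POINTS = 5


@dataclass
class COPTrajectory:
    """Per-frame pressure centers in foot-local (bbox-origin) coordinates."""

    points: np.ndarray  # (T, 2) columns (Xc, Yc), sensor units
    bbox_origin: tuple[float, float]
    L_X: float
    L_Y: float

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MappedTrajectory:
    """COP points after mapping onto the 30 x 20 standard frame."""

    points: np.ndarray  # (T, 2) columns (Xc', Yc')

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FeatureVector:
    """The flattened key points (C1x, C1y, ..., C5x, C5y)."""

    values: np.ndarray  # (10,)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 2 * N_KEY_POINTS:
            raise UsageError(f"feature vector must have 10 values, got {self.values.size}")


def pressure_center(frame: PressureFrame | np.ndarray) -> tuple[float, float]:
    """Pressure-weighted centroid (Xc, Yc) of one frame, in grid coordinates.

    Xc = sum(P_i x_i) / sum(P_i) with x_i the column index of the cell center
    and y_i its row index.  Raises for an all-zero frame (callers skip those).
    """
    grid = frame.grid if isinstance(frame, PressureFrame) else np.asarray(frame, dtype=float)
    total = grid.sum()
    if total <= 0:
        raise EmptyFrameError("frame has no positive pressure")
    ys, xs = np.nonzero(grid)
    w = grid[ys, xs]
    return float((w * xs).sum() / total), float((w * ys).sum() / total)


def extract_cop(recording: StanceRecording) -> COPTrajectory:
    """The COP line: per-frame centers, chronological, zero-pressure frames skipped.

    The foot's bounding box is the union of cells active in any frame; its
    lower-left corner becomes the local origin, so every COP point lies inside
    [0, L_X] x [0, L_Y].
    """
    centers = []
    active = np.zeros(recording.shape, dtype=bool)
    for frame in recording.frames:
        active |= frame.grid > 0
        try:
            centers.append(pressure_center(frame))
        except EmptyFrameError:
            logger.debug("skipping zero-pressure frame %d", frame.index)
    if not centers:
        raise EmptyTrajectoryError("no frame carries positive pressure")
    ys, xs = np.nonzero(active)
    x0, y0 = float(xs.min()), float(ys.min())
    L_X, L_Y = float(xs.max() - x0), float(ys.max() - y0)
    pts = np.asarray(centers, dtype=float) - [x0, y0]
    return COPTrajectory(points=pts, bbox_origin=(x0, y0), L_X=L_X, L_Y=L_Y)


def map_trajectory(traj: COPTrajectory) -> MappedTrajectory:
    """Map foot-local COP points onto the 30 x 20 standard frame.

    Xc' = 30 Xc / L_X and Yc' = 20 Yc / L_Y, removing foot-size differences.
    """
    if traj.L_X <= 0 or traj.L_Y <= 0:
        raise DegenerateFootError(
            f"foot bounding box has zero extent (L_X={traj.L_X}, L_Y={traj.L_Y})"
        )
    scale = np.array([MAPPED_EXTENT_X / traj.L_X, MAPPED_EXTENT_Y / traj.L_Y])
    return MappedTrajectory(points=traj.points * scale)


def key_point_indices(n_points: int, k: int = N_KEY_POINTS) -> np.ndarray:
    """Equally spaced indices over the trajectory, first and last anchored.

    Index j of k is round(j (T-1) / (k-1)) with half-up rounding, so key point
    1 is always the first COP sample and key point k the last.
    """
    if n_points < k:
        raise InsufficientDataError(f"need at least {k} COP points, got {n_points}")
    return np.array(
        [math.floor(j * (n_points - 1) / (k - 1) + 0.5) for j in range(k)], dtype=int
    )


def select_key_points(traj: MappedTrajectory, k: int = N_KEY_POINTS) -> FeatureVector:
    """Extract the k key points and flatten them as (C1x, C1y, ..., Ckx, Cky)."""
    idx = key_point_indices(len(traj), k)
    return FeatureVector(values=traj.points[idx].ravel(), normalized=False)


def feature_table_from_vectors(vectors: list[FeatureVector], **extra_columns) -> FeatureTable:
    """Stack raw feature vectors into an (unnormalized) FeatureTable."""
    X = np.vstack([v.values for v in vectors])
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    for name, col in extra_columns.items():
        df[name] = col
    return FeatureTable(df, normalized=False)


def normalize_features(table: FeatureTable) -> tuple[FeatureTable, np.ndarray]:
    """Divide each feature column by its own maximum over the table's rows.

    Returns the normalized table and the 10 column maxima, to be re-applied to
    query samples at identification time.  Every column must have a strictly
    positive maximum (otherwise the feature is degenerate for this sample set).
    """
    X = table.X
    maxima = X.max(axis=0)
    bad = np.nonzero(maxima <= 0)[0]
    if bad.size:
        raise DegenerateFeatureError(
            f"zero-max feature column(s): {[FEATURE_COLUMNS[i] for i in bad]}"
        )
    df = table.data.copy()
    df[FEATURE_COLUMNS] = X / maxima
    return FeatureTable(df, normalized=True), maxima


def apply_normalization(vector: FeatureVector, maxima: np.ndarray) -> FeatureVector:
    """Scale a raw query vector by stored training maxima (element-wise)."""
    maxima = np.asarray(maxima, dtype=float).ravel()
    if maxima.size != vector.values.size:
        raise UsageError(f"maxima length {maxima.size} != vector length {vector.values.size}")
    if np.any(maxima <= 0):
        raise UsageError("normalization maxima must all be positive")
    scaled = vector.values / maxima
    if np.any(scaled > 1):
        logger.info("query feature exceeds training maximum (max ratio %.3f)", scaled.max())
    return FeatureVector(values=scaled, normalized=False)


def extract_features(recording: StanceRecording, k: int = N_KEY_POINTS) -> FeatureVector:
    """Full per-recording chain: COP line -> 30x20 mapping -> k key points."""
    return select_key_points(map_trajectory(extract_cop(recording)), k)


def plot_trajectory(traj: COPTrajectory | MappedTrajectory, path=None, ax=None):
    """Plot a COP line (matplotlib); returns the axes. Optional artifact export."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = traj.points
    ax.plot(pts[:, 0], pts[:, 1], "-o", markersize=2)
    ax.set_xlabel("X (heel → toe)")
    ax.set_ylabel("Y (medio-lateral)")
    ax.set_title("COP trajectory")
    if path is not None:
        ax.figure.savefig(path, dpi=120)
    return ax
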