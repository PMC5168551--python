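"""Reading and writing stance-phase pressure recordings and COP feature tables.

A recording is stored as a plain-text *frame stack*: optional ``# key: value``
header lines, then one matrix per frame (whitespace- or comma-separated rows),
frames separated by blank lines.  Alternatively a directory of per-frame CSV
files, taken in lexicographic order.  Feature tables are ordinary CSV
(header row, UTF-8) with the ten COP feature columns ``C1x .. C5y`` plus
optional metadata columns.

The packaged fixtures ``table1``/``table2``/``table4`` transcribe, at printed
two-decimal precision, the clustered 10-feature COP tables for the combined
(100 samples, 4 models), left-side (50 samples, 2 models) and right-side
(50 samples, 2 models) analyses, including their fuzzy membership columns and
hard category labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

FEATURE_COLUMNS = ["C1x", "C1y", "C2x", "C2y", "C3x", "C3y", "C4x", "C4y", "C5x", "C5y"]

_FIXTURES = {"table1": "table1.csv", "table2": "table2.csv", "table4": "table4.csv"}


@dataclass
class PressureFrame:
    """One 2D snapshot of the sensor grid.

    ``grid[row, col]`` holds the pressure at sensor cell (row, col); the foot's
    long (heel->toe) axis runs along columns (the x axis), the medio-lateral
    axis along rows (y).
    """

    grid: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise FormatError(f"frame {self.index}: expected a 2D grid, got ndim={self.grid.ndim}")
        if not np.all(np.isfinite(self.grid)):
            raise FormatError(f"frame {self.index}: non-finite pressure value")
        if np.any(self.grid < 0):
            raise FormatError(f"frame {self.index}: negative pressure value")

    @property
    def total_pressure(self) -> float:
        return float(self.grid.sum())


@dataclass
class StanceRecording:
    """An ordered sequence of same-shape pressure frames for one stance."""

    frames: list[PressureFrame]
    frame_rate: float = 126.0
    side: str = "unknown"
    condition: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise FormatError("a stance recording needs at least 2 frames")
        if self.frame_rate <= 0:
            raise FormatError("frame_rate must be positive")
        shape = self.frames[0].grid.shape
        for f in self.frames:
            if f.grid.shape != shape:
                raise FormatError(
                    f"frame {f.index}: shape {f.grid.shape} differs from {shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].grid.shape

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FeatureTable:
    """An n x 10 table of COP key-point features plus optional metadata.

    ``data`` keeps the feature columns (in canonical order) and any extra
    columns (``side``, ``condition``, ``mode1..modeC`` memberships,
    ``category``) exactly as read.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"feature table missing columns: {missing}")
        if len(self.data) >= 1 and self.data[FEATURE_COLUMNS].isna().any().any():
            raise FormatError("feature table contains missing values")
        if self.normalized and len(self.data):
            vals = self.data[FEATURE_COLUMNS].to_numpy(dtype=float)
            if vals.min() < 0 or vals.max() > 1 + 1e-12:
                raise FormatError("normalized table has values outside [0, 1]")

    @property
    def X(self) -> np.ndarray:
        """The n x 10 feature matrix."""
        return self.data[FEATURE_COLUMNS].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def membership_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("mode")]

    @property
    def memberships(self) -> np.ndarray | None:
        cols = self.membership_columns
        if not cols:
            return None
        return self.data[cols].to_numpy(dtype=float)

    @property
    def categories(self) -> np.ndarray | None:
        if "category" not in self.data.columns:
            return None
        return self.data["category"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# frame-stack format


def _parse_matrix(lines: list[str], frame_index: int) -> np.ndarray:
    rows = []
    for line in lines:
        sep = "," if "," in line else None
        try:
            rows.append([float(tok) for tok in line.replace(",", " ").split()])
        except ValueError as exc:
            raise FormatError(f"frame {frame_index}: unparseable row {line!r}") from exc
        del sep
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"frame {frame_index}: ragged rows (widths {sorted(widths)})")
    return np.asarray(rows, dtype=float)


def read_recording(path: str | Path) -> StanceRecording:
    """Read a recording from a frame-stack file or a directory of frame CSVs."""
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file or directory: {path}")
    meta: dict[str, str] = {}
    grids: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".csv")
        if not files:
            raise FormatError(f"directory {path} contains no .csv frames")
        for i, f in enumerate(files):
            lines = [ln for ln in f.read_text().splitlines() if ln.strip()]
            header = [ln for ln in lines if ln.lstrip().startswith("#")]
            body = [ln for ln in lines if not ln.lstrip().startswith("#")]
            for ln in header:
                _read_header_line(ln, meta)
            grids.append(_parse_matrix(body, i))
    else:
        block: list[str] = []
        for raw in path.read_text().splitlines() + [""]:
            line = raw.strip()
            if line.startswith("#"):
                _read_header_line(line, meta)
            elif line:
                block.append(line)
            elif block:
                grids.append(_parse_matrix(block, len(grids)))
                block = []
    frames = [PressureFrame(g, i) for i, g in enumerate(grids)]
    return StanceRecording(
        frames,
        frame_rate=float(meta.get("frame_rate", 126.0)),
        side=meta.get("side", "unknown"),
        condition=meta.get("condition", "unknown"),
        subject_id=meta.get("subject_id", ""),
    )


def _read_header_line(line: str, meta: dict[str, str]) -> None:
    body = line.lstrip("#").strip()
    if ":" in body:
        key, _, value = body.partition(":")
        meta[key.strip()] = value.strip()


def write_recording(recording: StanceRecording, path: str | Path) -> None:
    """Write a recording in the frame-stack text format (lossless for floats)."""
    path = Path(path)
    lines = [
        f"# frame_rate: {recording.frame_rate!r}",
        f"# side: {recording.side}",
        f"# condition: {recording.condition}",
        f"# subject_id: {recording.subject_id}",
    ]
    for frame in recording.frames:
        lines.append("")
        for row in frame.grid:
            lines.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(path: str | Path, normalized: bool = False) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    return FeatureTable(df, normalized=normalized)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV; round-trips reals to <= 1e-12."""
    table.data.to_csv(path, index=False)


def load_fixture(table_id: str) -> FeatureTable:
    """Load a packaged clustered-feature fixture: ``table1``/``table2``/``table4``.

    Values are kept at their printed 2-decimal precision; no re-rounding.
    All three fixtures are max-normalized feature tables.
    """
    if table_id not in _FIXTURES:
        raise UsageError(f"unknown fixture {table_id!r}; expected one of {sorted(_FIXTURES)}")
    ref = importlib.resources.files("copgait.data") / _FIXTURES[table_id]
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return FeatureTable(df, normalized=True)
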