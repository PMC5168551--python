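"""Synthetic stance-phase recordings with known COP ground truth.

Each recording is an isotropic Gaussian pressure blob translating heel->toe
along a smooth COP path (piecewise-cubic through 5 control points, mirroring
the 5-key-point feature design), modulated by a loading/unloading amplitude
profile and corrupted by additive sensor noise truncated at zero.  Two path
families — a straight-ish "normal" roll-off and a medially deviated path
standing in for ACLD gait — let the full pipeline (frames -> features ->
clustering -> identification) be exercised without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import UsageError
from .pressure_io import PressureFrame, StanceRecording

DEFAULT_GRID = (20, 40)  # rows (medio-lateral) x cols (heel->toe)
PEAK_AMPLITUDE = 100.0  # sensor units at mid-stance


@dataclass
class SyntheticGaitConfig:
    """Generator settings; defaults approximate a ~0.5 s barefoot stance.

    cop_path holds 5 (x, y) control points in the unit square ([0,1] maps to
    the grid interior with a blob-sized margin); amplitude_profile gives the
    per-frame total-pressure scaling (default: half-sine loading curve);
    noise_sd is the additive per-cell noise SD in sensor units.
    """

    grid_shape: tuple[int, int] = DEFAULT_GRID
    n_frames: int = 63
    frame_rate: float = 126.0
    cop_path: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.05, 0.50], [0.25, 0.42], [0.50, 0.45], [0.75, 0.52], [0.95, 0.48]]
        )
    )
    blob_sigma: float = 2.0
    amplitude_profile: np.ndarray | None = None
    noise_sd: float = 0.0
    path_jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.cop_path = np.asarray(self.cop_path, dtype=float)
        if self.cop_path.shape != (5, 2):
            raise UsageError("cop_path must be 5 (x, y) control points")
        if self.cop_path.min() < 0 or self.cop_path.max() > 1:
            raise UsageError("control points must lie in the unit square")
        if self.blob_sigma <= 0 or self.n_frames < 5 or self.noise_sd < 0:
            raise UsageError("blob_sigma > 0, n_frames >= 5, noise_sd >= 0 required")


def _interpolate_path(control: np.ndarray, n_frames: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, len(control))
    t = np.linspace(0.0, 1.0, n_frames)
    sx = CubicSpline(u, control[:, 0])
    sy = CubicSpline(u, control[:, 1])
    return np.column_stack([sx(t), sy(t)])


def generate_stance(
    config: SyntheticGaitConfig, rng: np.random.Generator | None = None
) -> tuple[StanceRecording, np.ndarray]:
    """One synthetic recording plus the exact continuous COP path (grid coords).

    The unit-square path is placed in the grid with a 2-sigma margin; a path
    (after jitter) that would push the blob off the grid is a configuration
    error.  Returned ground truth is the (n_frames, 2) array of blob centers
    as (x, y) grid coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    margin = 2.0 * config.blob_sigma
    if cols - 1 <= 2 * margin or rows - 1 <= 2 * margin:
        raise UsageError(f"grid {config.grid_shape} too small for blob sigma {config.blob_sigma}")
    control = config.cop_path
    if config.path_jitter_sd > 0:
        control = control + rng.normal(0.0, config.path_jitter_sd, size=control.shape)
    path01 = _interpolate_path(control, config.n_frames)
    if path01.min() < -0.25 or path01.max() > 1.25:
        raise UsageError("interpolated COP path leaves the grid")
    # map unit square onto the grid interior, long axis along columns (x)
    path = np.empty_like(path01)
    path[:, 0] = margin + path01[:, 0] * (cols - 1 - 2 * margin)
    path[:, 1] = margin + path01[:, 1] * (rows - 1 - 2 * margin)
    if path.min() < 0 or path[:, 0].max() > cols - 1 or path[:, 1].max() > rows - 1:
        raise UsageError("blob center leaves the sensor grid")

    if config.amplitude_profile is None:
        t = np.linspace(0.0, 1.0, config.n_frames)
        amplitude = PEAK_AMPLITUDE * np.sin(np.pi * np.clip(t, 0.02, 0.98))
    else:
        amplitude = np.asarray(config.amplitude_profile, dtype=float)
        if amplitude.shape != (config.n_frames,):
            raise UsageError("amplitude_profile must have one value per frame")

    ygrid, xgrid = np.mgrid[0:rows, 0:cols]
    frames = []
    for i, ((cx, cy), amp) in enumerate(zip(path, amplitude)):
        blob = amp * np.exp(
            -((xgrid - cx) ** 2 + (ygrid - cy) ** 2) / (2 * config.blob_sigma**2)
        )
        if config.noise_sd > 0:
            blob = blob + rng.normal(0.0, config.noise_sd, size=blob.shape)
        frames.append(PressureFrame(np.clip(blob, 0.0, None), index=i))
    recording = StanceRecording(frames, frame_rate=config.frame_rate)
    return recording, path


def default_families(noise_sd: float = 0.05 * PEAK_AMPLITUDE) -> dict[str, SyntheticGaitConfig]:
    """The two study path families: normal roll-off vs. a COP line deviated
    medially by 0.15 (normalized units) at mid-stance, as ACLD alters it."""
    normal = SyntheticGaitConfig(noise_sd=noise_sd, path_jitter_sd=0.02)
    acld_path = normal.cop_path.copy()
    acld_path[1:4, 1] += np.array([0.10, 0.15, 0.10])
    acld = replace(normal, cop_path=acld_path)
    return {"normal": normal, "acld": acld}


def generate_cohort(
    n_per_family: int,
    family_configs: dict[str, SyntheticGaitConfig] | None = None,
    seed: int | None = None,
) -> list[dict]:
    """A labeled, reproducible cohort of synthetic recordings.

    Returns one dict per recording: ``recording``, ``family``, ``ground_truth``
    (the exact COP path) and ``seed`` (the per-recording child seed).
    """
    if family_configs is None:
        family_configs = default_families()
    if len(family_configs) < 2:
        raise UsageError("need at least 2 families")
    root = np.random.SeedSequence(seed)
    cohort = []
    for (family, config), child in zip(
        family_configs.items(), root.spawn(len(family_configs))
    ):
        for rec_seed in child.spawn(n_per_family):
            rng = np.random.default_rng(rec_seed)
            recording, path = generate_stance(config, rng)
            recording.condition = family
            cohort.append(
                {
                    "recording": recording,
                    "family": family,
                    "ground_truth": path,
                    "seed": rec_seed.entropy,
                }
            )
    return cohort
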