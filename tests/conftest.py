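import numpy as np
import pandas as pd
import pytest

from copgait.pressure_io import FEATURE_COLUMNS, FeatureTable, PressureFrame, StanceRecording


@pytest.fixture
def random_recording():
    """50 random positive frames, 8x12 grid (seeded)."""
    rng = np.random.default_rng(0)
    frames = [PressureFrame(rng.random((8, 12)) + 0.01, i) for i in range(50)]
    return StanceRecording(frames, frame_rate=126.0, side="left",
                           condition="normal", subject_id="s01")


@pytest.fixture
def two_cloud_table():
    """Two well-separated 10-feature clouds, 30 samples each (seeded)."""
    rng = np.random.default_rng(12)
    a = rng.normal(0.2, 0.03, size=(30, 10))
    b = rng.normal(0.8, 0.03, size=(30, 10))
    X = np.clip(np.vstack([a, b]), 0.01, None)
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df["category"] = [1] * 30 + [2] * 30
    return FeatureTable(df, normalized=False)
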