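import numpy as np
import pandas as pd
import pytest

import dreamdepth as dd


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at desk scale (16 participants, 16 channels)."""
    return dd.generate_cohort(dd.SimConfig(n_participants=16, n_channels=16,
                                           seed=42))


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort (44 participants x 4 nights, few channels)."""
    return dd.generate_cohort(dd.SimConfig(n_channels=4, seed=7))


@pytest.fixture(scope="session")
def sensors16():
    return dd.spherical_cap_grid(16)


@pytest.fixture()
def grid4x4():
    """Regular planar 4x4 electrode grid with unit spacing."""
    xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
    pos = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(16)])
    labels = tuple(f"G{i:02d}" for i in range(16))
    return dd.SensorArray(labels, pos)


@pytest.fixture()
def simple_records():
    """Hand-built records with two participants and a pure linear time effect."""
    rng = np.random.default_rng(5)
    rows = []
    for pid in ("P01", "P02"):
        for i in range(30):
            t = rng.uniform(-1, 7.5)
            rows.append(
                {"record_id": f"{pid}_{i}", "participant_id": pid,
                 "experiment": 1 if pid == "P01" else 2,
                 "night": int(rng.integers(1, 5)), "time": t,
                 "sleep_depth": 3.0 + 0.127 * t, "sleepiness": 3.0}
            )
    return pd.DataFrame(rows)
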