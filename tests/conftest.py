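import numpy as np
import pandas as pd
import pytest

from anclick.io import AnimalInfo, CohortManifest
from anclick.simulate import SimulationParams


@pytest.fixture
def manifest4() -> CohortManifest:
    """Four-animal manifest, 2 FF / 2 FR, counterbalanced."""
    return CohortManifest(
        [
            AnimalInfo("r1", "FF", "context", "left", "B"),
            AnimalInfo("r2", "FF", "context", "right", "A"),
            AnimalInfo("r3", "FR", "flavor", "left", "B"),
            AnimalInfo("r4", "FR", "flavor", "right", "A"),
        ]
    )


@pytest.fixture
def cohort_csv(tmp_path, manifest4):
    path = tmp_path / "cohort.csv"
    manifest4.to_frame().to_csv(path, index=False)
    return path


@pytest.fixture
def events_csv(tmp_path):
    """Six-row fixture: 3 licks port 1, 2 entries port 2, 1 sipper_extend."""
    path = tmp_path / "events.csv"
    rows = [
        ("r1", 1, 1, "MM", "sipper_extend", 1, 0.0),
        ("r1", 1, 1, "MM", "lick", 1, 1.0),
        ("r1", 1, 1, "MM", "lick", 1, 1.2),
        ("r1", 1, 1, "MM", "lick", 1, 1.4),
        ("r1", 1, 1, "MM", "entry", 2, 2.0),
        ("r1", 1, 1, "MM", "entry", 2, 3.0),
    ]
    pd.DataFrame(
        rows,
        columns=["animal_id", "test_day", "paired_session", "condition", "kind", "port", "timestamp_s"],
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def small_params() -> SimulationParams:
    """Small but realistic cohort: 1 animal per cell, 3 sessions."""
    return SimulationParams(n_per_cell=1, n_sessions=3, seed=7)


def brute_force_segment(times: np.ndarray, threshold: float) -> list[list[float]]:
    """Independent O(n^2)-ish oracle: examine every split point one lick at a
    time, appending to the current cluster unless the gap exceeds threshold."""
    clusters: list[list[float]] = []
    for t in times:
        if clusters and (t - clusters[-1][-1]) <= threshold:
            clusters[-1].append(float(t))
        else:
            clusters.append([float(t)])
    return clusters
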