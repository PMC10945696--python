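import numpy as np
import pandas as pd
import pytest

from flyarena import ArenaGeometry, FlyTrackTable, SimConfig, build_schedule, simulate_cohort


@pytest.fixture(scope="session")
def geometry():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def activation():
    return build_schedule("activation_v1")


@pytest.fixture(scope="session")
def small_cohort(activation):
    """Four neutral flies under the activation protocol, no dropout."""
    cfg = SimConfig(n_flies=4, seed=7, track_dropout_rate=0.0)
    cohort, truth = simulate_cohort(cfg, activation)
    return cohort, truth, cfg


def make_tracks(per_fly: dict, fps: float = 30.0, heading: dict | None = None) -> FlyTrackTable:
    """Build a track table from {fly_id: (frames, x, y)} arrays."""
    parts = []
    for fly_id, (frames, x, y) in per_fly.items():
        df = pd.DataFrame(
            {
                "fly_id": fly_id,
                "frame": np.asarray(frames, dtype=np.int64),
                "x": np.asarray(x, dtype=float),
                "y": np.asarray(y, dtype=float),
            }
        )
        if heading and fly_id in heading:
            df["heading"] = np.asarray(heading[fly_id], dtype=float)
        parts.append(df)
    data = pd.concat(parts, ignore_index=True)
    data["t"] = data["frame"] / fps
    return FlyTrackTable(data[["fly_id", "frame", "t", "x", "y"] +
                              (["heading"] if heading else [])], fps=fps)
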