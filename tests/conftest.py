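import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose test helpers (_oracles, _dot)

import mttree as mt


@pytest.fixture
def six_row_csv(tmp_path):
    """Tiny table with two numeric features, a continuous and a survival target."""
    path = tmp_path / "six.csv"
    path.write_text(
        "g1,g2,y,time,event\n"
        "0.1,1.0,2.0,1.5,1\n"
        "0.2,2.0,2.5,2.0,0\n"
        "0.3,1.5,3.0,0.5,1\n"
        "0.4,3.0,8.0,4.0,1\n"
        "0.5,2.5,8.5,3.5,0\n"
        "0.6,1.0,9.0,5.0,1\n"
    )
    return path


@pytest.fixture
def six_row_specs():
    return [
        mt.TargetSpec("y", mt.TargetType.CONTINUOUS),
        mt.TargetSpec("time", mt.TargetType.SURVIVAL, event_col="event"),
    ]


def make_random_dataset(rng, n_rows=30, n_features=4, prefix="x"):
    """Random numeric-feature dataset with one continuous target."""
    cols = {f"{prefix}{j}": rng.normal(size=n_rows) for j in range(n_features)}
    cols["y"] = rng.normal(size=n_rows)
    frame = pd.DataFrame(cols)
    specs = [mt.TargetSpec("y", mt.TargetType.CONTINUOUS)]
    return mt.build_dataset(frame, specs), specs


def make_mixed_dataset(rng, n_rows=60, n_features=3):
    """Random dataset with all four target types (no planted structure)."""
    cols = {f"f{j}": rng.normal(size=n_rows) for j in range(n_features)}
    cols["y_cont"] = rng.normal(size=n_rows)
    cols["y_cat"] = rng.choice(["A", "B", "C"], size=n_rows)
    cols["y_count"] = rng.poisson(3.0, size=n_rows).astype(float)
    cols["time"] = rng.exponential(1.0, size=n_rows)
    cols["event"] = rng.integers(0, 2, size=n_rows).astype(float)
    frame = pd.DataFrame(cols)
    specs = [
        mt.TargetSpec("y_cont", mt.TargetType.CONTINUOUS),
        mt.TargetSpec("y_cat", mt.TargetType.CATEGORICAL),
        mt.TargetSpec("y_count", mt.TargetType.COUNT),
        mt.TargetSpec("time", mt.TargetType.SURVIVAL, event_col="event"),
    ]
    return mt.build_dataset(frame, specs), specs


@pytest.fixture
def planted_small():
    spec = mt.PlantSpec(n_rows=300, n_noise_features=5, seed=11)
    data, labels = mt.generate(spec)
    return spec, data, labels
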