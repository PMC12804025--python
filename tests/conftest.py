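import numpy as np
import pandas as pd
import pytest

from granulekit import synthetic_data as sd
from granulekit.quantio import QuantTable


@pytest.fixture
def noise_free_config():
    """Small noise-free world: generated values equal their class templates."""
    return sd.SimulationConfig(seed=1, n_proteins=60, noise_cv=0.0, dropout_rate=0.0)


@pytest.fixture
def default_config():
    return sd.SimulationConfig(seed=1, n_proteins=120)


def make_table(values: dict, meta_rows: list[dict]) -> QuantTable:
    """Build a QuantTable from {protein: [intensities]} plus sample metadata
    dicts (sample order matches the intensity lists)."""
    ids = [m["sample_id"] for m in meta_rows]
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    frame = pd.DataFrame(values, index=ids).T
    frame.index.name = "protein"
    return QuantTable(frame.astype(float), samples)


def sample_meta(sample_id, condition, time_min, replicate=1, compartment="supernatant"):
    return {
        "sample_id": sample_id,
        "compartment": compartment,
        "condition": condition,
        "time_min": time_min,
        "replicate": replicate,
    }


@pytest.fixture
def two_condition_table():
    """2 proteins x (control + stimulated) x 3 time points, exact values."""
    meta = [
        sample_meta(f"{c}_{t}", c, t)
        for c in ("CONTROL", "LPS")
        for t in (0, 60, 120)
    ]
    values = {
        "P1": [100.0, 100.0, 100.0, 100.0, 200.0, 300.0],
        "P2": [50.0, 50.0, 50.0, 50.0, 50.0, 50.0],
    }
    return make_table(values, meta)
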