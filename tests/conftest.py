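import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from alteredpqr import SimulationConfig, make_pairs, simulate_dataset

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def tiny_matrix():
    """4 proteins x 6 samples (4 reference, 2 test), handcrafted log2 values."""
    data = {
        "R1": [5.0, 3.0, 10.0, 8.0],
        "R2": [5.1, 3.1, 10.2, 8.1],
        "R3": [4.9, 2.9, 9.9, 7.9],
        "R4": [5.05, 3.05, 10.1, 8.05],
        "T1": [7.0, 3.0, 10.0, 8.0],
        "T2": [5.0, 3.0, np.nan, 8.0],
    }
    return pd.DataFrame(data, index=pd.Index(["A", "B", "C", "D"],
                                             name="protein_id"))


@pytest.fixture
def tiny_design(tiny_matrix):
    groups = ["reference"] * 4 + ["test"] * 2
    return pd.DataFrame({"group": groups, "subtype": groups},
                        index=pd.Index(tiny_matrix.columns, name="sample_id"))


@pytest.fixture
def tiny_pairs(tiny_matrix):
    return make_pairs([("A", "B"), ("C", "D"), ("A", "C")],
                      matrix=tiny_matrix)


@pytest.fixture(scope="session")
def null_dataset():
    """Default-world simulation with no injected events."""
    cfg = SimulationConfig(seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def shifted_dataset():
    """Default world plus one strong pair shift and one hub protein."""
    cfg = SimulationConfig(
        seed=7,
        n_proteins=80,
        shift_pairs=[(("P0000", "P0001"), 8 * 0.25, 0.4)],
        hub_proteins=[("P0030", 1.5)])
    return cfg, simulate_dataset(cfg)
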