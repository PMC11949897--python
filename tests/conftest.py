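"""Shared fixtures: a small seeded synthetic dataset and hypothesis settings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mycohub.io import AsvCountTable, SampleMetadata
from mycohub.synthetic import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CONFIG = SimulationConfig(
    seed=7,
    n_tissues=4,
    replicates_per_tissue=4,
    n_asvs=60,
    pool_min=20,
    n_producers=6,
    n_modules=3,
    module_size=5,
    depth_log_mean=np.log(5000.0),
    n_reference_strains=10,
    gradient=(360.27, 220.0, 110.0, 60.0),
)


@pytest.fixture(scope="session")
def small_ds():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture()
def tiny_table():
    counts = pd.DataFrame(
        [[10, 0, 5], [0, 8, 2], [4, 4, 4], [1, 0, 9]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A1", "A2", "A3"],
    )
    return AsvCountTable(counts)


@pytest.fixture()
def tiny_meta():
    return SampleMetadata(
        pd.DataFrame(
            {
                "species": ["X", "X", "X", "X"],
                "tissue": ["leaf", "leaf", "stem", "stem"],
                "replicate": [1, 2, 1, 2],
            },
            index=["s1", "s2", "s3", "s4"],
        )
    )
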