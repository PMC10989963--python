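import numpy as np
import pandas as pd
import pytest

import habflux as hf


@pytest.fixture(scope="session")
def small_scenario():
    """A desk-scale survey-shaped scenario shared across test modules."""
    cfg = hf.ScenarioConfig(
        n_taxa=300, depth=5000, seed=11,
        mixing_matrix={"water": {"soil": 0.5, "water": 0.35, "unknown": 0.15}},
    )
    return hf.generate_metacommunity(cfg)


@pytest.fixture
def tiny_table():
    counts = np.array([
        [5, 0, 2],
        [0, 3, 3],
        [1, 1, 0],
    ])
    return hf.FeatureTable(["t1", "t2", "t3"], ["s1", "s2", "s3"], counts)


@pytest.fixture
def pair_metadata():
    rows = []
    for habitat in ("soil", "water"):
        for i in range(4):
            rows.append({"sample_id": f"{habitat}_{i}", "habitat": habitat,
                         "park": f"P{i + 1}", "replicate": 1, "region": "V4"})
    return hf.SampleMetadata(pd.DataFrame(rows))
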