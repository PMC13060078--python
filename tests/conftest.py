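import numpy as np
import pandas as pd
import pytest

import resilmet as rm


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 60 participants, 120 features, all structures planted."""
    return rm.GeneratorConfig(n_participants=60, n_features=120,
                              n_resilience_features=12, n_age_features=12,
                              n_contaminants=6, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return rm.generate_all(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the generator's default study conditions."""
    cfg = rm.GeneratorConfig(n_features=300, seed=1)
    return rm.generate_all(cfg)


@pytest.fixture
def toy_table():
    """Tiny hand-checkable feature table: 3 features x 4 samples + 1 blank."""
    features = pd.DataFrame(
        {"mz": [200.0, 300.0, 400.0], "rt": [0.5, 2.0, 5.0]},
        index=pd.Index(["FA", "FB", "FC"], name="feature_id"))
    areas = pd.DataFrame(
        [[1e5, 2e5, 0.0, 4e5, 1e3],
         [5e4, 5e4, 5e4, 5e4, 1e3],
         [0.0, 1e5, 2e5, 3e5, 8e4]],
        index=features.index,
        columns=["s1", "s2", "s3", "s4", "blank1"])
    return rm.FeatureTable(features, areas)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4", "blank1"],
        "participant_id": ["P1", "P2", "P3", "P4", None],
        "visit": [1, 1, 1, 1, None],
        "age": [70.0, 72.0, 74.0, 76.0, np.nan],
        "sex": ["female", "male", "female", "male", None],
        "education": [12.0, 16.0, 14.0, 12.0, np.nan],
        "resilience": [0.1, -0.2, 0.3, 0.0, np.nan],
        "is_blank": [False, False, False, False, True],
    })
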