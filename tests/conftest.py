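import numpy as np
import pandas as pd
import pytest

import heliosel as hs


@pytest.fixture(scope="session")
def worked():
    """The deterministic 12-plant, 2-population hand-checkable dataset."""
    frames, tidy = hs.worked_fixture()
    return frames, tidy


@pytest.fixture(scope="session")
def small_experiment():
    """One site x year x source pair, trimmed plant counts for speed."""
    cfg = hs.SyntheticConfig(
        n_sites=1, n_years=1, n_seed_sources=1, n_plants_range=(40, 60), rng_seed=11
    )
    frames, truth = hs.generate_experiment(cfg)
    return frames, truth


@pytest.fixture(scope="session")
def paired_experiment():
    """Two sites, one year, two sources: eight populations at field sizes."""
    cfg = hs.SyntheticConfig(n_sites=2, n_years=1, n_seed_sources=2, rng_seed=5)
    frames, truth = hs.generate_experiment(cfg)
    return frames, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
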