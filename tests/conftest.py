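import numpy as np
import pytest

from streamcom import CommunityParams, GeneratorConfig, generate_statespace_data


@pytest.fixture
def single_species():
    return CommunityParams(r=[1.5], alpha=[[1.0]], K=[100.0])


@pytest.fixture
def symmetric_pair():
    return CommunityParams(
        r=[1.5, 1.5],
        alpha=[[1.0, 0.25], [0.25, 1.0]],
        K=[100.0, 100.0],
    )


@pytest.fixture(scope="session")
def small_monitoring_dataset():
    """A small but fully-featured monitoring dataset (both groups,
    releases, covariates, truth)."""
    cfg = GeneratorConfig(
        n_watersheds=4, sites_per_watershed=2, gap_probs=((1, 1.0),), seed=42
    )
    return generate_statespace_data(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
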