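import numpy as np
import pytest

from scdkit.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_planted_cohort():
    """50 genes with the default planting gradient; session-cached."""
    config = SyntheticConfig(n_genes=50, seed=42)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_unplanted_cohort():
    """50 genes of pure background sequence; session-cached."""
    config = SyntheticConfig(
        n_genes=50,
        flank_planting_density=0.0,
        core_planting_density=0.0,
        flank3_planting_density=0.0,
        seed=43,
    )
    return generate_cohort(config)
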