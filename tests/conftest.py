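import numpy as np
import pytest

from harmon.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """5 sites x 40 subjects, 8 ROIs, planted g = 0.3, mild site effects, 5% missing."""
    cfg = SyntheticConfig(
        n_sites=5, site_sizes=40, roi_counts=(8, 0, 0), effect_g=0.3,
        gamma_spread=0.4, gamma_tau=0.3, delta_shape=6, delta_scale=5,
        missing_rate=0.05, seed=101,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def complete_dataset():
    """4 sites x 50 subjects, 6 ROIs, site effects, fully observed."""
    cfg = SyntheticConfig(
        n_sites=4, site_sizes=50, roi_counts=(6, 0, 0), effect_g=0.25,
        gamma_spread=0.5, gamma_tau=0.3, delta_shape=6, delta_scale=5,
        missing_rate=0.0, seed=202,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def no_site_effect_dataset():
    """6 sites x 300, 10 ROIs, gamma = 0 and delta ~ 1 (near-degenerate prior)."""
    cfg = SyntheticConfig(
        n_sites=6, site_sizes=300, roi_counts=(10, 0, 0), effect_g=0.3,
        gamma_spread=0.0, gamma_tau=0.0, delta_shape=2000.0, delta_scale=1999.0,
        missing_rate=0.0, seed=303,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
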