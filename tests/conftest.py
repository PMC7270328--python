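import numpy as np
import pytest

from connharm.synthetic_data import SyntheticConfig, generate_fc_cohort


@pytest.fixture(scope="session")
def easy_cohort():
    """Strong sparse diagnosis effect, no site bias: near-perfectly separable."""
    cfg = SyntheticConfig(
        n_sites=4,
        n_hc_per_site=10,
        n_mdd_per_site=10,
        n_rois=12,
        effect_size=2.0,
        effect_fraction=0.1,
        site_offset_sd=0.0,
        seed=11,
    )
    return generate_fc_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No diagnosis effect, no site bias: chance-level classification."""
    cfg = SyntheticConfig(
        n_sites=4,
        n_hc_per_site=10,
        n_mdd_per_site=10,
        n_rois=12,
        effect_size=0.0,
        effect_fraction=0.0,
        site_offset_sd=0.0,
        seed=12,
    )
    return generate_fc_cohort(cfg)


@pytest.fixture(scope="session")
def biased_cohort():
    """Moderate diagnosis effect plus per-site offsets and covariate slopes."""
    cfg = SyntheticConfig(
        n_sites=4,
        n_hc_per_site=12,
        n_mdd_per_site=12,
        n_rois=12,
        effect_size=1.0,
        effect_fraction=0.05,
        site_offset_sd=1.0,
        seed=13,
    )
    return generate_fc_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
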