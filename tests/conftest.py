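import dataclasses

import pytest
from hypothesis import settings

from stoichdemo.config import DesignConfig, PipelineConfig, default_params

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def design():
    return DesignConfig()


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def small_config():
    """A trimmed trial small enough for fast end-to-end tests."""
    cfg = PipelineConfig()
    cfg.design.n_individuals_per_replicate = 4
    cfg.design.n_chemostat_replicates = 3
    cfg.design.n_individuals_morphometry = 3
    cfg.design.census_days = 22
    cfg.n_boot = 200
    return cfg


def noiseless(params, label, **overrides):
    """Copy of one treatment's parameters with all randomness removed."""
    p = dataclasses.replace(
        params[label],
        maturation_time_sd=0.0,
        inter_egg_interval_sd=0.0,
        egg_development_time_sd=0.0,
        egg_mortality_prob=0.0,
        adult_hazard=0.0,
        male_egg_prob=0.0,
        algal_cp_se=0.0,
        census_log_sd=0.0,
    )
    return dataclasses.replace(p, **overrides)
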