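import numpy as np
import pytest
from hypothesis import settings

import apastep as ap

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gen_config():
    return ap.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def noisefree_config():
    return ap.GeneratorConfig(
        seed=7, force_noise_n=0.0, cop_noise_m=0.0, marker_noise_m=0.0
    )


@pytest.fixture(scope="session")
def participants(gen_config):
    rng = np.random.default_rng(gen_config.seed)
    return ap.gen_participants(gen_config, rng)


@pytest.fixture(scope="session")
def clean_trial(participants, gen_config):
    return ap.gen_timeseries_trial(
        participants[0], "dual-medial", 42, config=gen_config
    )


@pytest.fixture(scope="session")
def summary_cohort():
    cfg = ap.GeneratorConfig(seed=3)
    table, truth = ap.gen_cohort_summary(cfg)
    return cfg, table, truth
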