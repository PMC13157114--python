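import numpy as np
import pytest

from stressphys.synthetic_data import (NoiseParams, SimulationConfig,
                                       generate_session)


def quiet_config(**kw) -> SimulationConfig:
    """Small, noiseless, jitter-free configuration for recovery tests."""
    cfg = SimulationConfig(n_participants_per_group=2, n_trials_atb=8,
                           n_trials_viewing=4, seed=7, **kw)
    cfg.noise = NoiseParams(sd_uv=0.0)
    cfg.ssvep.trial_sigma = 0.0
    cfg.ssvep.subject_bias_sd = 0.0
    cfg.erp.subject_sigma = 0.0
    cfg.erp.trial_sigma = 0.0
    cfg.erp_attenuation = {"stress": 1.0, "control": 1.0}
    cfg.scr.noise_sd_us = 0.0
    cfg.scr.trial_sigma = 0.0
    cfg.scr.response_prob = 1.0
    cfg.rr.noise_ms = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small noisy configuration for smoke/bookkeeping tests."""
    return SimulationConfig(n_participants_per_group=2, n_trials_atb=8,
                            n_trials_viewing=4, seed=7)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, "stress", 0)


@pytest.fixture(scope="session")
def symmetric_session():
    """Noiseless session with no attention or hemifield asymmetries."""
    cfg = quiet_config()
    cfg.ssvep.attention_weights = {"angry": 1.0, "happy": 1.0, "neutral": 1.0}
    cfg.hemifield_bias = {"stress": 0.0, "control": 0.0}
    return generate_session(cfg, "stress", 0)


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(2024)
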