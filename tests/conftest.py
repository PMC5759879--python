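import numpy as np
import pytest

from posturometry.synthetic import SimulationConfig, SubjectProfile, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def profile():
    """One deterministic healthy subject with round-number traits."""
    cfg = SimulationConfig(n_subjects=1, master_seed=42)
    return make_cohort(cfg)[0]


@pytest.fixture
def quiet_profile():
    """A subject whose planted traits are exactly known round numbers."""
    from posturometry.variables import VARIABLE_NAMES

    traits = {name: 0.0 for name in VARIABLE_NAMES}
    traits.update({"P-WB": 50.0, "SB-LF": 25.0, "SB-RF": 27.0, "SB-%BW": 80.0,
                   "P-HL": 2.0, "P-HF": 1.5, "P-NA": 5.0, "P-PP": 0.8,
                   "P-HS": -1.2})
    return SubjectProfile(subject_id="T001", height=175.0, weight=70.0,
                          group="healthy", trait_vector=traits,
                          sway_scale=1.0, seed=7)


@pytest.fixture
def noise_free_config():
    return SimulationConfig(
        n_subjects=1, sigma_between=0.0, sigma_within=0.0, sigma_device=0.0,
        marker_noise_sd=0.0, cop_noise_sd=0.0, sway_sd_stand=(0.0, 0.0),
        sway_sd_single=(0.0, 0.0), granularity="trace", master_seed=1)
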