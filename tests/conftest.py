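import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emtrial.config import SimulationConfig
from emtrial.simulate import generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_world():
    """A mid-size cohort under the shipped default generator settings."""
    cfg = SimulationConfig(
        n_patients=5000, seed=42, true_log_hr=float(np.log(0.8)),
        baseline_event_odds=0.008,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_world():
    """A small cohort with the incidental realism knobs switched off."""
    cfg = SimulationConfig(
        n_patients=800, seed=7, true_log_hr=0.0, baseline_event_odds=0.01,
        missingness_prob=0.0, baseline_oac_prob=0.0, pre_start_event_prob=0.0,
    )
    return cfg, generate_cohort(cfg)
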