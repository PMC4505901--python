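import numpy as np
import pytest

from wristid import SyntheticConfig, default_muscles, generate_subject
from wristid.synth import GroupRatioModel


@pytest.fixture(scope="session")
def specs():
    return default_muscles()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free study conditions for deterministic structural checks."""
    return SyntheticConfig(snr_db=None, angle_noise_deg=0.0)


@pytest.fixture(scope="session")
def study_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def control_subject(study_config):
    """One virtual control subject at the study noise level."""
    rng = np.random.default_rng(7)
    return generate_subject("C1", "control", rng, study_config)


@pytest.fixture(scope="session")
def fixed_ratio_subject_factory(study_config):
    """Subjects whose ground-truth B/K ratio is pinned exactly per task."""

    def make(step_ratio=0.17, pursuit_ratio=1.30, seed=0, config=None):
        model = GroupRatioModel(step_ratio, 0.0, pursuit_ratio, 0.0)
        rng = np.random.default_rng(seed)
        return generate_subject(
            "S", "control", rng, config or study_config, model=model
        )

    return make
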