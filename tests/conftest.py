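import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fnirsglm.montage import Montage, Channel, default_montage
from fnirsglm.paradigm import CONDITIONS, DesignConfig, generate_schedule
from fnirsglm.simulate import NoiseSpec, SubjectTruth


@pytest.fixture(scope="session")
def montage() -> Montage:
    return default_montage()


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(seed=12345)


@pytest.fixture(scope="session")
def short_schedule():
    """Two cycles (8 blocks): the reduced design used for simulations."""
    return generate_schedule(DesignConfig(n_cycles=2), seed=54321)


@pytest.fixture
def silent_noise() -> NoiseSpec:
    return NoiseSpec(ar_coeffs=(), white_sd=0.0, oscillations=(), drift_slope=0.0)


@pytest.fixture
def null_truth(montage, silent_noise) -> SubjectTruth:
    return SubjectTruth(
        beta_true=np.zeros((montage.n_channels, len(CONDITIONS))),
        conditions=CONDITIONS,
        subject_offset_sd=0.0,
        noise=silent_noise,
    )
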