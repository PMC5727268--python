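import numpy as np
import pytest
from hypothesis import settings

import cmaplin as cml

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return cml.StimulusSchedule(mt=0.3)


@pytest.fixture(scope="session")
def cohort_seed1():
    """Default synthetic cohort: 16 nerves x 4 conditions, seed 1."""
    return cml.generate_cohort(cml.SimConfig(seed=1))


@pytest.fixture(scope="session")
def ramp_matrix():
    """One-subject matrix whose baseline row is a clean 100..500 uV ramp."""
    vpp = np.array(
        [
            [100.0, 200.0, 300.0, 400.0, 500.0],
            [100.0, 180.0, 260.0, 340.0, 420.0],
            [80.0, 110.0, 140.0, 150.0, 160.0],
            [50.0, 55.0, 52.0, 54.0, 53.0],
        ]
    )
    return cml.CmapMatrix(vpp=vpp, subject_id="ramp")


def random_cmap_matrix(rng):
    """Random strictly positive 4x5 amplitude matrix."""
    vpp = rng.uniform(10.0, 800.0, size=(4, 5))
    return cml.CmapMatrix(vpp=vpp)
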