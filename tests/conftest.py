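import numpy as np
import pytest
from hypothesis import settings

import sarcoscreen as sc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_record(sex="male", age=70.0, height=1.6, asmi=6.5, grip=30.0,
                gait_speed=1.1, cc=34.0, id="x"):
    return sc.ParticipantRecord(
        id=id, sex=sc.Sex.parse(sex), age=age, height=height, asmi=asmi,
        grip=grip, gait_speed=gait_speed, calf_circumference=cc,
    )


@pytest.fixture(scope="session")
def table1_config():
    return sc.default_config_from_table1(n_total=941, seed=7)


@pytest.fixture(scope="session")
def calibrated_config():
    """Config with diagnostic means calibrated to the study's 18.38% prevalence."""
    base = sc.default_config_from_table1(n_total=941, seed=7)
    return sc.calibrate_prevalence(base, 0.1838, tolerance=0.005)


@pytest.fixture(scope="session")
def calibrated_cohort(calibrated_config):
    return sc.generate_cohort(calibrated_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
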