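import numpy as np
import pytest

from vmtrack.simulate import CONTROL_TEMPLATE, PATIENT_TEMPLATE, LoopConfig, simulate_tracking
from vmtrack.stimulus import build_spec, generate_sum_of_sines

BEST4_TRUTH = np.array([2.7, 2.7, 0.39, 0.39, 0.210, 0.141, 0.141, 0.0])


@pytest.fixture(scope="session")
def default_spec():
    return build_spec(phase_seed=11)


@pytest.fixture(scope="session")
def sum_of_sines(default_spec):
    return generate_sum_of_sines(default_spec)


@pytest.fixture(scope="session")
def short_spec():
    # 40 s trials: after the 20 s transient discard, one full fundamental
    # period remains and every stimulated frequency is still an exact bin.
    return build_spec(phase_seed=11, trial_duration=40.0)


@pytest.fixture(scope="session")
def short_trajectory(short_spec):
    return generate_sum_of_sines(short_spec)


@pytest.fixture(scope="session")
def control_trials_short(short_trajectory):
    """One noiseless trial of the control-like template (40 s)."""
    loop = LoopConfig(n_trials=1, seed=0)
    return simulate_tracking(CONTROL_TEMPLATE, short_trajectory, loop), loop


@pytest.fixture(scope="session")
def patient_trials_short(short_trajectory):
    loop = LoopConfig(n_trials=1, seed=0)
    return simulate_tracking(PATIENT_TEMPLATE, short_trajectory, loop), loop
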