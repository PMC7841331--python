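import numpy as np
import pytest

from chemocontrol import reference_setup


@pytest.fixture(scope="session")
def ref():
    """Reference study configuration: (ModelParams, DoseSchedule, ObjectiveWeights)."""
    return reference_setup()


@pytest.fixture(scope="session")
def ref_params(ref):
    return ref[0]


@pytest.fixture(scope="session")
def ref_schedule(ref):
    return ref[1]


@pytest.fixture(scope="session")
def ref_weights(ref):
    return ref[2]


@pytest.fixture(scope="session")
def baseline_trajectory(ref):
    """Coupled-system trajectory at the reference configuration, t in [0, 500]."""
    from chemocontrol import simulate

    params, schedule, _ = ref
    return simulate(params, schedule, t_end=500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
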