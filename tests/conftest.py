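import numpy as np
import pytest

from nutriredox import default_parameters, reference_environment
from nutriredox.dynamics import steady_initial_state
from nutriredox.model import NutrientEnvironment


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def env():
    return reference_environment()


@pytest.fixture(scope="session")
def high_state(params, env):
    """Reference high-GSH steady state at abundant nutrients."""
    return steady_initial_state(env, params, branch="high_gsh", n_starts=64)


@pytest.fixture(scope="session")
def deprivation():
    """Schedule factory: step glucose to a low level at t=0."""
    base = reference_environment()

    def make(glc_low, gln_fold=1.0, cys2_fold=1.0):
        return NutrientEnvironment(
            base.glc_ext, base.gln_ext, base.cys2_ext,
            schedule=((0.0, glc_low, base.gln_ext * gln_fold,
                       base.cys2_ext * cys2_fold),))

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(20211048)


def jitter_params(params, rng, cv=0.3, skip=("switch_nadp_import", "f_ros_from_glc",
                                             "f_ros_from_glu", "n1")):
    """Random admissible parameter set near the defaults (lognormal jitter)."""
    sigma = np.sqrt(np.log1p(cv**2))
    changes = {}
    for name, value in params.to_dict().items():
        if name in skip or value == 0:
            continue
        changes[name] = value * float(np.exp(rng.normal(0.0, sigma)))
    return params.replace(**changes)
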