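import numpy as np
import pytest
from hypothesis import settings

from redusim import DoseRegimen, ModelParameters, Scenario, simulate
from redusim.model import build_runtime

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def runtime(params):
    """Forced runtime parameters and the intact steady state."""
    rp, x0 = build_runtime(params)
    return rp, x0


@pytest.fixture(scope="session")
def treated_result(params, runtime):
    """One shared 21-day 40 mg/kg QD simulation (sampled hourly)."""
    rp, x0 = runtime
    scenario = Scenario(kind="treated", regimen=DoseRegimen(40.0, 24.0, 21.0))
    return simulate(scenario, params, t_end_hr=504.0, runtime=rp, x0=x0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120906)
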