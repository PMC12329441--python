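import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from goebox import Params, nominal_scenario, run
from goebox.scenario import fig2_grid, fig3_grid


@pytest.fixture(scope="session")
def params():
    return Params()


@pytest.fixture(scope="session")
def nominal_result():
    """The reference 4-Gyr run (fixation 3.8 Ga, oxygenesis 3.5 Ga)."""
    return run(nominal_scenario())


@pytest.fixture(scope="session")
def fig2_results():
    """All 18 metabolic-onset scenarios, keyed by scenario id."""
    return {res.scenario.id: res for res in map(run, fig2_grid())}


@pytest.fixture(scope="session")
def fig3_results():
    """All 18 phosphorus-sensitivity scenarios, keyed by scenario id."""
    return {res.scenario.id: res for res in map(run, fig3_grid())}


def age_index(result, age_ga: float) -> int:
    return int(np.argmin(np.abs(result.age_ga - age_ga)))


def window_mask(result, age_old: float, age_young: float):
    age = result.age_ga
    return (age <= age_old) & (age >= age_young)
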