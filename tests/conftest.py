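import numpy as np
import pytest

from hepfast import model_core, synthetic_menus


@pytest.fixture(scope="session")
def params():
    return model_core.default_parameters()


@pytest.fixture(scope="session")
def menus():
    return synthetic_menus.fixture_menus()


@pytest.fixture(scope="session")
def scenario_grid():
    return synthetic_menus.fixture_scenarios()


@pytest.fixture()
def rng():
    return np.random.default_rng(20221124)


@pytest.fixture(scope="session")
def lunch1_init():
    """Initial state for the ketogenic-menu lunch scenario."""
    class _Scen:
        G_B0, T_LB0 = 3.2, 9.1
    return model_core.initial_state(_Scen)
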