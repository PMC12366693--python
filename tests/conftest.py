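import numpy as np
import pytest

from demicwave import coalescent, forward, synth
from demicwave.scenarios import ParameterDraw


@pytest.fixture(scope="session")
def toy():
    return synth.make_toy_world()


@pytest.fixture(scope="session")
def toy_scheme(toy):
    return synth.toy_scheme(toy)


@pytest.fixture(scope="session")
def mid_draw():
    """A mid-prior AM1 parameter draw used for shared forward runs."""
    return ParameterDraw(
        scenario_id="AM1", gamma=0.05, K_HG=300, K_FA=1500,
        m_FA=0.3, P_LDD=0.01, alpha_N=0.3, eps=7e-5,
    )


@pytest.fixture(scope="session")
def db_default(toy, mid_draw):
    return forward.run_forward(synth.forward_config(toy, mid_draw), 11)


@pytest.fixture(scope="session")
def panel_default(db_default, toy_scheme):
    return coalescent.simulate_genomes(
        db_default, toy_scheme, coalescent.LocusConfig(), 5e-5,
        np.random.default_rng(7),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
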