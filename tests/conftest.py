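import numpy as np
import pytest
from hypothesis import settings

import wingmod as wm
from wingmod.synthetic import SyntheticConfig, generate_scenario, simulate_tree

settings.register_profile("suite", deadline=None, max_examples=40, derandomize=True)
settings.load_profile("suite")

NWK3 = "((A:1,B:1):1,C:2);"


@pytest.fixture
def tree3():
    return wm.read_newick(NWK3)


@pytest.fixture(scope="session")
def tree64():
    """Fixed ultrametric 64-tip Yule tree used for estimator calibration."""
    return simulate_tree(SyntheticConfig(n_species=64, seed=64))


@pytest.fixture(scope="session")
def tree32():
    return simulate_tree(SyntheticConfig(n_species=32, seed=32))


def star_newick(n: int, depth: float = 1.0) -> str:
    tips = ",".join(f"t{i}:{depth}" for i in range(n))
    return f"({tips});"


@pytest.fixture(scope="session")
def mass_dependent_small():
    """One mass-dependent scenario realisation shared across tests."""
    return generate_scenario("mass_dependent", seed=17, n_species=228)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
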