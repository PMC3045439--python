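import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import imprintgen as ig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strategy1_data():
    return ig.simulate(ig.strategy_preset("strategy1"), seed=11)


@pytest.fixture(scope="session")
def strategy2_data():
    return ig.simulate(ig.strategy_preset("strategy2"), seed=12)


@pytest.fixture(scope="session")
def tiny_data():
    """A small dataset (30 phenotyped subjects) for brute-force oracles."""
    design = ig.DesignSpec(n_gen1_families=15, sons_per_family=1,
                           children_per_couple=1)
    return ig.simulate(design, seed=13)


@pytest.fixture(scope="session")
def two_snp_data():
    hs = ig.HaplotypeSystem(frequencies=(0.4, 0.1, 0.1, 0.4), r=0.05,
                            risk_haplotype="AB")
    design = ig.DesignSpec(n_gen1_families=160, sons_per_family=1,
                           children_per_couple=1)
    return ig.simulate_two_snp(design, hs, seed=14)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
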