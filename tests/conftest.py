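import numpy as np
import pytest
from hypothesis import settings

import meiocross as mc
from meiocross.classify import tabulate

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ten_cm_map():
    return mc.IntervalPairMap(d1=10.0, d2=10.0)


@pytest.fixture(scope="session")
def poisson_50k(ten_cm_map):
    """50,000 tetrads from a pure non-interfering (Poisson) crossover process."""
    params = mc.PathwayParams(nu=1.0, frac_class2=1.0)
    return mc.simulate_sample(50_000, ten_cm_map, params, seed=101)


@pytest.fixture(scope="session")
def poisson_50k_counts(poisson_50k):
    return tabulate(poisson_50k, genotype="poisson")


@pytest.fixture(scope="session")
def interfering_50k(ten_cm_map):
    """50,000 tetrads, pure Class I with strong interference (nu = 8)."""
    params = mc.PathwayParams(nu=8.0, frac_class2=0.0)
    return mc.simulate_sample(50_000, ten_cm_map, params, seed=202)


@pytest.fixture(scope="session")
def interfering_50k_counts(interfering_50k):
    return tabulate(interfering_50k, genotype="interfering")


@pytest.fixture(scope="session")
def mixed_10k(ten_cm_map):
    """10,000 tetrads under the wild-type-like two-pathway defaults."""
    return mc.simulate_sample(10_000, ten_cm_map, mc.PathwayParams(), seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
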