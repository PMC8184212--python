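import numpy as np
import pytest

from crossfeed import MoserParams, StrainPhenotype
from crossfeed.synth import ancestor_phenotype, partner_phenotype, mutant_phenotype


@pytest.fixture
def ancestor():
    return ancestor_phenotype()


@pytest.fixture
def partner():
    return partner_phenotype()


@pytest.fixture
def mutant():
    return mutant_phenotype()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_phenotype(rng, **overrides):
    """A random but well-posed strain phenotype for property tests."""
    kw = dict(
        release_rate=rng.uniform(0.05, 2.0),
        consumption_per_birth=rng.uniform(0.5, 10.0),
        kinetics=MoserParams(
            b_max=rng.uniform(0.2, 0.8),
            K=rng.uniform(0.05, 2.0),
            n=rng.uniform(1.0, 3.0),
        ),
        death_rate=0.0,
    )
    kw.update(overrides)
    return StrainPhenotype(**kw)
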