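import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmpkit.popdata import Individual, PopulationSample

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def diploid(i, genotypes):
    return Individual(
        id=f"i{i}", sex="female", declared_ploidy="diploid", genotypes=genotypes
    )


@pytest.fixture
def make_diploid_pop():
    """Population of diploid females from a list of genotype dicts."""

    def build(genotype_dicts, name="p1", habitat="mainland"):
        inds = [diploid(i, g) for i, g in enumerate(genotype_dicts)]
        return PopulationSample(name=name, habitat=habitat, individuals=inds)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20160831)
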