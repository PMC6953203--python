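import numpy as np
import pytest

from redleaf.simulate import MarkerMap
from redleaf.trait import GeneticArchitecture


@pytest.fixture(scope="session")
def arch() -> GeneticArchitecture:
    return GeneticArchitecture.default()


@pytest.fixture(scope="session")
def small_map(arch) -> MarkerMap:
    """Nine chromosomes, 12 background markers each plus the causal loci."""
    return MarkerMap.regular(arch, n_per_chrom=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
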