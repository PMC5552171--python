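import pytest

from tgmap.models import SyntheticGenomeSpec
from tgmap.synthetic import default_element, generate_genome


@pytest.fixture(scope="session")
def element():
    return default_element()


@pytest.fixture(scope="session")
def small_bundle(element):
    """2 x 300 kb genome with the default composition: fast enough for unit
    tests, large enough to have dozens of genes and a planted residual copy."""
    spec = SyntheticGenomeSpec(n_chromosomes=2, chromosome_length=300_000, seed=1)
    return generate_genome(spec, element)


@pytest.fixture(scope="session")
def toy_bundle():
    """Single 30 kb chromosome, no residual copy: brute-force oracle scale."""
    spec = SyntheticGenomeSpec(n_chromosomes=1, chromosome_length=30_000, seed=9)
    return generate_genome(spec, residual_length=0)
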