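import pytest

from cnvdx import make_design, make_genome_model
from cnvdx.io import load_hg18_region_cytobands


@pytest.fixture(scope="session")
def model():
    return make_genome_model(5, seed=7)


@pytest.fixture(scope="session")
def small_model():
    """One-chromosome 5 Mb genome for fast per-replicate simulations."""
    return make_genome_model(1, seed=7, min_length=5_000_000, max_length=5_000_001)


@pytest.fixture(scope="session")
def design_400k(model):
    return make_design(model, "400K", seed=1)


@pytest.fixture(scope="session")
def small_design(small_model):
    return make_design(small_model, "400K", seed=1)


@pytest.fixture(scope="session")
def hg18_bands():
    return load_hg18_region_cytobands()
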