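import numpy as np
import pytest

from quartetprio.synth import PlantSpec, make_toy_genes, simulate_quartet


@pytest.fixture(scope="session")
def toy_build():
    """One toy gene build shared across tests (genes + reference genome)."""
    return make_toy_genes(n_genes=24, seed=7)


@pytest.fixture(scope="session")
def toy_genes(toy_build):
    return toy_build[0]


@pytest.fixture(scope="session")
def toy_reference(toy_build):
    return toy_build[1]


@pytest.fixture(scope="session")
def apcl(toy_genes):
    return next(t for t in toy_genes if t.gene == "APCL")


@pytest.fixture(scope="session")
def wasl(toy_genes):
    return next(t for t in toy_genes if t.gene == "WASL")


@pytest.fixture(scope="session")
def quartet(toy_build):
    genes, reference = toy_build
    return simulate_quartet(PlantSpec(de_novo_singletons=2, ar_homozygous=2, seed=7), genes, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
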