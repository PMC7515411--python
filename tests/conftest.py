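import pytest

from infosimplex import synthetic


@pytest.fixture(scope="session")
def borromean():
    """Three pairwise-independent binary variables bound by an XOR constraint."""
    return synthetic.gen_borromean()


@pytest.fixture(scope="session")
def borromean_plus_noise():
    """The XOR triple tensored with one independent uniform bit (4 variables)."""
    return synthetic.block_product(
        [synthetic.gen_borromean(), synthetic.gen_independent(1)]
    )


@pytest.fixture(scope="session")
def independent3():
    return synthetic.gen_independent(3)


@pytest.fixture(scope="session")
def redundant3():
    return synthetic.gen_redundant(3)


@pytest.fixture
def dirichlet():
    """Factory for strictly positive seeded random joint laws."""

    def make(n=3, cardinality=2, seed=0, concentration=1.0):
        return synthetic.gen_random_dirichlet(n, cardinality, concentration, seed)

    return make
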