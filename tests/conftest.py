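import pytest

from cenpcscan import (
    blosum62_scheme,
    generate_proteome,
    load_fixture_motifs,
    synthetic_cupin_reference,
)


@pytest.fixture(scope="session")
def motifs():
    return load_fixture_motifs()


@pytest.fixture(scope="session")
def scheme():
    return blosum62_scheme()


@pytest.fixture(scope="session")
def cupin_reference():
    return synthetic_cupin_reference()


@pytest.fixture(scope="session")
def small_proteome():
    """60 synthetic proteins at substitution rate 0, with truth."""
    records, truth = generate_proteome(n=60, seed=20160120)
    return records, truth
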