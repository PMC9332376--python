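import pytest

from mitocompare import tapinoma_ibericum_annotation, tapinoma_ibericum_codon_counts
from mitocompare.simulate import SimSpec, simulate


@pytest.fixture(scope="session")
def ibericum():
    """Published coordinate-only annotation of accession ON746721."""
    return tapinoma_ibericum_annotation()


@pytest.fixture(scope="session")
def ibericum_counts():
    """Published per-codon counts over the 13 PCGs (DNA-keyed)."""
    return tapinoma_ibericum_codon_counts()


@pytest.fixture(scope="session")
def default_truth():
    """One default synthetic genome shared by read-only tests."""
    return simulate(SimSpec(seed=1))
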