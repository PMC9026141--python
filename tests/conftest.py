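import numpy as np
import pytest

from codonusage.codon_stats import CodonCountTable
from codonusage.synthetic import cpmmv_like_spec, generate_isolate_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_table():
    def _make(counts: dict[str, int]) -> CodonCountTable:
        return CodonCountTable(counts=counts)

    return _make


@pytest.fixture(scope="session")
def small_isolate_set():
    """A scaled-down virus-like isolate set shared across tests."""
    spec = cpmmv_like_spec(
        seed=11, n_isolates=9, n_codons=600, n_orfs=3, utr_length=60
    )
    return generate_isolate_set(spec)
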