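import numpy as np
import pytest

from rna_cosmos import SynthConfig, planted_dataset, score_matrix


@pytest.fixture(scope="session")
def planted():
    """Default 5-family x 6-member planted dataset, seed 0."""
    arrays, labels = planted_dataset(SynthConfig(seed=0))
    return arrays, labels


@pytest.fixture(scope="session")
def planted_matrix(planted):
    """Weighted k=10 all-vs-all score matrix of the planted dataset."""
    arrays, labels = planted
    ids, matrix, records = score_matrix(arrays, 10)
    return ids, matrix, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_kmer(rng, k, alphabet="HMXIBELR"):
    return "".join(rng.choice(list(alphabet), size=k))
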