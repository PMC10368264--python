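import numpy as np
import pytest

from rbcltrace.seqio import Lineage
from rbcltrace import synthetic_data


@pytest.fixture(scope="session")
def small_db():
    """8-species reference DB at 10% divergence, seeded."""
    return synthetic_data.make_reference_db(n_taxa=8, seq_length=230, divergence=0.10, seed=7)


@pytest.fixture(scope="session")
def decoys(small_db):
    return synthetic_data.make_host_decoy(n_seqs=2, length=1500, seed=8, db=small_db)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def lineage(*names):
    padded = list(names) + [None] * (4 - len(names))
    return Lineage(*padded)
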