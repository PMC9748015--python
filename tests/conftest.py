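import numpy as np
import pytest

from sticklat import default_contact_model
from sticklat.mc import LatticeConfiguration
from sticklat.sequences import encode_sequence, make_homopolymer_equivalent


@pytest.fixture(scope="session")
def model():
    return default_contact_model()


@pytest.fixture(scope="session")
def uniform_model():
    _, m = make_homopolymer_equivalent(2, -5.0)
    return m


def build_config(box, chains, sequences):
    """Helper: build a LatticeConfiguration from explicit chain
    coordinate lists and raw sequence strings (one per chain)."""
    seqs = [encode_sequence(s, id=f"c{i}") for i, s in enumerate(sequences)]
    positions = np.concatenate([np.asarray(c, dtype=np.int64) for c in chains])
    lens = np.array([len(c) for c in chains], dtype=np.int64)
    cfg = LatticeConfiguration(box, positions, lens, seqs)
    cfg.validate()
    return cfg


@pytest.fixture
def make_config():
    return build_config
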