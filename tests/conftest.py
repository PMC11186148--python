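import numpy as np
import pytest

from molenc import chem
from molenc.model import EncoderConfig
from molenc.tokenizer import build_vocab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """50 distinct random molecules, canonical spellings."""
    return chem.generate_corpus(50, rng_seed=11)


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return build_vocab(small_corpus)


@pytest.fixture
def tiny_encoder_config():
    return EncoderConfig(n_layers=1, n_heads=2, embed_dim=16, dropout=0.0,
                         max_positions=102, ffn_mult=2)
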