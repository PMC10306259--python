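"""Shared fixtures: toy corpora and session-scoped trained models.

Everything is generated programmatically and seeded; the expensive pieces
(the pretrained RNN prior, the briefly trained graph transformer) are built
once per session and shared across tests.
"""

import numpy as np
import pytest

from denovogen.corpus import build_graph_vocab, build_smiles_vocab
from denovogen.fixtures import FixtureSpec, make_corpus
from denovogen.generators import (GraphTransformerGenerator,
                                  GraphTransformerSpec, RnnGenerator,
                                  RnnGeneratorSpec, TrainConfig,
                                  encode_graph_dataset, encode_smiles_dataset,
                                  pretrain)
from denovogen.molprep import PrepConfig, enumerate_pairs, standardize

CORPUS_SEED = 3
CORPUS_SIZE = 300


@pytest.fixture(scope="session")
def toy_corpus():
    return make_corpus(FixtureSpec(n_molecules=CORPUS_SIZE, seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def smiles_vocab(toy_corpus):
    return build_smiles_vocab(toy_corpus)


@pytest.fixture(scope="session")
def toy_pairs(toy_corpus):
    cfg = PrepConfig(min_weight=0, max_fragments=3, subset_cap=4)
    pairs = []
    for s in toy_corpus[:40]:
        pairs.extend(enumerate_pairs(standardize(s), cfg))
    return pairs


@pytest.fixture(scope="session")
def graph_vocab(toy_corpus, toy_pairs):
    frags = sorted({f for p in toy_pairs for f in p.fragments})
    return build_graph_vocab(list(toy_corpus) + frags)


@pytest.fixture(scope="session")
def pretrained_prior(toy_corpus, smiles_vocab):
    """A small SMILES LSTM pretrained well enough to emit mostly-valid
    molecules; shared by the sampling, fine-tuning and RL tests."""
    data = encode_smiles_dataset(toy_corpus, smiles_vocab)
    gen = RnnGenerator(RnnGeneratorSpec(embedding_size=48, hidden_size=96),
                       smiles_vocab, seed=0)
    gen, _ = pretrain(gen, data, TrainConfig(
        epochs=60, batch_size=64, learning_rate=1e-2, patience=60, seed=0))
    return gen


@pytest.fixture(scope="session")
def trained_graph_generator(toy_pairs, graph_vocab):
    """Graph transformer briefly trained on fragment pairs (enough for the
    decode machinery to be exercised with realistic weights)."""
    data = encode_graph_dataset(toy_pairs[:80], graph_vocab)
    gen = GraphTransformerGenerator(
        GraphTransformerSpec(model_dim=48, ff_dim=96, dec_hidden=96),
        graph_vocab, seed=0)
    gen, _ = pretrain(gen, data, TrainConfig(
        epochs=2, batch_size=8, learning_rate=3e-3, patience=2, seed=0))
    return gen


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
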