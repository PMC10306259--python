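"""Pretrain a small SMILES LSTM and sample molecules from it.

Trains a 3-layer recurrent language model on 200 toy molecules (about two
minutes); the per-epoch test loss (mean negative log-likelihood per token)
should fall well below its first-epoch value, and a growing share of sampled
strings parse into valid molecules. (Run longer for higher validity.)
"""

from rdkit import Chem

from denovogen.corpus import build_smiles_vocab
from denovogen.fixtures import FixtureSpec, make_corpus
from denovogen.generators import (RnnGenerator, RnnGeneratorSpec, TrainConfig,
                                  encode_smiles_dataset, pretrain, sample)

corpus = make_corpus(FixtureSpec(n_molecules=200, seed=5))
vocab = build_smiles_vocab(corpus)
data = encode_smiles_dataset(corpus, vocab)

model = RnnGenerator(RnnGeneratorSpec(embedding_size=32, hidden_size=64),
                     vocab, seed=0)
model, log = pretrain(model, data, TrainConfig(
    epochs=40, batch_size=32, learning_rate=1e-2, patience=40, seed=0))
print(f"epoch  1: test loss {log[0]['test_loss']:.3f}")
print(f"epoch {len(log):2d}: test loss {log[-1]['test_loss']:.3f} "
      "(nats per token; lower = better next-token prediction)")

smis = sample(model, 50, seed=1)
valid = [s for s in smis if s and Chem.MolFromSmiles(s) is not None]
print(f"sampled 50 molecules, {len(valid)} valid; examples: {valid[:3]}")
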