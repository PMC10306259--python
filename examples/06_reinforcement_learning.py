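"""A small reinforcement-learning run against the toy environment.

Pretrains a compact SMILES LSTM (the frozen exploration prior), then
optimizes a copy of it by policy gradient for 15 epochs: each epoch samples
a batch from the agent/prior mixture (epsilon = 0.1), scores it with the
contains-nitrogen + 250-400 Da environment, and reinforces high-reward
sequences. The desired ratio at the selected best epoch should clearly beat
epoch 1. Takes a few minutes on one CPU.
"""

import copy

from denovogen.corpus import build_smiles_vocab
from denovogen.explorer import ExplorerConfig, rl_train
from denovogen.fixtures import FixtureSpec, make_corpus, make_env_toy
from denovogen.generators import (RnnGenerator, RnnGeneratorSpec, TrainConfig,
                                  encode_smiles_dataset, pretrain)

corpus = make_corpus(FixtureSpec(n_molecules=300, seed=3))
vocab = build_smiles_vocab(corpus)
prior = RnnGenerator(RnnGeneratorSpec(embedding_size=48, hidden_size=96),
                     vocab, seed=0)
print("pretraining the prior (about 2 minutes) ...")
prior, _ = pretrain(prior, encode_smiles_dataset(corpus, vocab), TrainConfig(
    epochs=60, batch_size=64, learning_rate=1e-2, patience=60, seed=0))

agent = copy.deepcopy(prior)
agent, log, syncs = rl_train(agent, prior, make_env_toy(), ExplorerConfig(
    epsilon=0.1, batch_size=64, epochs=15, learning_rate=2e-3, seed=0,
    sync_interval=10))

print(f"{'epoch':>5} {'valid':>6} {'unique':>7} {'desired':>8}")
for m in log:
    print(f"{m.epoch:>5} {m.valid_ratio:>6.2f} {m.unique_ratio:>7.2f} "
          f"{m.desired_ratio:>8.2f}")
print(f"\nauxiliary network refreshed after epochs: {syncs}")
print(f"desired ratio: epoch 1 = {log[0].desired_ratio:.2f}, "
      f"best epoch = {max(m.desired_ratio for m in log):.2f}")
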