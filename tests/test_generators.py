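"""Generator architectures, training contracts and sampling behavior."""

import logging
import math

import numpy as np
import pytest
from rdkit import Chem

from denovogen.corpus import build_smiles_vocab
from denovogen.fixtures import FixtureSpec, make_corpus
from denovogen.generators import (GraphTransformerGenerator,
                                  GraphTransformerSpec, RnnGenerator,
                                  RnnGeneratorSpec, SeqTransformerGenerator,
                                  SeqTransformerSpec, TrainConfig,
                                  check_vocab_covers, encode_pair_dataset,
                                  encode_smiles_dataset, finetune,
                                  load_checkpoint, nll_loss, pretrain, sample,
                                  save_checkpoint)


class TestNllLoss:
    def test_perfect_prediction_gives_zero_loss(self):
        dists = np.zeros((3, 5))
        targets = np.array([4, 1, 2])
        dists[np.arange(3), targets] = 1.0
        assert nll_loss(dists, targets) == pytest.approx(0.0)

    @pytest.mark.parametrize("V", [2, 7, 33])
    def test_uniform_model_gives_log_vocab_size(self, V):
        dists = np.full((4, V), 1.0 / V)
        targets = np.array([1, 1, 1, 1])
        assert nll_loss(dists, targets) == pytest.approx(math.log(V))

    def test_hand_computed_three_token_example(self):
        # -(ln .5 + ln .25 + ln .25) / 3 computed by hand
        dists = np.array([[0.5, 0.5], [0.75, 0.25], [0.75, 0.25]])
        targets = np.array([1, 1, 1])
        expected = -(math.log(0.5) + math.log(0.25) + math.log(0.25)) / 3
        assert nll_loss(dists, targets) == pytest.approx(expected)

    def test_padding_positions_are_excluded(self):
        dists = np.array([[0.5, 0.5, 0.0], [1 / 3, 1 / 3, 1 / 3]])
        targets = np.array([1, 0])          # second position is PAD
        assert nll_loss(dists, targets) == pytest.approx(math.log(2))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            nll_loss(np.ones((2, 3)), np.array([1, 2, 0]))


class TestSpecs:
    def test_rnn_default_has_three_recurrent_layers(self):
        assert RnnGeneratorSpec().n_recurrent_layers == 3

    def test_rnn_rejects_unknown_cell(self):
        with pytest.raises(ValueError):
            RnnGeneratorSpec(cell="ELMAN")

    def test_transformer_dim_must_divide_heads(self):
        with pytest.raises(ValueError):
            SeqTransformerSpec(model_dim=65, n_heads=4)
        with pytest.raises(ValueError):
            GraphTransformerSpec(model_dim=65, n_heads=4)


@pytest.fixture(scope="module")
def small_corpus():
    return make_corpus(FixtureSpec(n_molecules=200, seed=5))


@pytest.fixture(scope="module")
def small_vocab(small_corpus):
    return build_smiles_vocab(small_corpus)


@pytest.fixture(scope="module")
def small_data(small_corpus, small_vocab):
    return encode_smiles_dataset(small_corpus, small_vocab)


class TestPretraining:
    def test_loss_decreases_over_twenty_epochs(self, small_data, small_vocab):
        gen = RnnGenerator(RnnGeneratorSpec(embedding_size=32, hidden_size=48),
                           small_vocab, seed=1)
        gen, log = pretrain(gen, small_data, TrainConfig(
            epochs=20, batch_size=32, learning_rate=5e-3, patience=20,
            seed=1))
        best = min(r["test_loss"] for r in log)
        assert best < log[0]["test_loss"]

    @pytest.mark.parametrize("sched,patience,expected_epochs", [
        ([3.0, 2.0, 2.0, 1.9, 1.8], 0, 3),   # stop right at non-improvement
        ([3.0, 2.0, 2.0, 2.0, 1.0], 1, 4),   # one grace epoch
        ([3.0, 2.5, 2.0, 1.5, 1.0], 0, 5),   # monotone: runs to the end
    ])
    def test_patience_stops_after_configured_non_improving_epochs(
            self, sched, patience, expected_epochs):
        from denovogen.generators import fit
        from denovogen.tensor import Tensor

        class ScriptedModel:
            """Loss follows a fixed schedule; isolates stopping logic."""

            def __init__(self):
                self.calls = 0

            def parameters(self):
                return []

            def state_dict(self):
                return {}

            def load_state_dict(self, state):
                pass

            def loss_on_batch(self, batch):
                value = sched[min(self.calls // 2, len(sched) - 1)]
                self.calls += 1                 # one train + one test batch
                return Tensor(np.array(value))

        model = ScriptedModel()
        data = np.zeros((8, 3), dtype=np.int64)
        _, log = fit(model, data, TrainConfig(
            epochs=len(sched), batch_size=8, patience=patience, seed=0))
        assert len(log) == expected_epochs

    def test_same_seed_gives_identical_logs(self, small_data, small_vocab):
        logs = []
        for _ in range(2):
            gen = RnnGenerator(RnnGeneratorSpec(embedding_size=16,
                                                hidden_size=24),
                               small_vocab, seed=3)
            _, log = pretrain(gen, small_data, TrainConfig(
                epochs=3, batch_size=64, learning_rate=5e-3, patience=3,
                seed=3))
            logs.append(log)
        assert logs[0] == logs[1]

    def test_empty_corpus_raises(self, small_vocab):
        gen = RnnGenerator(RnnGeneratorSpec(), small_vocab, seed=0)
        with pytest.raises(ValueError):
            pretrain(gen, np.zeros((0, 5), dtype=int), TrainConfig())

    def test_divergence_aborts_with_diagnostic(self, small_data, small_vocab):
        gen = RnnGenerator(RnnGeneratorSpec(embedding_size=16, hidden_size=16),
                           small_vocab, seed=4)
        gen.embed.W.data[:] = np.nan
        with pytest.raises(FloatingPointError):
            pretrain(gen, small_data, TrainConfig(epochs=1, patience=1,
                                                  seed=4))


class TestFinetune:
    def test_zero_epochs_returns_weights_unchanged(self, pretrained_prior,
                                                   small_data):
        before = {k: v.copy() for k, v
                  in pretrained_prior.state_dict().items()}
        gen, log = finetune(pretrained_prior, small_data,
                            TrainConfig(epochs=0, patience=0))
        assert log == []
        after = gen.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_empty_corpus_raises(self, pretrained_prior):
        with pytest.raises(ValueError):
            finetune(pretrained_prior, np.zeros((0, 4), dtype=int),
                     TrainConfig(epochs=1, patience=1))

    def test_vocabulary_mismatch_lists_missing_tokens(self, pretrained_prior):
        with pytest.raises(ValueError, match="Br"):
            check_vocab_covers(pretrained_prior, ["CBr"])

    def test_nitrogen_rich_finetuning_shifts_samples(self, pretrained_prior,
                                                     toy_corpus):
        import copy
        biased = make_corpus(FixtureSpec(n_molecules=200, seed=21,
                                         nitrogen_bias=3.0))
        check_vocab_covers(pretrained_prior, biased)
        data = encode_smiles_dataset(biased, pretrained_prior.vocab)
        tuned = copy.deepcopy(pretrained_prior)
        tuned, _ = finetune(tuned, data, TrainConfig(
            epochs=8, batch_size=64, learning_rate=5e-3, patience=8, seed=7))

        def n_fraction(gen):
            smis = sample(gen, 500, seed=99)
            hits = [s for s in smis
                    if s and Chem.MolFromSmiles(s) is not None
                    and any(a.GetSymbol() == "N" for a in
                            Chem.MolFromSmiles(s).GetAtoms())]
            return len(hits) / 500

        assert n_fraction(tuned) > n_fraction(pretrained_prior)


class TestSampling:
    def test_n_zero_returns_empty_list(self, pretrained_prior):
        assert sample(pretrained_prior, 0, seed=0) == []

    def test_rnn_ignores_inputs_with_warning(self, pretrained_prior, caplog):
        with caplog.at_level(logging.WARNING):
            out = sample(pretrained_prior, 3, inputs=[("C",)], seed=0)
        assert len(out) == 3
        assert any("ignores" in r.message for r in caplog.records)

    def test_same_seed_gives_identical_samples(self, pretrained_prior):
        assert sample(pretrained_prior, 20, seed=11) == \
            sample(pretrained_prior, 20, seed=11)

    def test_transformer_without_inputs_raises(self, small_vocab):
        gen = SeqTransformerGenerator(SeqTransformerSpec(model_dim=32,
                                                         ff_dim=32,
                                                         n_layers=1),
                                      small_vocab, seed=0)
        with pytest.raises(ValueError):
            sample(gen, 5, seed=0)

    def test_graph_transformer_sampling_is_always_valid(
            self, trained_graph_generator, toy_pairs):
        inputs = [p.fragments for p in toy_pairs[:10]]
        smis = sample(trained_graph_generator, 30, inputs=inputs, seed=2)
        assert len(smis) == 30
        assert all(Chem.MolFromSmiles(s) is not None for s in smis)

    def test_graph_transformer_incorporates_input_fragments(
            self, trained_graph_generator, toy_pairs):
        inputs = [toy_pairs[0].fragments]
        smis = sample(trained_graph_generator, 10, inputs=inputs, seed=3)
        for s in smis:
            mol = Chem.MolFromSmiles(s)
            assert all(mol.HasSubstructMatch(Chem.MolFromSmiles(f))
                       for f in inputs[0])


class TestSeqTransformer:
    def test_training_reduces_loss(self, toy_pairs, small_vocab):
        vocab = build_smiles_vocab(
            [p.molecule for p in toy_pairs]
            + [".".join(p.fragments) for p in toy_pairs])
        data = encode_pair_dataset(toy_pairs[:120], vocab)
        gen = SeqTransformerGenerator(
            SeqTransformerSpec(model_dim=32, ff_dim=64, n_layers=1,
                               max_len=data.shape[1] + 4), vocab, seed=0)
        gen, log = pretrain(gen, data, TrainConfig(
            epochs=3, batch_size=16, learning_rate=3e-3, patience=3, seed=0))
        assert log[-1]["train_loss"] < log[0]["train_loss"]


class TestCheckpoints:
    def test_round_trip_preserves_weights_and_samples(self, pretrained_prior,
                                                      tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(pretrained_prior, path)
        loaded = load_checkpoint(path)
        assert sample(loaded, 10, seed=4) == sample(pretrained_prior, 10,
                                                    seed=4)

    def test_vocabulary_hash_mismatch_refuses_to_load(self, pretrained_prior,
                                                      tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(pretrained_prior, path)
        other = build_smiles_vocab(["CBr"])
        with pytest.raises(ValueError, match="vocabulary"):
            load_checkpoint(path, expect_vocab=other)
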