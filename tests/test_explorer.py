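"""Reinforcement-learning loop: mixing, policy gradient, metrics, schedule."""

import copy

import numpy as np
import pandas as pd
import pytest

from denovogen import nn
from denovogen.corpus import build_smiles_vocab
from denovogen.environment import Identity, Objective, get_scorer, score_batch
from denovogen.explorer import (ExplorerConfig, compute_metrics, mixed_sample,
                                policy_gradient_update, rl_train)
from denovogen.fixtures import make_env_toy
from denovogen.generators import RnnGenerator, RnnGeneratorSpec


class StubGenerator:
    """Emits a fixed molecule; lets mixing statistics be tested exactly."""

    requires_inputs = False

    def __init__(self, smiles):
        self.smiles = smiles

    def sample_smiles(self, n, rng):
        return [self.smiles] * n, [[1, 5, 2]] * n


class TestMixedSample:
    def test_epsilon_zero_draws_only_from_agent(self, rng):
        smiles, _, prov = mixed_sample(StubGenerator("CC"), StubGenerator("NN"),
                                       0.0, 50, rng)
        assert set(prov) == {"agent"} and set(smiles) == {"CC"}

    def test_epsilon_one_draws_only_from_prior(self, rng):
        smiles, _, prov = mixed_sample(StubGenerator("CC"), StubGenerator("NN"),
                                       1.0, 50, rng)
        assert set(prov) == {"prior"} and set(smiles) == {"NN"}

    def test_half_mixing_fraction_within_three_sigma(self, rng):
        n = 10_000
        _, _, prov = mixed_sample(StubGenerator("CC"), StubGenerator("NN"),
                                  0.5, n, rng)
        frac = prov.count("prior") / n
        sigma = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) < 3 * sigma

    def test_auxiliary_network_takes_half_the_agent_share(self, rng):
        _, _, prov = mixed_sample(StubGenerator("CC"), StubGenerator("NN"),
                                  0.0, 40, rng, aux=StubGenerator("OO"))
        assert prov.count("aux") == 20 and prov.count("agent") == 20


@pytest.fixture(scope="module")
def tiny_rnn():
    vocab = build_smiles_vocab(["CCO", "CCN", "CCC"])
    return RnnGenerator(RnnGeneratorSpec(embedding_size=8, hidden_size=12),
                        vocab, seed=0)


class TestPolicyGradient:
    def test_zero_rewards_leave_parameters_unchanged(self, tiny_rnn):
        agent = copy.deepcopy(tiny_rnn)
        before = agent.state_dict()
        opt = nn.Adam(agent.parameters(), lr=0.1)
        codes = [[1, 5, 4, 2], [1, 4, 4, 2]]
        policy_gradient_update(agent, codes, np.zeros(2), opt)
        after = agent.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_single_reward_one_loss_equals_sequence_nll(self, tiny_rnn):
        codes = [[1, 5, 4, 2]]
        opt = nn.Adam([], lr=0.0)
        loss = policy_gradient_update(copy.deepcopy(tiny_rnn), codes,
                                      np.array([1.0]), opt)
        nll = -copy.deepcopy(tiny_rnn).sequence_log_prob(
            np.array(codes)).item()
        assert loss == pytest.approx(nll)

    def test_doubling_rewards_doubles_the_loss(self, tiny_rnn):
        codes = [[1, 5, 4, 2], [1, 4, 5, 2]]
        opt = nn.Adam([], lr=0.0)
        l1 = policy_gradient_update(copy.deepcopy(tiny_rnn), codes,
                                    np.array([0.3, 0.4]), opt)
        l2 = policy_gradient_update(copy.deepcopy(tiny_rnn), codes,
                                    np.array([0.6, 0.8]), opt)
        assert l2 == pytest.approx(2 * l1)

    def test_reward_count_mismatch_raises(self, tiny_rnn):
        with pytest.raises(ValueError):
            policy_gradient_update(tiny_rnn, [[1, 2]], np.array([1.0, 2.0]),
                                   nn.Adam([], lr=0.0))


class TestMetrics:
    def _table(self, smiles):
        return score_batch(smiles, [
            Objective(get_scorer("contains_nitrogen"), Identity(), 0.5)])

    def test_copies_of_one_molecule_give_unique_ratio_one_over_n(self):
        smiles = ["CCO"] * 5
        m = compute_metrics(1, smiles, self._table(smiles))
        assert m.unique_ratio == pytest.approx(1 / 5)
        assert m.valid_ratio == 1.0

    def test_all_invalid_batch_zeroes_everything(self):
        smiles = ["xxx", "yyy"]
        m = compute_metrics(1, smiles, self._table(smiles))
        assert m.valid_ratio == 0.0
        assert m.mean_arithmetic == 0.0 and m.mean_geometric == 0.0

    def test_half_desired_batch(self):
        smiles = ["CCN", "CN", "CCO", "CCC"]
        m = compute_metrics(1, smiles, self._table(smiles))
        assert m.desired_ratio == pytest.approx(0.5)

    def test_geometric_never_exceeds_arithmetic(self, rng):
        for _ in range(20):
            smiles = [s for s in ["CCN", "CCO", "CN", "CCC", "xxx"]
                      if rng.random() < 0.8]
            if not smiles:
                continue
            m = compute_metrics(1, smiles, self._table(smiles))
            assert m.mean_geometric <= m.mean_arithmetic + 1e-12

    def test_accuracy_counts_fragment_incorporation(self):
        smiles = ["CC(=O)Nc1ccc(O)cc1", "CCO"]
        m = compute_metrics(1, smiles, self._table(smiles),
                            fragment_inputs=[("N",), ("N",)])
        assert m.accurate_ratio == pytest.approx(0.5)


class TestRlTrain:
    def test_zero_epochs_returns_agent_unchanged(self, tiny_rnn):
        agent = copy.deepcopy(tiny_rnn)
        before = agent.state_dict()
        out, log, syncs = rl_train(agent, copy.deepcopy(tiny_rnn),
                                   make_env_toy(),
                                   ExplorerConfig(epochs=0, batch_size=4))
        assert log == [] and syncs == []
        after = out.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_sync_interval_refreshes_at_declared_epochs(self, tiny_rnn):
        agent = copy.deepcopy(tiny_rnn)
        _, log, syncs = rl_train(
            agent, copy.deepcopy(tiny_rnn), make_env_toy(),
            ExplorerConfig(epochs=12, batch_size=4, sync_interval=5,
                           use_periodic_agent=True, learning_rate=1e-3,
                           seed=0))
        assert syncs == [5, 10]

    def test_epsilon_one_zero_lr_keeps_agent_bit_identical(self, tiny_rnn):
        agent = copy.deepcopy(tiny_rnn)
        before = {k: v.copy() for k, v in agent.state_dict().items()}
        agent, _, _ = rl_train(
            agent, copy.deepcopy(tiny_rnn), make_env_toy(),
            ExplorerConfig(epsilon=1.0, epochs=3, batch_size=4,
                           learning_rate=0.0, seed=1))
        after = agent.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_vocabulary_mismatch_rejected(self, tiny_rnn):
        other = RnnGenerator(RnnGeneratorSpec(embedding_size=8,
                                              hidden_size=12),
                             build_smiles_vocab(["CBr"]), seed=0)
        with pytest.raises(ValueError):
            rl_train(copy.deepcopy(tiny_rnn), other, make_env_toy(),
                     ExplorerConfig(epochs=1, batch_size=2))

    def test_logged_metrics_match_saved_molecule_tsv(self, tiny_rnn,
                                                     tmp_path):
        agent = copy.deepcopy(tiny_rnn)
        env = make_env_toy()
        _, log, _ = rl_train(agent, copy.deepcopy(tiny_rnn), env,
                             ExplorerConfig(epochs=2, batch_size=8, seed=2),
                             out_dir=tmp_path)
        saved = pd.read_csv(tmp_path / "molecules_epoch_0001.tsv", sep="\t")
        table = env.score(saved["SMILES"].fillna("").tolist())
        recomputed = compute_metrics(1, saved["SMILES"].fillna("").tolist(),
                                     table)
        assert recomputed.valid_ratio == pytest.approx(log[0].valid_ratio)
        assert recomputed.desired_ratio == pytest.approx(log[0].desired_ratio)
        assert (tmp_path / "rl_log.tsv").exists()
        assert (tmp_path / "rl_run.json").exists()

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            ExplorerConfig(epsilon=1.5)
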