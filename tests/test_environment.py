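"""Objectives, desirability modifiers and batch scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denovogen.environment import (ClippedScore, Environment, Gaussian,
                                   Identity, Objective, SmoothHump,
                                   clipped_score, gaussian_modifier,
                                   get_scorer, register_scorer, score_batch,
                                   smooth_hump)


class TestClippedScore:
    def test_reaches_one_at_high(self):
        assert clipped_score(5.0, 0.0, 5.0) == 1.0
        assert clipped_score(9.0, 0.0, 5.0) == 1.0

    def test_midpoint_is_half(self):
        assert clipped_score(2.5, 0.0, 5.0) == pytest.approx(0.5)

    def test_reversed_bounds_flip_direction(self):
        assert clipped_score(1.5, 2.0, 1.0) == pytest.approx(0.5)
        assert clipped_score(2.5, 2.0, 1.0) == 0.0

    def test_equal_bounds_raise(self):
        with pytest.raises(ValueError):
            clipped_score(1.0, 3.0, 3.0)

    @given(st.floats(-1e6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_output_in_unit_interval(self, x):
        assert 0.0 <= clipped_score(x, -10.0, 10.0) <= 1.0

    def test_monotone_on_grid(self):
        grid = np.linspace(-50, 50, 10_000)
        y = clipped_score(grid, -10.0, 10.0)
        assert (np.diff(y) >= 0).all()
        y_rev = clipped_score(grid, 10.0, -10.0)
        assert (np.diff(y_rev) <= 0).all()


class TestGaussian:
    def test_peak_at_center(self):
        assert gaussian_modifier(3.0, 3.0, 1.0) == 1.0

    def test_one_sigma_value(self):
        assert gaussian_modifier(4.0, 3.0, 1.0) == \
            pytest.approx(math.exp(-0.5))

    def test_monotone_decreasing_in_distance(self):
        d = np.abs(np.linspace(-5, 5, 1001) - 0.3)
        y = gaussian_modifier(np.linspace(-5, 5, 1001), 0.3, 2.0)
        order = np.argsort(d)
        assert (np.diff(y[order]) <= 1e-12).all()

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            gaussian_modifier(0.0, 0.0, 0.0)


class TestSmoothHump:
    def test_center_of_plateau_is_exactly_one(self):
        assert smooth_hump(325.0, 250.0, 400.0, 50.0) == \
            pytest.approx(1.0, abs=1e-6)

    def test_decays_to_zero_far_away(self):
        assert smooth_hump(-1e4, 250.0, 400.0, 50.0) < 1e-6
        assert smooth_hump(1e4, 250.0, 400.0, 50.0) < 1e-6

    def test_symmetric_about_the_plateau(self):
        for delta in (5.0, 40.0, 120.0):
            assert smooth_hump(250.0 - delta, 250.0, 400.0, 50.0) == \
                pytest.approx(smooth_hump(400.0 + delta, 250.0, 400.0, 50.0))

    def test_nonpositive_width_raises(self):
        with pytest.raises(ValueError):
            smooth_hump(300.0, 250.0, 400.0, 0.0)


@pytest.mark.parametrize("modifier", [
    ClippedScore(low=-3.0, high=7.0),
    ClippedScore(low=7.0, high=-3.0),
    Gaussian(center=2.0, sigma=3.0),
    SmoothHump(lower=250.0, upper=400.0, width=50.0),
])
def test_modifier_outputs_stay_in_unit_interval_on_dense_grid(modifier):
    grid = np.linspace(-1000.0, 2000.0, 10_000)
    y = np.asarray(modifier(grid))
    assert (y >= 0.0).all() and (y <= 1.0).all()


class TestScorers:
    def test_mol_weight_of_methane(self):
        mw = get_scorer("mol_weight").compute(["C"])[0]
        assert mw == pytest.approx(16.04, abs=0.01)

    def test_tanimoto_self_similarity_is_one(self):
        sc = get_scorer("tanimoto_similarity", reference="CC(=O)Nc1ccc(O)cc1")
        assert sc.compute(["CC(=O)Nc1ccc(O)cc1"])[0] == pytest.approx(1.0)

    def test_ligand_efficiency_zero_affinity_is_zero(self):
        sc = get_scorer("ligand_efficiency", affinity=0.0)
        assert sc.compute(["CCO"])[0] == 0.0

    def test_invalid_smiles_scores_missing(self):
        out = get_scorer("mol_weight").compute(["CCO", "xxx"])
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_plugin_scorer_registration(self):
        register_scorer("ring_count",
                        lambda m: float(m.GetRingInfo().NumRings()))
        sc = get_scorer("ring_count")
        assert sc.compute(["c1ccccc1"])[0] == 1.0

    def test_unknown_scorer_raises(self):
        with pytest.raises(KeyError):
            get_scorer("does_not_exist")

    def test_sa_proxy_in_unit_interval(self, toy_corpus):
        vals = get_scorer("sa_score_proxy").compute(toy_corpus[:30])
        assert ((vals >= 0) & (vals <= 1)).all()


class TestScoreBatch:
    def _objectives(self):
        return [
            Objective(get_scorer("mol_weight"),
                      SmoothHump(lower=250, upper=400, width=50), 0.5),
            Objective(get_scorer("contains_nitrogen"), Identity(), 0.5),
        ]

    def test_all_above_thresholds_is_desired(self):
        table = score_batch(["c1ccc(cc1)C(=O)Nc1ccc(CCOC2CCCCC2)cc1"],
                            self._objectives())
        assert table.desired[0]

    def test_one_below_threshold_is_not_desired(self):
        # right weight, no nitrogen
        table = score_batch(["c1ccc(cc1)C(=O)Oc1ccc(CCOC2CCCCC2)cc1"],
                            self._objectives())
        assert not table.desired[0]

    def test_invalid_smiles_gets_zero_modified_and_not_desired(self):
        table = score_batch(["xxx"], self._objectives())
        assert not table.valid[0]
        assert not table.desired[0]
        assert (table.modified[0] == 0).all()

    def test_raising_scorer_skips_column_and_continues(self):
        def broken(mol):
            raise RuntimeError("boom")

        objectives = self._objectives()
        objectives.append(Objective(
            type(objectives[0].scorer)("broken", broken), Identity(), 0.5))
        table = score_batch(["CCO"], objectives)
        assert np.isnan(table.raw[0, 2])
        assert table.valid[0]

    def test_empty_objectives_raise(self):
        with pytest.raises(ValueError):
            score_batch(["CCO"], [])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_desired_equals_explicit_conjunction(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 12, 3
        modified = rng.random((n, k))
        thresholds = rng.random(k)
        desired = (modified >= thresholds).all(axis=1)
        explicit = np.array([all(modified[i, j] >= thresholds[j]
                                 for j in range(k)) for i in range(n)])
        assert (desired == explicit).all()

    def test_threshold_tie_counts_as_desired(self):
        table = score_batch(["CN"], [Objective(
            get_scorer("contains_nitrogen"), Identity(), 1.0)])
        assert table.desired[0]


class TestEnvironmentConfig:
    def test_yaml_round_trip(self, tmp_path):
        env = Environment(objectives=[
            Objective(get_scorer("mol_weight"),
                      Gaussian(center=300.0, sigma=50.0), 0.4),
            Objective(get_scorer("tanimoto_similarity", reference="CCO"),
                      ClippedScore(low=0.0, high=0.8), 0.6),
        ], scheme="PRCD")
        path = tmp_path / "env.yml"
        env.save(path)
        loaded = Environment.load(path)
        assert loaded.to_config() == env.to_config()

    def test_json_round_trip(self, tmp_path):
        env = Environment(objectives=[
            Objective(get_scorer("constant", value=0.7), Identity(), 0.5)])
        path = tmp_path / "env.json"
        env.save(path)
        assert Environment.load(path).to_config() == env.to_config()

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            Environment(objectives=[], scheme="MAGIC")
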