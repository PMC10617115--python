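"""Importance ranking, candidate evaluation, and the selection loop."""

import numpy as np
import pytest

from rbfs import (
    EnsembleConfig,
    SelectionConfig,
    evaluate_candidate,
    fit_final_model,
    rank_features,
    reset_weights,
    select_features,
)
from conftest import make_signal_dataset


@pytest.fixture
def light_cfg(light_ensemble):
    def _cfg(seed=0, q=5, k=3, max_iterations=50):
        return SelectionConfig(
            q=q, k=k, seed=seed, max_iterations=max_iterations, ensemble=light_ensemble
        )

    return _cfg


class TestRankFeatures:
    def test_constant_column_scores_zero_and_ranks_last(self, light_ensemble):
        X, y = make_signal_dataset(n=120, p=5, seed=0)
        X[:, 3] = 7.0
        r = rank_features(X, y, seed=0, ensemble=light_ensemble)
        assert r.scores[3] == 0.0
        nonzero = np.nonzero(r.scores)[0]
        assert all(
            list(r.order).index(i) < list(r.order).index(3) for i in nonzero
        )

    def test_label_equal_feature_ranks_first(self, light_ensemble):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 200)
        X = rng.standard_normal((400, 51))
        X[:, 20] = y
        r = rank_features(X, y, seed=3, ensemble=light_ensemble)
        assert r.order[0] == 20

    def test_zero_score_ties_break_by_ascending_index(self, light_ensemble):
        X, y = make_signal_dataset(n=120, p=6, seed=2)
        X[:, 4] = 1.0
        X[:, 2] = 1.0  # two constant columns: tied zero scores
        r = rank_features(X, y, seed=0, ensemble=light_ensemble)
        assert list(r.order).index(2) < list(r.order).index(4)

    def test_weighted_and_unweighted_runs_are_deterministic(self, light_ensemble):
        X, y = make_signal_dataset(n=100, p=8, seed=3)
        w = reset_weights(100)
        a = rank_features(X, y, w, seed=5, ensemble=light_ensemble)
        b = rank_features(X, y, w, seed=5, ensemble=light_ensemble)
        np.testing.assert_array_equal(a.order, b.order)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_single_class_rejected(self, light_ensemble):
        with pytest.raises(ValueError, match="both classes"):
            rank_features(np.zeros((20, 2)), np.zeros(20), ensemble=light_ensemble)


class TestEvaluateCandidate:
    def test_label_equal_column_is_perfect(self, light_ensemble):
        y = np.array([0, 1] * 100)
        X = np.c_[y.astype(float), np.random.default_rng(0).standard_normal(200)]
        acc = evaluate_candidate(X, y, [0], k=5, seed=1, ensemble=light_ensemble)
        assert acc == 1.0

    def test_constant_column_predicts_majority_class(self, light_ensemble):
        rng = np.random.default_rng(4)
        y = np.array([1] * 120 + [0] * 80)
        X = np.ones((200, 1))
        acc = evaluate_candidate(X, y, [0], k=5, seed=2, ensemble=light_ensemble)
        assert acc == pytest.approx(0.6, abs=0.05)

    def test_determinism(self, light_ensemble):
        X, y = make_signal_dataset(n=100, p=4, seed=5)
        args = (X, y, [0, 2])
        a = evaluate_candidate(*args, k=4, seed=9, ensemble=light_ensemble)
        b = evaluate_candidate(*args, k=4, seed=9, ensemble=light_ensemble)
        assert a == b

    def test_invalid_column_rejected(self, light_ensemble):
        X, y = make_signal_dataset(n=60, p=3, seed=0)
        with pytest.raises(ValueError, match="invalid column"):
            evaluate_candidate(X, y, [5], ensemble=light_ensemble)

    def test_empty_subset_rejected(self, light_ensemble):
        X, y = make_signal_dataset(n=60, p=3, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_candidate(X, y, [], ensemble=light_ensemble)


class TestSelectFeatures:
    def test_single_perfect_feature_trace(self, perfect_feature_data, light_cfg):
        """Hand-derived trace: accept the only feature, phase-1 trigger with
        weight reset, phase-2 trigger, stop with m=1."""
        X, y = perfect_feature_data
        res = select_features(X, y, light_cfg(seed=1))
        assert res.selected == [0]
        events = [(r.phase, r.accepted, r.reason, r.reset) for r in res.history]
        assert events == [
            (1, 0, None, False),
            (1, None, "exhausted", True),
            (2, None, "exhausted", False),
        ]
        # snapshot immediately after the phase boundary is uniform 1/n
        reset_rec = res.history[1]
        np.testing.assert_allclose(reset_rec.weights, np.full(len(y), 1 / len(y)))

    def test_pure_noise_terminates_with_few_features(self, light_cfg):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 30))
        y = np.array([0, 1] * 40)
        res = select_features(X, y, light_cfg(seed=2, q=5))
        assert res.n_selected < 10  # m much smaller than p
        assert res.history[-1].reason in ("no_improvement", "exhausted")

    def test_accepted_accuracies_strictly_increase(self, light_cfg):
        X, y = make_signal_dataset(n=150, p=20, seed=7)
        res = select_features(X, y, light_cfg(seed=7))
        accs = res.accepted_accuracies()
        assert all(b > a for a, b in zip(accs, accs[1:]))

    def test_no_duplicate_selections_and_halting(self, light_cfg):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 12))
            y = rng.integers(0, 2, 60)
            y[:2] = [0, 1]
            res = select_features(X, y, light_cfg(seed=seed, q=4, k=3))
            assert len(res.selected) == len(set(res.selected))
            assert len(res.history) <= 50

    def test_weight_snapshots_are_valid_distributions(self, light_cfg):
        X, y = make_signal_dataset(n=100, p=15, seed=8)
        res = select_features(X, y, light_cfg(seed=8))
        for rec in res.history:
            assert rec.weights is not None
            assert (rec.weights >= 0).all()
            assert rec.weights.sum() == pytest.approx(1.0, abs=1e-9)
            if rec.reset:
                np.testing.assert_allclose(rec.weights, np.full(len(y), 1 / len(y)))

    def test_determinism_of_full_run(self, light_cfg):
        X, y = make_signal_dataset(n=100, p=10, seed=9)
        a = select_features(X, y, light_cfg(seed=4))
        b = select_features(X, y, light_cfg(seed=4))
        assert a.selected == b.selected
        assert a.to_json() == b.to_json()

    def test_planted_feature_recovered(self, light_cfg):
        X, y = make_signal_dataset(n=200, p=25, seed=10, coef=4.0)
        res = select_features(X, y, light_cfg(seed=10))
        assert 0 in res.selected

    def test_invalid_max_iterations_rejected(self, perfect_feature_data, light_cfg):
        X, y = perfect_feature_data
        cfg = light_cfg(max_iterations=0)
        with pytest.raises(ValueError, match="max_iterations"):
            select_features(X, y, cfg)


class TestFitFinalModel:
    def test_probability_rows_sum_to_one(self, light_ensemble):
        X, y = make_signal_dataset(n=80, p=5, seed=1)
        _, probs = fit_final_model(X, y, [0, 1], seed=0, ensemble=light_ensemble)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_refit_same_seed_identical_predictions(self, light_ensemble):
        X, y = make_signal_dataset(n=80, p=5, seed=2)
        _, p1 = fit_final_model(X, y, [0, 3], seed=6, ensemble=light_ensemble)
        _, p2 = fit_final_model(X, y, [0, 3], seed=6, ensemble=light_ensemble)
        np.testing.assert_array_equal(p1, p2)

    def test_label_equal_column_fits_training_labels(self, light_ensemble):
        y = np.array([0, 1] * 40)
        X = y[:, None].astype(float)
        model, probs = fit_final_model(X, y, [0], seed=0, ensemble=light_ensemble)
        assert (probs.argmax(axis=1) == y).all()

    def test_empty_selection_rejected(self, light_ensemble):
        X, y = make_signal_dataset(n=60, p=3, seed=0)
        with pytest.raises(ValueError, match="empty"):
            fit_final_model(X, y, [], ensemble=light_ensemble)
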