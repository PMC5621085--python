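"""Adaptation strategies: selection rules, transduction, retraining loop."""

import numpy as np
import pytest

from lmradapt.adaptation import (
    AdaptationState,
    eba_select,
    lift_select,
    retrain,
    run_adaptive_session,
    tsvm_adapt,
    tsvm_multiclass,
)
from lmradapt.bank import classify_stream
from tests.conftest import make_toy_phase_set


class TestEbaSelect:
    def test_strictly_below_threshold(self, tiny_bank, tiny_features):
        _, test_feats = tiny_features
        fs = test_feats[0]
        stream = classify_stream(tiny_bank, fs.X, fs.phase, fs.true_mode)
        idx, labels = eba_select(stream, 0.6)
        expected = {i for i, e in enumerate(stream.entropy) if e < 0.6}
        assert set(idx) == expected
        assert np.array_equal(labels, stream.raw_label[idx])

    def test_boundary_value_excluded(self):
        class FakeStream:
            entropy = np.array([0.3, 0.59, 0.6, 1.2])
            raw_label = np.array([0, 1, 2, 3])

        idx, labels = eba_select(FakeStream(), 0.6)
        assert list(idx) == [0, 1]
        assert list(labels) == [0, 1]

    def test_zero_threshold_selects_nothing(self):
        class FakeStream:
            entropy = np.array([0.0, 0.1])
            raw_label = np.array([0, 1])

        idx, _ = eba_select(FakeStream(), 0.0)
        assert idx.size == 0

    def test_perfectly_confident_decisions_all_selected(self):
        class FakeStream:
            entropy = np.zeros(4)
            raw_label = np.array([0, 1, 2, 3])

        idx, _ = eba_select(FakeStream(), 0.6)
        assert list(idx) == [0, 1, 2, 3]


class TestLiftSelect:
    @pytest.mark.parametrize(
        "row,selected,label",
        [
            ([1, 0, 0, 0, 0], True, 0),
            ([0, 0, 0, 1, 0], True, 3),
            ([1, 1, 0, 0, 0], False, None),
            ([0, 0, 0, 0, 0], False, None),
            ([1, 1, 1, 1, 1], False, None),
        ],
    )
    def test_unanimity_rule(self, row, selected, label):
        idx, labels = lift_select(np.array([row]))
        assert (idx.size == 1) == selected
        if selected:
            assert labels[0] == label

    def test_malformed_vector_rejected(self):
        with pytest.raises(ValueError):
            lift_select(np.array([[1, 0, 0]]))
        with pytest.raises(ValueError):
            lift_select(np.array([[2, 0, 0, 0, 0]]))

    def test_exhaustive_equivalence_on_real_decisions(self, tiny_bank, tiny_features):
        _, test_feats = tiny_features
        fs = test_feats[0]
        stream = classify_stream(tiny_bank, fs.X, fs.phase, fs.true_mode)
        idx, labels = lift_select(stream.binary_pos.astype(int))
        for i in range(len(stream)):
            claims = stream.binary_pos[i].sum()
            assert (i in idx) == (claims == 1)
        assert np.array_equal(labels, stream.binary_pos[idx].argmax(axis=1))


class TestTsvmAdapt:
    def test_empty_unlabeled_is_plain_fit(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array([-1] * 20 + [1] * 20)
        clf, labels, info = tsvm_adapt(X, y, np.empty((0, 2)))
        assert labels.size == 0
        assert info["n_iterations"] == 0
        ref = tsvm_adapt(X, y, np.empty((0, 2)))[0]
        assert np.array_equal(clf.dual_coef_, ref.dual_coef_)

    def test_one_class_labeled_set_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            tsvm_adapt(X, np.ones(10, dtype=int), X)

    def test_batch_rule_bounds_moves_and_iterations(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-1, 1, (30, 2)), rng.normal(1, 1, (30, 2))])
        y = np.array([-1] * 30 + [1] * 30)
        U = rng.normal(0, 1.5, (20, 2))
        _, labels, info = tsvm_adapt(X, y, U, m=5)
        assert np.isin(labels, (-1, 1)).all()
        assert all(c <= 10 for c in info["moved_per_iteration"])
        assert info["n_iterations"] <= 20

    def test_two_cluster_bridge_geometry(self):
        """Bridge points between well-separated clusters take the sign of
        their x-coordinate."""
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 0.2, (25, 2)), rng.normal(3, 0.2, (25, 2))])
        X[:, 1] = rng.normal(0, 0.5, 50)
        y = np.array([-1] * 25 + [1] * 25)
        U = np.array([[x, 0.0] for x in (-1.5, -0.5, 0.5, 1.5)])
        _, labels, _ = tsvm_adapt(X, y, U, C=10.0, gamma=0.1, m=2)
        assert np.array_equal(labels, np.sign(U[:, 0]).astype(int))

    def test_contract_on_random_problems(self):
        """Termination, exactly-once labeling and the 2m move bound hold on
        random binary problems of mixed difficulty."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_lab = int(rng.integers(10, 60))
            n_unlab = int(rng.integers(0, 120))
            sep = rng.uniform(0.3, 3.0)
            X = np.vstack(
                [rng.normal(-sep, 1, (n_lab, 3)), rng.normal(sep, 1, (n_lab, 3))]
            )
            y = np.array([-1] * n_lab + [1] * n_lab)
            U = rng.normal(0, sep + 1, (n_unlab, 3))
            m = int(rng.integers(1, 8))
            _, labels, info = tsvm_adapt(X, y, U, m=m, max_iter=200)
            assert labels.shape == (n_unlab,)
            assert np.isin(labels, (-1, 1)).all() or n_unlab == 0
            assert all(c <= 2 * m for c in info["moved_per_iteration"])
            assert not info["max_iter_exhausted"]


class TestTsvmMulticlass:
    def test_no_unlabeled_data_leaves_bank_unchanged(self, toy_bank):
        bank, (X, phase, y) = toy_bank
        out, labels, _ = tsvm_multiclass(
            bank, X, phase, y, np.empty((0, X.shape[1])), np.empty(0, dtype=int)
        )
        assert out is bank
        assert labels.size == 0

    def test_easy_regime_matches_plain_classification(self, toy_bank):
        bank, (X, phase, y) = toy_bank
        Xu, pu, yu = make_toy_phase_set(n_per_cell=3, seed=9)
        out, labels, info = tsvm_multiclass(bank, X, phase, y, Xu, pu, m=5)
        plain = classify_stream(bank, Xu, pu, vote_len=1)
        assert np.array_equal(labels, plain.raw_label)
        assert np.array_equal(labels, yu)
        for per_phase in info.values():
            for d in per_phase.values():
                assert d["n_iterations"] >= 0
                assert not d["max_iter_exhausted"]


class TestRetrainLoop:
    def test_empty_augmented_set_is_noop(self, toy_bank):
        bank, (X, phase, y) = toy_bank
        state = AdaptationState(X, phase, y, strategy="eba")
        assert retrain(bank, state) is bank

    def test_duplicating_base_data_does_not_hurt(self, toy_bank):
        bank, (X, phase, y) = toy_bank
        state = AdaptationState(X, phase, y, strategy="eba", retrain_seed=1)
        state.add(1, X, phase, y)
        new = retrain(bank, state)
        probe = classify_stream(new, X, phase, vote_len=1)
        assert (probe.raw_label == y).mean() == 1.0

    def test_retrain_deterministic(self, toy_bank):
        bank, (X, phase, y) = toy_bank
        state = AdaptationState(X, phase, y, strategy="eba", retrain_seed=7)
        state.add(1, X[:50], phase[:50], y[:50])
        a = retrain(bank, state)
        b = retrain(bank, state)
        assert a.fingerprint == b.fingerprint
        pa = classify_stream(a, X[:30], phase[:30], vote_len=1)
        pb = classify_stream(b, X[:30], phase[:30], vote_len=1)
        assert np.array_equal(pa.posterior, pb.posterior)

    def test_unknown_phase_in_augmented_rejected(self, toy_bank):
        _, (X, phase, y) = toy_bank
        state = AdaptationState(X, phase, y, strategy="eba")
        with pytest.raises(ValueError, match="phase"):
            state.add(1, X[:2], np.array([0, 9]), y[:2])

    def test_fifo_cap_evicts_oldest(self, toy_bank):
        _, (X, phase, y) = toy_bank
        state = AdaptationState(X, phase, y, strategy="eba", max_augmented=60)
        state.add(1, X[:50], phase[:50], y[:50])
        state.add(2, X[:50], phase[:50], y[:50])
        assert state.n_augmented == 60
        trials = np.concatenate(state.aug_trial)
        assert (trials == 1).sum() == 10 and (trials == 2).sum() == 50


class TestAdaptiveSession:
    def test_unknown_strategy_rejected(self, tiny_bank, tiny_features):
        (X, phase, y), test_feats = tiny_features
        with pytest.raises(ValueError):
            run_adaptive_session("bogus", tiny_bank, (X, phase, y), test_feats)

    def test_none_strategy_equals_static_bank(self, tiny_bank, tiny_features):
        (X, phase, y), test_feats = tiny_features
        streams, state = run_adaptive_session(
            "none", tiny_bank, (X, phase, y), test_feats
        )
        for fs, stream in zip(test_feats, streams):
            direct = classify_stream(tiny_bank, fs.X, fs.phase, fs.true_mode,
                                     fs.last_sample)
            assert np.array_equal(stream.voted_label, direct.voted_label)
        assert state.n_augmented == 0

    def test_eba_with_zero_threshold_matches_none(self, tiny_bank, tiny_features):
        (X, phase, y), test_feats = tiny_features
        none_streams, _ = run_adaptive_session(
            "none", tiny_bank, (X, phase, y), test_feats
        )
        eba_streams, state = run_adaptive_session(
            "eba", tiny_bank, (X, phase, y), test_feats, tau=0.0
        )
        for a, b in zip(none_streams, eba_streams):
            assert np.array_equal(a.voted_label, b.voted_label)
        assert state.n_augmented == 0

    def test_history_records_selection_counts(self, tiny_bank, tiny_features):
        (X, phase, y), test_feats = tiny_features
        _, state = run_adaptive_session(
            "eba", tiny_bank, (X, phase, y), test_feats, tau=0.6
        )
        assert len(state.history) == len(test_feats)
        running = 0
        for h in state.history:
            running += h["n_selected"]
            assert h["n_augmented_total"] == running
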