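"""Classifier estimators, balanced batching, ensemble voting."""

import numpy as np
import pytest

from preictal.models import (
    DeepEEGClassifier,
    ShallowNetClassifier,
    VotingEnsemble,
    balanced_batches,
    majority_vote,
)


def separable_features(rng, n_per_class=150, n_features=20, gap=4.0):
    """Z-scored two-blob problem (the estimators expect normalised input)."""
    X0 = rng.standard_normal((n_per_class, n_features))
    X1 = rng.standard_normal((n_per_class, n_features))
    X1[:, :3] += gap
    X = np.vstack([X0, X1])
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestBalancedBatches:
    def test_imbalanced_input_gives_32_per_class(self, rng):
        X = np.arange(1100)[:, None].astype(float)
        y = np.array([0] * 1000 + [1] * 100)
        batches = balanced_batches(X, y, 64, np.random.default_rng(0))
        assert len(batches) == int(np.ceil(1000 / 32))
        for Xb, yb in batches:
            assert (yb == 0).sum() == 32
            assert (yb == 1).sum() == 32
        # minority samples recur across the epoch
        minority = np.concatenate([Xb[yb == 1, 0] for Xb, yb in batches])
        assert len(minority) > 100

    def test_divisible_balanced_input_has_no_replication(self):
        X = np.arange(256)[:, None].astype(float)
        y = np.array([0] * 128 + [1] * 128)
        batches = balanced_batches(X, y, 64, np.random.default_rng(0))
        seen = np.concatenate([Xb[:, 0] for Xb, _ in batches])
        assert len(seen) == 256
        assert len(np.unique(seen)) == 256

    def test_deterministic_given_seed(self):
        X = np.arange(300)[:, None].astype(float)
        y = (np.arange(300) % 3 == 0).astype(int)
        b1 = balanced_batches(X, y, 64, np.random.default_rng(5))
        b2 = balanced_batches(X, y, 64, np.random.default_rng(5))
        for (Xa, _), (Xb, _) in zip(b1, b2):
            assert np.array_equal(Xa, Xb)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_batches(np.zeros((10, 1)), np.zeros(10), 64,
                             np.random.default_rng(0))


class TestMajorityVote:
    def test_threshold_cases(self):
        votes16 = np.array([[1]] * 16 + [[0]] * 15)
        assert majority_vote(votes16)[0] == 1
        votes15 = np.array([[1]] * 15 + [[0]] * 16)
        assert majority_vote(votes15)[0] == 0

    def test_unanimous(self):
        assert majority_vote(np.ones((31, 4))).tolist() == [1, 1, 1, 1]

    def test_even_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote(np.ones((30, 2)))

    def test_member_order_invariance(self, rng):
        votes = (rng.random((31, 50)) > 0.5).astype(int)
        shuffled = votes[rng.permutation(31)]
        assert np.array_equal(majority_vote(votes), majority_vote(shuffled))


class TestShallowNet:
    def test_learns_separable_data(self, rng):
        X, y = separable_features(rng, n_per_class=400)
        clf = ShallowNetClassifier(max_epochs=300, random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.95
        assert clf.best_val_loss_ < 0.25
        proba = clf.predict_proba(X[:5])
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_shuffled_labels_stay_at_chance(self, rng):
        X, y = separable_features(rng)
        y_shuffled = rng.permutation(y)
        clf = ShallowNetClassifier(max_epochs=60, random_state=0)
        clf.fit(X, y_shuffled)
        assert clf.best_val_loss_ > np.log(2) - 0.15

    def test_early_stopping_restores_best(self, rng):
        X, y = separable_features(rng, n_per_class=60)
        clf = ShallowNetClassifier(max_epochs=120, patience=10,
                                   random_state=1)
        clf.fit(X, y)
        assert clf.best_val_loss_ == pytest.approx(min(clf.loss_history_))

    def test_patience_zero_stops_at_first_non_improvement(self, rng):
        X, y = separable_features(rng, n_per_class=60)
        # a large learning rate makes the validation loss oscillate, so a
        # non-improving epoch arrives quickly
        clf = ShallowNetClassifier(max_epochs=500, patience=0,
                                   learning_rate=0.05, random_state=1)
        clf.fit(X, y)
        hist = np.array(clf.loss_history_)
        assert len(hist) < 500
        # every epoch but the last improved on the running best; the final
        # epoch is the single allowed non-improvement
        best = np.inf
        for i, v in enumerate(hist[:-1]):
            assert v < best - 1e-9, f"non-improvement at epoch {i} not final"
            best = v
        assert hist[-1] >= best - 1e-9
        assert clf.best_val_loss_ == pytest.approx(best)

    def test_deterministic_given_seed(self, rng):
        X, y = separable_features(rng, n_per_class=40)
        p1 = ShallowNetClassifier(max_epochs=30, random_state=7).fit(
            X, y).predict(X)
        p2 = ShallowNetClassifier(max_epochs=30, random_state=7).fit(
            X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_hidden_layer_variant(self, rng):
        X, y = separable_features(rng, n_per_class=60)
        clf = ShallowNetClassifier(hidden_neurons=16, max_epochs=250,
                                   random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9


class TestDeepEEG:
    def test_learns_separable_time_series(self):
        """Class 1 carries a strong 6 Hz rhythm absent from class 0."""
        rng = np.random.default_rng(1234)
        fs, T, n = 32.0, 320, 50
        t = np.arange(T) / fs
        X0 = rng.standard_normal((n, 2, T))
        X1 = rng.standard_normal((n, 2, T)) + 2.5 * np.sin(
            2 * np.pi * 6 * t)
        X = np.concatenate([X0, X1]).astype(np.float32)
        y = np.array([0] * n + [1] * n)
        clf = DeepEEGClassifier.reduced(max_epochs=25, patience=8,
                                        random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_reduced_profile_keeps_topology(self):
        clf = DeepEEGClassifier.reduced()
        assert clf.n_blocks == 3
        assert clf.kernel_size == 3
        assert clf.filters_start < 128

    def test_full_profile_defaults(self):
        clf = DeepEEGClassifier()
        assert clf.filters_start == 128
        assert clf.lstm_units == 64
        assert clf.spatial_dropout == 0.5

    def test_2d_input_rejected(self, rng):
        clf = DeepEEGClassifier.reduced()
        with pytest.raises(ValueError, match="n_channels"):
            clf.fit(rng.standard_normal((10, 20)), np.arange(10) % 2)


class TestVotingEnsemble:
    def test_even_member_count_rejected(self, rng):
        X, y = separable_features(rng, n_per_class=30)
        ens = VotingEnsemble(ShallowNetClassifier(max_epochs=5),
                             n_members=4)
        with pytest.raises(ValueError, match="odd"):
            ens.fit(X, y)

    def test_reproducible_end_to_end(self, rng):
        X, y = separable_features(rng, n_per_class=40)
        mk = lambda: VotingEnsemble(  # noqa: E731
            ShallowNetClassifier(max_epochs=15), n_members=3, seed_base=2)
        p1 = mk().fit(X, y).predict(X)
        p2 = mk().fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_members_get_distinct_seeds(self, rng):
        X, y = separable_features(rng, n_per_class=40)
        ens = VotingEnsemble(ShallowNetClassifier(max_epochs=5),
                             n_members=3, seed_base=10).fit(X, y)
        assert [m.random_state for m in ens.members_] == [10, 11, 12]
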