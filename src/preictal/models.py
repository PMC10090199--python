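"""Seizure-prediction classifiers and the majority-vote ensemble.

Two scikit-learn style estimators:

* :class:`ShallowNetClassifier` — input dropout (50%) followed by a
  two-neuron fully connected softmax layer, fed with the 55-per-channel
  handcrafted feature vectors (optionally one hidden layer);
* :class:`DeepEEGClassifier` — a compact CNN-BiLSTM for raw 10-s windows:
  three convolutional blocks (two conv layers each, the second with stride
  2 as a learnable pooling layer, then spatial dropout, swish and batch
  norm), filters doubling from ``filters_start``, kernel size 3, a
  bidirectional LSTM of 64 units read at its final states, dropout, and a
  two-neuron softmax head.

Both are trained with balanced 64-sample batches (32 per class, minority
oversampled by replication), Adam at 3e-4, binary cross-entropy, up to 500
epochs with early-stopping patience 50 on a validation set, restoring the
best-validation-loss weights.  :class:`VotingEnsemble` trains an odd number
of members (31 in the full profile) with per-member seeds and fuses their
per-window hard labels by majority vote.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from . import _nn
from ._nn import softmax, swish  # re-exported  # noqa: F401
from .dataset import holdout_split

BATCH_SIZE = 64
LEARNING_RATE = 3e-4
MAX_EPOCHS = 500
PATIENCE = 50
N_RUNS = 31


def balanced_batches(
    X: np.ndarray,
    y: np.ndarray,
    batch_size: int = BATCH_SIZE,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One epoch of class-balanced batches (``batch_size // 2`` per class).

    The epoch holds ``ceil(n_majority / (batch_size // 2))`` batches; each
    class's samples are shuffled and cycled with replacement as needed, so
    the minority class recurs while a class whose size divides the slot
    count is seen exactly once per pass.
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("balanced batches need exactly 2 classes present")
    per_class = batch_size // 2
    idx_by_class = [np.where(y == c)[0] for c in classes]
    n_major = max(len(ix) for ix in idx_by_class)
    n_batches = math.ceil(n_major / per_class)
    slots = n_batches * per_class
    orders = []
    for ix in idx_by_class:
        reps = math.ceil(slots / len(ix))
        order = np.concatenate([rng.permutation(ix) for _ in range(reps)])
        orders.append(order[:slots])
    batches = []
    for b in range(n_batches):
        sel = np.concatenate(
            [o[b * per_class:(b + 1) * per_class] for o in orders]
        )
        batches.append((X[sel], y[sel]))
    return batches


def majority_vote(member_predictions: np.ndarray) -> np.ndarray:
    """Per-window class predicted by more than half of the members."""
    preds = np.asarray(member_predictions)
    if preds.ndim != 2:
        raise ValueError("expected (n_members, n_windows) predictions")
    if preds.shape[0] % 2 == 0:
        raise ValueError("member count must be odd to avoid ties")
    return (preds.sum(axis=0) > preds.shape[0] / 2).astype(np.int64)


def _train_network(
    net: _nn.Sequential,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    learning_rate: float,
    batch_size: int,
    max_epochs: int,
    patience: int,
) -> tuple[int, float, list[float]]:
    """Adam + early stopping; leaves ``net`` at the best-validation weights."""
    opt = _nn.Adam(net.params, lr=learning_rate)
    best_loss = np.inf
    best_weights = net.get_weights()
    since_best = 0
    history: list[float] = []
    n_epochs = 0
    for epoch in range(max_epochs):
        for Xb, yb in balanced_batches(X_tr, y_tr, batch_size, rng):
            logits = net.forward(Xb, train=True, rng=rng)
            loss, dlogits = _nn.cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}"
                )
            net.backward(dlogits)
            opt.step(net.grads)
        val_loss, _ = _nn.cross_entropy(net.forward(X_val), y_val)
        history.append(val_loss)
        n_epochs = epoch + 1
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best > patience:
                break
    net.set_weights(best_weights)
    return n_epochs, float(best_loss), history


class _NetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the two network estimators."""

    def _build(self, n_features_or_shape, rng):  # pragma: no cover
        raise NotImplementedError

    def _validate(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64)

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._validate(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        y_idx = np.searchsorted(self.classes_, y)
        if X_val is None:
            X, X_val, y_idx, yv = holdout_split(
                X, y_idx, ratio=0.8, seed=self.random_state
            )
            y_val_idx = yv
        else:
            X_val = self._validate(X_val)
            y_val_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        rng = np.random.default_rng(self.random_state)
        self.input_shape_ = X.shape[1:]
        self.net_ = self._build(X.shape[1:], rng)
        self.n_epochs_, self.best_val_loss_, self.loss_history_ = (
            _train_network(
                self.net_, X, y_idx, X_val, y_val_idx, rng,
                self.learning_rate, self.batch_size, self.max_epochs,
                self.patience,
            )
        )
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.forward(self._validate(X))

    def predict_proba(self, X) -> np.ndarray:
        return _nn.softmax(self.decision_scores(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


class ShallowNetClassifier(_NetClassifier):
    """Dropout + two-neuron softmax layer over handcrafted features."""

    def __init__(
        self,
        hidden_neurons: int | None = None,
        dropout_rate: float = 0.5,
        learning_rate: float = LEARNING_RATE,
        batch_size: int = BATCH_SIZE,
        max_epochs: int = MAX_EPOCHS,
        patience: int = PATIENCE,
        random_state: int = 0,
    ):
        self.hidden_neurons = hidden_neurons
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    def _build(self, shape, rng):
        (n_features,) = shape
        layers: list[_nn.Layer] = [_nn.Dropout(self.dropout_rate)]
        if self.hidden_neurons:
            layers += [
                _nn.Dense(n_features, self.hidden_neurons, rng),
                _nn.Swish(),
                _nn.Dense(self.hidden_neurons, 2, rng),
            ]
        else:
            layers.append(_nn.Dense(n_features, 2, rng))
        return _nn.Sequential(layers)


class DeepEEGClassifier(_NetClassifier):
    """Compact CNN-BiLSTM over raw (n_channels, window_samples) windows."""

    def __init__(
        self,
        filters_start: int = 128,
        n_blocks: int = 3,
        kernel_size: int = 3,
        lstm_units: int = 64,
        spatial_dropout: float = 0.5,
        dropout_rate: float = 0.5,
        learning_rate: float = LEARNING_RATE,
        batch_size: int = BATCH_SIZE,
        max_epochs: int = MAX_EPOCHS,
        patience: int = PATIENCE,
        random_state: int = 0,
    ):
        self.filters_start = filters_start
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        self.lstm_units = lstm_units
        self.spatial_dropout = spatial_dropout
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    @classmethod
    def reduced(cls, **overrides) -> "DeepEEGClassifier":
        """Desk-scale profile: same topology, far fewer parameters."""
        defaults = dict(filters_start=8, lstm_units=8)
        defaults.update(overrides)
        return cls(**defaults)

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                "expected (n_windows, n_channels, window_samples) input"
            )
        return X

    def _build(self, shape, rng):
        n_ch, _ = shape
        layers: list[_nn.Layer] = []
        c_in = n_ch
        filters = self.filters_start
        for _ in range(self.n_blocks):
            layers += [
                _nn.Conv1d(c_in, filters, self.kernel_size, 1, rng),
                _nn.Conv1d(filters, filters, self.kernel_size, 2, rng),
                _nn.SpatialDropout1d(self.spatial_dropout),
                _nn.Swish(),
                _nn.BatchNorm1d(filters),
            ]
            c_in = filters
            filters *= 2
        layers += [
            _nn.Transpose(),
            _nn.BiLSTM(c_in, self.lstm_units, rng),
            _nn.Dropout(self.dropout_rate),
            _nn.Dense(2 * self.lstm_units, 2, rng),
        ]
        return _nn.Sequential(layers)


def save_model(clf: "_NetClassifier", path) -> None:
    """Checkpoint: weights in an .npz, metadata in a JSON sidecar."""
    import json
    from pathlib import Path

    check_is_fitted(clf, "net_")
    path = Path(path)
    np.savez_compressed(
        path, **{f"p{i}": p for i, p in enumerate(clf.net_.get_weights())}
    )
    meta = {
        "class": type(clf).__name__,
        "params": clf.get_params(),
        "classes": clf.classes_.tolist(),
        "n_epochs": clf.n_epochs_,
        "best_val_loss": clf.best_val_loss_,
        "input_shape": list(clf.input_shape_),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2))


def load_model(path) -> "_NetClassifier":
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cls = {"ShallowNetClassifier": ShallowNetClassifier,
           "DeepEEGClassifier": DeepEEGClassifier}[meta["class"]]
    clf = cls(**meta["params"])
    rng = np.random.default_rng(clf.random_state)
    clf.net_ = clf._build(tuple(meta["input_shape"]), rng)
    with np.load(path) as data:
        clf.net_.set_weights([data[f"p{i}"] for i in range(len(data))])
    clf.classes_ = np.asarray(meta["classes"])
    clf.n_epochs_ = meta["n_epochs"]
    clf.best_val_loss_ = meta["best_val_loss"]
    return clf


class VotingEnsemble(BaseEstimator, ClassifierMixin):
    """Majority-vote fusion of independently seeded training runs.

    Members are clones of ``base_estimator`` trained with seeds
    ``seed_base + run`` (covering initialisation, batch order and dropout);
    an odd member count avoids ties.  Votes are cast on per-window hard
    labels, making the ensemble a drop-in prediction source for the
    firing-power stage.
    """

    def __init__(self, base_estimator, n_members: int = N_RUNS,
                 seed_base: int = 0):
        self.base_estimator = base_estimator
        self.n_members = n_members
        self.seed_base = seed_base

    def fit(self, X, y, X_val=None, y_val=None):
        if self.n_members % 2 == 0:
            raise ValueError("n_members must be odd to avoid ties")
        self.members_ = []
        for run in range(self.n_members):
            member = clone(self.base_estimator)
            member.set_params(random_state=self.seed_base + run)
            member.fit(X, y, X_val=X_val, y_val=y_val)
            self.members_.append(member)
        self.classes_ = self.members_[0].classes_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        votes = np.stack(
            [np.searchsorted(self.classes_, m.predict(X))
             for m in self.members_]
        )
        return self.classes_[majority_vote(votes)]
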