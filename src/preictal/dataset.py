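"""Window labeling, chronological splits, and standardisation.

Labeling follows SOP/SPH alarm semantics: for each seizure, windows whose
start time lies in [onset - SPH - SOP, onset - SPH) are preictal (1),
windows inside the SPH [onset - SPH, onset) are discarded (-1), and
everything earlier is interictal (0).  Splits are chronological at the
seizure level (first 60% of seizures train); training data is restricted
to the hours immediately before each training seizure; each test seizure's
segment runs from 30 min after the previous onset up to its own onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .types import (
    LABEL_DISCARDED,
    LABEL_INTERICTAL,
    LABEL_PREICTAL,
    POSTICTAL_S,
    SOP_S,
    SPH_S,
    LabelledWindowSet,
)

TRAIN_WINDOW_S = 14400.0  # hours of data kept before each training onset


@dataclass(frozen=True)
class SplitSpec:
    """Chronological seizure-level partition (train strictly before test)."""

    train_seizure_indices: tuple[int, ...]
    test_seizure_indices: tuple[int, ...]
    train_fraction: float = 0.6

    def __post_init__(self) -> None:
        tr, te = self.train_seizure_indices, self.test_seizure_indices
        if set(tr) & set(te):
            raise ValueError("train/test seizure sets overlap")
        if tr and te and max(tr) >= min(te):
            raise ValueError("training seizures must precede test seizures")


def label_windows(
    X: np.ndarray,
    timestamps: np.ndarray,
    onsets: np.ndarray,
    sop_s: float = float(SOP_S),
    sph_s: float = float(SPH_S),
) -> LabelledWindowSet:
    """Assign SOP/SPH labels by window start time.

    ``seizure_index[i]`` is the index of the first onset at or after the
    window start (windows after the last onset get ``len(onsets)``).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    onsets = np.sort(np.asarray(onsets, dtype=float))
    labels = np.full(len(timestamps), LABEL_INTERICTAL, dtype=np.int8)
    for onset in onsets:
        pre = (timestamps >= onset - sph_s - sop_s) & (
            timestamps < onset - sph_s
        )
        sph = (timestamps >= onset - sph_s) & (timestamps < onset)
        labels[pre] = LABEL_PREICTAL
        labels[sph] = LABEL_DISCARDED
    # index of the seizure each window precedes; a window starting exactly
    # at an onset already belongs to the next seizure (side="right")
    seizure_index = np.searchsorted(onsets, timestamps, side="right").astype(
        np.int64
    )
    return LabelledWindowSet(np.asarray(X), labels, timestamps, seizure_index)


def chronological_split(
    onsets: np.ndarray | list[float], train_fraction: float = 0.6
) -> SplitSpec:
    """First round(fraction * n) seizures train (min 2), the rest test."""
    n = len(onsets)
    if n < 3:
        raise ValueError(
            f"need at least 3 leading seizures, got {n}"
        )
    n_train = int(np.floor(train_fraction * n + 0.5))  # round half up
    n_train = min(max(n_train, 2), n - 1)
    return SplitSpec(tuple(range(n_train)), tuple(range(n_train, n)),
                     train_fraction)


def training_view(
    labelled: LabelledWindowSet,
    onsets: np.ndarray,
    split: SplitSpec,
    train_window_s: float = TRAIN_WINDOW_S,
) -> LabelledWindowSet:
    """Restrict to the ``train_window_s`` seconds before each train onset."""
    onsets = np.asarray(onsets, dtype=float)
    keep = np.zeros(len(labelled), dtype=bool)
    for i in split.train_seizure_indices:
        onset = onsets[i]
        keep |= (labelled.timestamps >= onset - train_window_s) & (
            labelled.timestamps < onset
        )
    return labelled.subset(keep)


def test_view(
    labelled: LabelledWindowSet,
    onsets: np.ndarray,
    split: SplitSpec,
) -> tuple[LabelledWindowSet, list[tuple[float, float, float]]]:
    """Per test seizure: windows in [previous onset + 30 min, onset).

    Returns the concatenated view plus ``(segment_start, segment_end,
    onset)`` triples for downstream alarm evaluation.
    """
    onsets = np.asarray(onsets, dtype=float)
    keep = np.zeros(len(labelled), dtype=bool)
    segments: list[tuple[float, float, float]] = []
    for i in split.test_seizure_indices:
        onset = onsets[i]
        start = onsets[i - 1] + POSTICTAL_S if i > 0 else 0.0
        keep |= (labelled.timestamps >= start) & (labelled.timestamps < onset)
        segments.append((start, onset, onset))
    return labelled.subset(keep), segments


def holdout_split(
    X: np.ndarray,
    y: np.ndarray,
    ratio: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample-level random 80/20 split, stratified by class by default."""
    y = np.asarray(y)
    if len(y) < 5:
        raise ValueError("need at least 5 labelled samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for the holdout")
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, train_size=ratio, random_state=seed,
        stratify=y if stratify else None, shuffle=True,
    )
    return X_tr, X_val, y_tr, y_val


class Normaliser:
    """Z-score with statistics frozen on the training samples.

    2-D input (samples x features) is standardised per feature; 3-D input
    (windows x channels x samples) per channel.  Zero-variance features map
    to 0.  ``fit_tag`` records what the statistics were computed on so
    leakage can be audited.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.fit_tag: str = ""
        self.n_fit_: int = 0

    def fit(self, X: np.ndarray, tag: str = "train") -> "Normaliser":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:  # raw windows: per-channel statistics
            self.mean_ = X.mean(axis=(0, 2), keepdims=True)[0]
            sd = X.std(axis=(0, 2), keepdims=True)[0]
        else:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
        self.scale_ = np.where(sd > 1e-12, sd, 1.0)
        self.fit_tag = tag
        self.n_fit_ = len(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Normaliser not fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray, tag: str = "train") -> np.ndarray:
        return self.fit(X, tag).transform(X)


def zscore_fit(train_samples: np.ndarray, tag: str = "train") -> Normaliser:
    return Normaliser().fit(train_samples, tag)


def zscore_apply(normaliser: Normaliser, samples: np.ndarray) -> np.ndarray:
    return normaliser.transform(samples)
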