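"""Core containers shared by every pipeline stage.

The pipeline passes around a small set of plain dataclasses: a multichannel
recording with seizure annotations (:class:`EEGRecord`), the 10-s windowing
of it (:class:`WindowSet`), per-window feature vectors or labelled samples,
alarm times, and a per-patient evaluation report.  All signal arrays are
``channels x samples`` in microvolts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

#: Seizure occurrence period (s): the interval in which a predicted seizure
#: is expected to occur once the warning horizon has elapsed.
SOP_S = 1800
#: Seizure prediction horizon (s): warning interval between an alarm and the
#: start of the SOP.
SPH_S = 600
#: Refractory period after an alarm (s) = SPH + SOP.
REFRACTORY_S = SPH_S + SOP_S
#: Analysis window length (s).
WINDOW_S = 10
#: Postictal discard after each onset (s).
POSTICTAL_S = 1800

LABEL_INTERICTAL = 0
LABEL_PREICTAL = 1
LABEL_DISCARDED = -1


@dataclass
class EEGRecord:
    """A multichannel scalp-EEG recording with seizure-onset annotations.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    start_time : float
        Absolute start time in seconds (offset applied to all timestamps).
    onsets : ndarray
        Seizure-onset times in seconds from ``start_time``.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0
    onsets: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signal.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        dur = self.duration
        if self.onsets.size and (
            self.onsets.min() < 0 or self.onsets.max() > dur
        ):
            raise ValueError("onsets must lie within [0, duration]")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecord":
        return EEGRecord(
            self.signal.copy(),
            self.fs,
            list(self.channel_labels),
            self.start_time,
            self.onsets.copy(),
        )


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic recording.

    ``artefact_mask`` flags injected artefact samples per channel,
    ``preictal_mask`` is true exactly on [onset-SPH-SOP, onset-SPH) for each
    onset, and ``clean_signal`` is the recording before artefact injection.
    ``artefact_events`` maps artefact type -> list of (start_s, duration_s).
    """

    artefact_mask: np.ndarray
    preictal_mask: np.ndarray
    clean_signal: np.ndarray
    artefact_events: dict[str, list[tuple[float, float]]] = field(
        default_factory=dict
    )


@dataclass
class WindowSet:
    """Ordered non-overlapping 10-s windows with gap bookkeeping.

    Attributes
    ----------
    windows : ndarray, shape (n_windows, n_channels, window_samples)
    timestamps : ndarray
        Window start times (s), strictly increasing.
    contiguous_with_previous : ndarray of bool
        ``True`` at i iff ``timestamps[i] == timestamps[i-1] + 10``.
    """

    windows: np.ndarray
    timestamps: np.ndarray
    contiguous_with_previous: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    fs: float = 256.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.contiguous_with_previous = np.asarray(
            self.contiguous_with_previous, dtype=bool
        )
        n = len(self.timestamps)
        if len(self.windows) != n or len(self.contiguous_with_previous) != n:
            raise ValueError("windows/timestamps/contiguity length mismatch")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class FeatureMatrix:
    """Per-window flattened feature vectors (channel-major blocks).

    ``values`` has one row per window and ``55 * n_channels`` columns;
    ``feature_names`` are ``"<channel>/<feature>"`` strings.
    """

    values: np.ndarray
    feature_names: list[str]
    timestamps: np.ndarray
    contiguous_with_previous: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature name / column count mismatch")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class LabelledWindowSet:
    """Samples (features or raw windows) with SOP/SPH labels.

    ``labels``: 0 interictal, 1 preictal, -1 discarded (SPH).
    ``seizure_index[i]`` is the index of the seizure each window precedes.
    """

    X: np.ndarray
    labels: np.ndarray
    timestamps: np.ndarray
    seizure_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.X) == len(self.timestamps) == len(self.seizure_index) == n):
            raise ValueError("labelled set field length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "LabelledWindowSet":
        return LabelledWindowSet(
            self.X[mask],
            self.labels[mask],
            self.timestamps[mask],
            self.seizure_index[mask],
        )


@dataclass
class AlarmRecord:
    """Alarm timestamps plus their SOP/SPH classification."""

    alarm_times: np.ndarray
    refractory_s: float = float(REFRACTORY_S)
    is_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alarm_times = np.asarray(self.alarm_times, dtype=float)
        if self.alarm_times.size > 1:
            gaps = np.diff(self.alarm_times)
            if np.any(gaps < self.refractory_s - 1e-9):
                raise ValueError("alarms closer than the refractory period")


@dataclass
class EvalReport:
    """Evaluation of one patient/approach on its test seizures."""

    n_test_seizures: int
    n_true_alarms: int
    n_false_alarms: int
    interictal_duration_h: float
    sensitivity: float
    fpr_per_h: float
    surrogate_sensitivities: list[float] = field(default_factory=list)
    p_value: float = float("nan")
    above_chance: bool = False
    approach: str = ""
    metadata: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=float, **kwargs)
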