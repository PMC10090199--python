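"""Gap-aware firing-power regularisation and alarm generation.

The firing power at window ``n`` is the fraction of preictal-classified
windows among the ``tau`` most recent 10-s slots (``tau`` = SOP / 10 s =
180 at defaults).  Slots missing from the stream — windows dropped by
preprocessing — contribute 0, so after a gap the firing power has decayed
toward zero exactly as if null predictions had been observed; before the
stream has seen ``tau`` slots the missing history likewise counts as zeros.
An alarm fires at the first window whose firing power exceeds the 0.5
threshold; for the following refractory period (SPH + SOP = 40 min) no new
alarm may fire, and eligibility resumes unconditionally afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import REFRACTORY_S, SOP_S, WINDOW_S, AlarmRecord

TAU = SOP_S // WINDOW_S  # 180 slots at defaults
THRESHOLD = 0.5


@dataclass
class FiringPowerSeries:
    """Per-window firing power values on [0, 1], aligned with timestamps."""

    fp: np.ndarray
    timestamps: np.ndarray
    tau: int = TAU
    threshold: float = THRESHOLD

    def __post_init__(self) -> None:
        self.fp = np.asarray(self.fp, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.fp.shape != self.timestamps.shape:
            raise ValueError("fp/timestamps shape mismatch")


def firing_power(
    predictions: np.ndarray,
    timestamps: np.ndarray,
    tau: int = TAU,
) -> FiringPowerSeries:
    """Moving fraction of preictal outputs over the last ``tau`` slots.

    ``timestamps`` are window start times on the 10-s grid; gaps between
    consecutive windows are filled with zero-valued virtual slots.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    o = np.asarray(predictions, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if o.shape != timestamps.shape:
        raise ValueError("predictions/timestamps shape mismatch")
    if o.size == 0:
        return FiringPowerSeries(np.empty(0), np.empty(0), tau)
    if np.any((o != 0) & (o != 1)):
        raise ValueError("predictions must be 0/1 classes")

    slots = np.round((timestamps - timestamps[0]) / WINDOW_S).astype(np.int64)
    if np.any(np.diff(slots) < 1):
        raise ValueError("timestamps must be strictly increasing on the grid")
    dense = np.zeros(slots[-1] + 1)
    dense[slots] = o
    csum = np.concatenate(([0.0], np.cumsum(dense)))
    # sum over the tau slots ending at each emitted slot (inclusive);
    # history before the stream start counts as zeros
    hi = slots + 1
    lo = np.maximum(hi - tau, 0)
    fp = (csum[hi] - csum[lo]) / tau
    return FiringPowerSeries(fp, timestamps.copy(), tau)


def raise_alarms(
    fp: FiringPowerSeries,
    threshold: float = THRESHOLD,
    refractory_s: float = float(REFRACTORY_S),
) -> AlarmRecord:
    """Threshold crossing with refractory suppression.

    Strict inequality (``fp > threshold``); an alarm suppresses further
    alarms for ``refractory_s`` seconds of wall-clock time (gaps included),
    after which eligibility resumes with no re-arm condition.
    """
    alarm_times: list[float] = []
    last = -np.inf
    for t, value in zip(fp.timestamps, fp.fp):
        if value > threshold and t - last >= refractory_s:
            alarm_times.append(float(t))
            last = t
    return AlarmRecord(np.asarray(alarm_times), refractory_s)
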