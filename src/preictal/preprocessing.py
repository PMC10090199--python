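"""Raw-EEG conditioning: filtering, error masking, denoising, windowing.

The stage order mirrors the analysis pipeline: a 0.5-100 Hz fourth-order
band-pass plus a 50 Hz second-order notch (both zero-phase), removal of
experimental errors (flatlines, saturated segments, very high amplitude),
a pluggable physiological-artefact denoiser, discarding the first 30 min
after every seizure onset, and division into non-overlapping 10-s windows
that contain only valid samples.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import POSTICTAL_S, WINDOW_S, EEGRecord, WindowSet

BAND_LO_HZ = 0.5
BAND_HI_HZ = 100.0
NOTCH_HZ = 50.0
NOTCH_Q = 30.0

FLAT_MIN_S = 1.0
SAT_FRAC = 0.99
SAT_MIN_S = 0.1
AMP_MAX_UV = 500.0


def frequency_filter(record: EEGRecord) -> EEGRecord:
    """Zero-phase 0.5-100 Hz band-pass (order 4) + 50 Hz notch (order 2)."""
    if record.fs <= 2 * BAND_HI_HZ:
        raise ValueError(
            f"sampling rate {record.fs} Hz too low: band edge "
            f"{BAND_HI_HZ} Hz is at or above Nyquist"
        )
    # butter with btype='band' and N=2 has 4 poles (a fourth-order filter)
    sos = sps.butter(2, [BAND_LO_HZ, BAND_HI_HZ], btype="band",
                     fs=record.fs, output="sos")
    b, a = sps.iirnotch(NOTCH_HZ, NOTCH_Q, fs=record.fs)
    x = sps.sosfiltfilt(sos, record.signal, axis=-1)
    x = sps.filtfilt(b, a, x, axis=-1)
    return EEGRecord(x.astype(record.signal.dtype), record.fs,
                     list(record.channel_labels), record.start_time,
                     record.onsets.copy())


def _run_lengths(flags: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each True run in a boolean vector."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8), prepend=0, append=0)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def remove_experimental_errors(
    record: EEGRecord,
    flat_min_s: float = FLAT_MIN_S,
    sat_frac: float = SAT_FRAC,
    amp_max: float = AMP_MAX_UV,
) -> np.ndarray:
    """Per-sample validity mask (True = keep), applied across all channels.

    Invalid are: flatline runs of identical consecutive samples lasting at
    least ``flat_min_s``; runs of at least ``SAT_MIN_S`` pinned above
    ``sat_frac`` of the per-channel observed rail (converter clipping); and
    samples with ``|x| > amp_max`` microvolts.
    """
    if flat_min_s <= 0 or sat_frac <= 0 or amp_max <= 0:
        raise ValueError("thresholds must be positive")
    fs, n = record.fs, record.n_samples
    invalid = np.zeros(n, dtype=bool)
    flat_n = max(int(round(flat_min_s * fs)), 2)
    sat_n = max(int(round(SAT_MIN_S * fs)), 2)
    for c in range(record.n_channels):
        x = record.signal[c]
        same = np.concatenate(([False], np.diff(x) == 0))
        for start, length in _run_lengths(same):
            if length + 1 >= flat_n:  # run of equal values incl. first sample
                invalid[start - 1:start + length] = True
        rail = np.abs(x).max()
        if rail > 0:
            pinned = np.abs(x) >= sat_frac * rail
            for start, length in _run_lengths(pinned):
                if length >= sat_n:
                    invalid[start:start + length] = True
        invalid |= np.abs(x) > amp_max
    return ~invalid


def discard_postictal(record: EEGRecord) -> np.ndarray:
    """Validity mask invalidating [onset, onset + 30 min) for every onset."""
    valid = np.ones(record.n_samples, dtype=bool)
    for onset in record.onsets:
        a = int(round(onset * record.fs))
        b = int(round((onset + POSTICTAL_S) * record.fs))
        valid[max(a, 0):b] = False
    return valid


class Denoiser:
    """Physiological-artefact removal interface: EEGRecord -> EEGRecord.

    Implementations must preserve shape.  The registry makes the denoiser a
    pluggable stage so a learned model can be dropped in later.
    """

    name = "base"

    def transform(self, record: EEGRecord) -> EEGRecord:
        raise NotImplementedError


class IdentityDenoiser(Denoiser):
    """The 'noisy' branch: pass the record through unchanged."""

    name = "identity"

    def transform(self, record: EEGRecord) -> EEGRecord:
        return record


class TemplateSubtractionDenoiser(Denoiser):
    """Deterministic signal-processing denoiser for blink and muscle noise.

    Ocular artefacts: the low-frequency (0.5-8 Hz) average of the frontal
    channels serves as a blink/flutter reference; wherever its smoothed RMS
    envelope exceeds ``blink_k`` x its median, the reference is regressed
    out of every channel's low band on that segment.  Muscle bursts: where the
    20-90 Hz band's short-window RMS exceeds ``muscle_k`` x its median, the
    excess high-band component is scaled back to the median level.
    Thresholded activation keeps distortion on artefact-free data small.
    """

    name = "template"

    def __init__(self, blink_k: float = 2.0, muscle_k: float = 4.0,
                 n_frontal: int = 4, rms_win_s: float = 0.25) -> None:
        self.blink_k = blink_k
        self.muscle_k = muscle_k
        self.n_frontal = n_frontal
        self.rms_win_s = rms_win_s

    def _bandpass(self, x: np.ndarray, lo: float, hi: float,
                  fs: float) -> np.ndarray:
        sos = sps.butter(2, [lo, min(hi, 0.45 * fs)], btype="band",
                         fs=fs, output="sos")
        return sps.sosfiltfilt(sos, x, axis=-1)

    def transform(self, record: EEGRecord) -> EEGRecord:
        x = record.signal.astype(np.float64)
        fs = record.fs
        n_f = min(self.n_frontal, record.n_channels)

        from scipy.ndimage import uniform_filter1d

        low = self._bandpass(x, BAND_LO_HZ, 8.0, fs)
        ref = low[:n_f].mean(axis=0)
        env = np.sqrt(np.maximum(
            uniform_filter1d(ref ** 2, size=max(int(0.3 * fs), 1),
                             mode="nearest"), 0.0))
        thr = self.blink_k * max(np.median(env), 1e-9)
        active = env > thr
        # widen each active sample to the event's full footprint
        widen = int(0.15 * fs)
        if active.any() and widen:
            kernel = np.ones(2 * widen + 1)
            active = np.convolve(active, kernel, mode="same") > 0
        if active.any():
            denom = float(ref[active] @ ref[active])
            if denom > 0:
                beta = (low[:, active] @ ref[active]) / denom
                x[:, active] -= np.outer(beta, ref[active])

        high = self._bandpass(x, 20.0, 90.0, fs)
        win = max(int(self.rms_win_s * fs), 1)
        rms = np.sqrt(np.maximum(
            uniform_filter1d(high ** 2, size=win, axis=-1, mode="nearest"),
            0.0,
        ))
        med = np.median(rms, axis=-1, keepdims=True)
        burst = rms > self.muscle_k * np.maximum(med, 1e-9)
        scale = np.where(burst, 1.0 - med / np.maximum(rms, 1e-9), 0.0)
        x -= scale * high

        return EEGRecord(x.astype(record.signal.dtype), fs,
                         list(record.channel_labels), record.start_time,
                         record.onsets.copy())


DENOISERS: dict[str, type[Denoiser]] = {
    IdentityDenoiser.name: IdentityDenoiser,
    TemplateSubtractionDenoiser.name: TemplateSubtractionDenoiser,
}


def get_denoiser(name: str, **kwargs) -> Denoiser:
    try:
        cls = DENOISERS[name]
    except KeyError:
        raise KeyError(
            f"unknown denoiser {name!r}; registered: {sorted(DENOISERS)}"
        ) from None
    return cls(**kwargs)


def denoise(record: EEGRecord, denoiser: Denoiser | str) -> EEGRecord:
    """Apply a registered denoiser (identity = the noisy branch)."""
    if isinstance(denoiser, str):
        denoiser = get_denoiser(denoiser)
    out = denoiser.transform(record)
    if out.signal.shape != record.signal.shape:
        raise ValueError("denoiser changed the signal shape")
    return out


def segment(record: EEGRecord, validity: np.ndarray | None = None
            ) -> WindowSet:
    """Cut fully-valid, grid-aligned, non-overlapping 10-s windows.

    Windows are aligned to the record start on a fixed 10-s grid; any window
    spanning an invalid sample is dropped; a trailing partial window is
    dropped.  Contiguity flags mark windows directly following the previous
    emitted window.
    """
    n = record.n_samples
    win_n = int(round(WINDOW_S * record.fs))
    if validity is None:
        validity = np.ones(n, dtype=bool)
    validity = np.asarray(validity, dtype=bool)
    if validity.shape != (n,):
        raise ValueError("validity mask not aligned to the signal")

    n_slots = n // win_n
    if n_slots == 0:
        empty = np.empty((0, record.n_channels, win_n),
                         dtype=record.signal.dtype)
        return WindowSet(empty, np.empty(0), np.empty(0, dtype=bool),
                         list(record.channel_labels), record.fs)

    ok = validity[: n_slots * win_n].reshape(n_slots, win_n).all(axis=1)
    idx = np.where(ok)[0]
    windows = (
        record.signal[:, : n_slots * win_n]
        .reshape(record.n_channels, n_slots, win_n)
        .transpose(1, 0, 2)[idx]
    )
    timestamps = record.start_time + idx * float(WINDOW_S)
    contig = np.zeros(idx.size, dtype=bool)
    if idx.size > 1:
        contig[1:] = np.diff(idx) == 1
    return WindowSet(np.ascontiguousarray(windows), timestamps, contig,
                     list(record.channel_labels), record.fs)
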