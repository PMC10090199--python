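"""Ground-truthed synthetic long-term scalp EEG.

The generator emulates the statistical regime the analysis assumes rather
than the biophysics of real EEG: each channel is 1/f-shaped broadband noise
plus a narrowband alpha (8-13 Hz) rhythm; a parametric preictal signature —
relative theta power raised, relative alpha lowered — is confined to
[onset - SPH - SOP, onset - SPH); eye-blink/muscle artefacts and
experimental errors (flatlines, saturation) are injected at Poisson times;
and a slow linear drift of the alpha amplitude can emulate concept drift.

Everything is deterministic for a fixed seed, per-artefact-type seed streams
are independent (toggling one type does not move the others), and masks in
:class:`~preictal.types.GroundTruth` record exactly what was planted, so
every downstream stage can be tested against known truth.

Components are white Gaussian noise shaped by small IIR cascades (fast
enough for tens of synthetic hours on one core); the transfer functions are
exposed (:func:`pink_sos`, :func:`alpha_sos`, :func:`theta_sos`,
:func:`band_fraction`) so tests can derive expected band powers by
integrating ``|H(f)|^2`` independently of any feature code:

* broadband ~1/f background scaled to ``PINK_RMS``,
* narrowband alpha rhythm (8-13 Hz band-pass) with RMS ``ALPHA_RMS``,
* preictal theta component (5-7 Hz band-pass) with RMS
  ``preictal_effect * ALPHA_RMS`` while alpha RMS is multiplied by
  ``1 - ALPHA_SUPPRESSION * preictal_effect``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SOP_S, SPH_S, EEGRecord, GroundTruth

MIN_ONSET_SPACING_S = 16200.0  # 4 h 30 min between leading seizures

PINK_RMS = 12.0  # microvolts, broadband ~1/f background
ALPHA_RMS = 8.0  # microvolts, narrowband alpha rhythm
ALPHA_BAND_HZ = (8.0, 13.0)
THETA_COMPONENT_HZ = (5.0, 7.0)
ALPHA_SUPPRESSION = 0.5  # fraction of alpha removed per unit preictal_effect
RAMP_S = 5.0  # cosine ramp at preictal boundaries

SATURATION_RAIL_UV = 550.0
BLINK_AMPLITUDE_UV = 130.0
BLINK_DURATION_S = 0.4
FLUTTER_PROB = 0.6  # fraction of ocular events that are eyelid flutter
FLUTTER_HZ_RANGE = (4.5, 7.5)  # per-epoch flutter frequency
FLUTTER_AMPLITUDE_UV = 30.0  # per-epoch median flutter amplitude
BLINK_ACTIVE_MEAN_S = 2700.0  # waking epochs with dense ocular activity
BLINK_QUIET_MEAN_S = 14400.0
BLINK_ACTIVE_FACTOR = 5.0  # rate multiplier inside active epochs
BLINK_QUIET_FACTOR = 0.05
MUSCLE_RMS_UV = 25.0

_TEN20 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]

# fixed spawn keys: independent seed streams per randomness source
_STREAMS = {"background": 0, "blink": 1, "muscle": 2, "flatline": 3,
            "saturation": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SynthConfig:
    """Study conditions for one synthetic patient.

    ``artefact_rates`` are events/hour per type; ``drift_rate`` is the
    fractional change of the alpha amplitude per hour.
    """

    duration: float
    seizure_onsets: list[float] = field(default_factory=list)
    n_channels: int = 19
    fs: float = 256.0
    preictal_len: float = float(SOP_S)
    preictal_effect: float = 0.5
    artefact_rates: dict[str, float] = field(
        default_factory=lambda: {
            "blink": 60.0, "muscle": 20.0, "flatline": 1.0, "saturation": 1.0,
        }
    )
    drift_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.seizure_onsets, dtype=float)
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("seizure onsets must be strictly increasing")
            if onsets.size > 1:
                gap = float(np.diff(onsets).min())
                if gap < MIN_ONSET_SPACING_S:
                    raise ValueError(
                        f"consecutive onsets must be >= {MIN_ONSET_SPACING_S}"
                        f" s apart (got {gap} s)"
                    )
                if self.preictal_len + SPH_S > gap:
                    raise ValueError(
                        "preictal_len + SPH exceeds minimum inter-onset gap"
                    )
            if onsets.max() > self.duration:
                raise ValueError("onsets must lie within the recording")
        if self.preictal_effect < 0:
            raise ValueError("preictal_effect must be >= 0")
        if self.drift_rate < 0:
            raise ValueError("drift_rate must be >= 0")

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray(self.seizure_onsets, dtype=float)


def channel_names(n: int) -> list[str]:
    """10-20 montage names, cycled with suffixes beyond 19 channels."""
    return [
        _TEN20[i % len(_TEN20)] + ("" if i < len(_TEN20) else f"_{i // 19}")
        for i in range(n)
    ]


def pink_sos(fs: float) -> np.ndarray:
    """~ -10 dB/decade shaping cascade (pole/zero pairs per decade)."""
    from scipy.signal import bilinear

    sections = []
    for f_pole, f_zero in [(0.25, 0.79), (2.5, 7.9), (25.0, 79.0)]:
        wp, wz = 2 * np.pi * f_pole, 2 * np.pi * f_zero
        b, a = bilinear([1.0, wz], [1.0, wp], fs)
        sections.append(np.concatenate([np.append(b, 0.0),
                                        np.append(a, 0.0)]))
    return np.asarray(sections)


def alpha_sos(fs: float) -> np.ndarray:
    from scipy.signal import butter

    return butter(4, ALPHA_BAND_HZ, btype="band", fs=fs, output="sos")


def theta_sos(fs: float) -> np.ndarray:
    from scipy.signal import butter

    return butter(4, THETA_COMPONENT_HZ, btype="band", fs=fs, output="sos")


def band_fraction(sos: np.ndarray, fs: float, lo: float, hi: float,
                  n_points: int = 8192) -> float:
    """Fraction of a shaped component's power lying in [lo, hi] Hz.

    Integrates the squared magnitude response numerically; the analytic
    counterpart of measuring band power on the generated noise.
    """
    from scipy.signal import sosfreqz

    freqs, h = sosfreqz(sos, worN=n_points, fs=fs)
    p = np.abs(h) ** 2
    total = np.trapezoid(p, freqs)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(p[sel], freqs[sel]) / total)


def _filtered_noise(
    rng: np.random.Generator, n_ch: int, n: int, sos: np.ndarray,
    rms: float,
) -> np.ndarray:
    """White Gaussian noise shaped by an IIR cascade, scaled per channel."""
    from scipy.signal import sosfilt

    out = np.empty((n_ch, n), dtype=np.float32)
    for c in range(n_ch):
        x = sosfilt(sos, rng.standard_normal(n, dtype=np.float32))
        x *= rms / max(x.std(), 1e-12)
        out[c] = x.astype(np.float32)
    return out


def preictal_mask_for(
    onsets: np.ndarray, n_samples: int, fs: float
) -> np.ndarray:
    """Boolean per-sample mask, true on [onset-SPH-SOP, onset-SPH)."""
    mask = np.zeros(n_samples, dtype=bool)
    for onset in np.asarray(onsets, dtype=float):
        a = int(round((onset - SPH_S - SOP_S) * fs))
        b = int(round((onset - SPH_S) * fs))
        mask[max(a, 0):max(b, 0)] = True
    return mask


def _gate(mask: np.ndarray, fs: float) -> np.ndarray:
    """Smooth 0/1 gate with short cosine ramps at mask edges."""
    gate = mask.astype(np.float32)
    ramp_n = int(RAMP_S * fs)
    if ramp_n > 1:
        kernel = np.hanning(2 * ramp_n + 1).astype(np.float32)
        kernel /= kernel.sum()
        gate = np.convolve(gate, kernel, mode="same")
    return gate


def generate_recording(config: SynthConfig) -> tuple[EEGRecord, GroundTruth]:
    """Synthesize the clean (artefact-free) recording plus ground truth.

    The preictal signature is applied on the ground-truth preictal mask of
    each onset; with ``preictal_effect=0`` preictal and interictal segments
    are statistically indistinguishable.
    """
    n = int(round(config.duration * config.fs))
    rng = _rng(config.seed, "background")
    fs = config.fs

    pink = _filtered_noise(rng, config.n_channels, n, pink_sos(fs),
                           PINK_RMS)
    alpha = _filtered_noise(rng, config.n_channels, n, alpha_sos(fs),
                            ALPHA_RMS)

    pre_mask = preictal_mask_for(config.onsets, n, fs)
    signal = pink
    if config.preictal_effect > 0 and pre_mask.any():
        theta = _filtered_noise(
            rng, config.n_channels, n, theta_sos(fs),
            config.preictal_effect * ALPHA_RMS,
        )
        gate = _gate(pre_mask, fs)
        alpha_gain = 1.0 - ALPHA_SUPPRESSION * config.preictal_effect * gate
        signal = signal + alpha_gain * alpha + gate * theta
    else:
        signal = signal + alpha
    signal = signal.astype(np.float32)

    record = EEGRecord(
        signal=signal,
        fs=fs,
        channel_labels=channel_names(config.n_channels),
        onsets=config.onsets,
    )
    truth = GroundTruth(
        artefact_mask=np.zeros(signal.shape, dtype=bool),
        preictal_mask=pre_mask,
        clean_signal=signal.copy(),
    )
    return record, truth


def _blink_template(fs: float) -> np.ndarray:
    """Biphasic low-frequency transient (sharp rise, slower recovery)."""
    t = np.arange(int(BLINK_DURATION_S * fs)) / fs
    tpl = np.exp(-0.5 * ((t - 0.12) / 0.04) ** 2) - 0.45 * np.exp(
        -0.5 * ((t - 0.24) / 0.08) ** 2
    )
    return (tpl / np.abs(tpl).max()).astype(np.float32)


def _ocular_events(
    rng: np.random.Generator, mean_rate_per_h: float, duration: float,
) -> list[tuple[float, float, float]]:
    """(time, epoch flutter frequency, epoch amplitude scale) per event.

    Ocular activity alternates between rare dense "active" epochs (waking,
    restlessness) and long quiet stretches — a doubly stochastic Poisson
    process whose long-run mean rate approximates ``mean_rate_per_h``.
    Flutter frequency and amplitude scale are drawn once per active epoch,
    so each epoch has its own artefact character.
    """
    if mean_rate_per_h <= 0:
        return []
    events: list[tuple[float, float, float]] = []
    t = 0.0
    active = rng.random() < BLINK_ACTIVE_MEAN_S / (
        BLINK_ACTIVE_MEAN_S + BLINK_QUIET_MEAN_S
    )
    while t < duration:
        span = rng.exponential(
            BLINK_ACTIVE_MEAN_S if active else BLINK_QUIET_MEAN_S
        )
        end = min(t + span, duration)
        factor = BLINK_ACTIVE_FACTOR if active else BLINK_QUIET_FACTOR
        rate = mean_rate_per_h * factor / 3600.0
        k = rng.poisson(rate * (end - t))
        freq = rng.uniform(*FLUTTER_HZ_RANGE)
        amp_scale = rng.lognormal(0.0, 0.6)
        events.extend(
            (float(x), freq, amp_scale)
            for x in np.sort(rng.uniform(t, end, size=k))
        )
        t = end
        active = not active
    return events


def _poisson_events(
    rng: np.random.Generator, rate_per_h: float, duration: float,
    dur_lo: float, dur_hi: float,
) -> list[tuple[float, float]]:
    n_events = rng.poisson(rate_per_h * duration / 3600.0)
    starts = np.sort(rng.uniform(0, duration, size=n_events))
    durs = rng.uniform(dur_lo, dur_hi, size=n_events)
    return [
        (float(s), float(min(d, duration - s))) for s, d in zip(starts, durs)
    ]


def inject_artefacts(
    record: EEGRecord, truth: GroundTruth, config: SynthConfig
) -> tuple[EEGRecord, GroundTruth]:
    """Add blink/muscle/flatline/saturation events at Poisson times.

    ``truth.clean_signal`` is left untouched; masks and the per-type event
    list are updated in the returned :class:`GroundTruth`.
    """
    sig = record.signal.copy()
    mask = truth.artefact_mask.copy()
    events: dict[str, list[tuple[float, float]]] = {
        k: list(v) for k, v in truth.artefact_events.items()
    }
    fs, n = record.fs, record.n_samples
    n_ch = record.n_channels
    rates = config.artefact_rates

    frontal_w = np.full(n_ch, 0.15, dtype=np.float32)
    frontal_w[: min(4, n_ch)] = 1.0

    rng = _rng(config.seed, "blink")
    tpl = _blink_template(fs)
    for start, freq, amp_scale in _ocular_events(
        rng, rates.get("blink", 0.0), record.duration
    ):
        if rng.random() < FLUTTER_PROB:  # eyelid flutter burst
            dur = rng.uniform(2.0, 6.0)
            i, j = int(start * fs), min(int((start + dur) * fs), n)
            if j - i < int(0.5 * fs):
                continue
            t = np.arange(j - i) / fs
            wave = np.sin(2 * np.pi * freq * t) * np.hanning(j - i)
            amp = FLUTTER_AMPLITUDE_UV * amp_scale * rng.lognormal(0.0, 0.2)
            sig[:, i:j] += amp * np.outer(frontal_w, wave).astype(np.float32)
        else:  # single biphasic blink
            i = int(start * fs)
            j = min(i + tpl.size, n)
            amp = BLINK_AMPLITUDE_UV * rng.lognormal(0.0, 0.2)
            sig[:, i:j] += amp * np.outer(frontal_w, tpl[: j - i])
        mask[frontal_w >= 0.5, i:j] = True
        events.setdefault("blink", []).append((start, (j - i) / fs))

    rng = _rng(config.seed, "muscle")
    from scipy.signal import butter, sosfilt

    sos = butter(4, [20.0, min(90.0, 0.45 * fs)], btype="band",
                 fs=fs, output="sos")
    for start, dur in _poisson_events(
        rng, rates.get("muscle", 0.0), record.duration, 0.5, 2.0
    ):
        i, j = int(start * fs), min(int((start + dur) * fs), n)
        if j - i < int(0.2 * fs):
            continue
        chans = np.where(rng.random(n_ch) < 0.5)[0]
        if chans.size == 0:
            chans = np.array([int(rng.integers(n_ch))])
        burst = sosfilt(sos, rng.standard_normal((chans.size, j - i)), axis=-1)
        burst *= MUSCLE_RMS_UV / np.maximum(
            burst.std(axis=-1, keepdims=True), 1e-12
        )
        burst *= np.hanning(j - i)
        sig[chans, i:j] += burst.astype(np.float32)
        mask[chans, i:j] = True
        events.setdefault("muscle", []).append((start, (j - i) / fs))

    rng = _rng(config.seed, "flatline")
    for start, dur in _poisson_events(
        rng, rates.get("flatline", 0.0), record.duration, 2.0, 8.0
    ):
        i, j = int(start * fs), min(int((start + dur) * fs), n)
        sig[:, i:j] = sig[:, i:i + 1]
        mask[:, i:j] = True
        events.setdefault("flatline", []).append((start, (j - i) / fs))

    rng = _rng(config.seed, "saturation")
    for start, dur in _poisson_events(
        rng, rates.get("saturation", 0.0), record.duration, 1.0, 4.0
    ):
        i, j = int(start * fs), min(int((start + dur) * fs), n)
        rail = SATURATION_RAIL_UV * (1 if rng.random() < 0.5 else -1)
        sig[:, i:j] = np.clip(sig[:, i:j] + 2 * rail, -abs(rail), abs(rail))
        mask[:, i:j] = True
        events.setdefault("saturation", []).append((start, (j - i) / fs))

    noisy = EEGRecord(
        sig, record.fs, list(record.channel_labels),
        record.start_time, record.onsets.copy(),
    )
    return noisy, GroundTruth(mask, truth.preictal_mask, truth.clean_signal,
                              events)


def apply_concept_drift(record: EEGRecord, config: SynthConfig) -> EEGRecord:
    """Attenuate the alpha-band component linearly in time by drift_rate/h.

    Deterministic given the config (no random draws): the 8-13 Hz component
    is extracted with a zero-phase band-pass and scaled by
    ``max(1 - drift_rate * t_hours, 0.1)``.  Suppressing alpha moves the
    interictal background toward the preictal signature (relative theta
    up), the adversarial drift that periodic retraining must absorb.
    ``drift_rate = 0`` is the identity.
    """
    if config.drift_rate == 0:
        return record
    from scipy.signal import sosfiltfilt

    n = record.n_samples
    sos = alpha_sos(record.fs)
    t_hours = (np.arange(n) / record.fs / 3600.0).astype(np.float32)
    gain = np.maximum(1.0 - config.drift_rate * t_hours, 0.1) - 1.0
    sig = record.signal.copy()
    for c in range(record.n_channels):
        alpha_part = sosfiltfilt(sos, sig[c]).astype(np.float32)
        sig[c] += gain * alpha_part
    return EEGRecord(sig, record.fs, list(record.channel_labels),
                     record.start_time, record.onsets.copy())
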