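"""Handcrafted univariate EEG features: 55 per channel per 10-s window.

Composition per channel (names in :data:`FEATURE_NAMES_PER_CHANNEL`):

* 5 statistical moments: mean, sample variance, skewness, excess kurtosis,
  normalised mean intensity (mean |x| / max |x|);
* 2 Hjorth parameters: mobility and complexity (activity is the variance,
  already counted above);
* 1 decorrelation time: lag of the first zero crossing of the sample
  autocorrelation function, in seconds;
* 7 absolute band powers: delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30,
  gamma1 30-47, gamma2 53-75, gamma3 75-90 Hz;
* 6 relative band powers (delta..gamma2; the seventh is linearly redundant
  given the other six and is omitted);
* 21 pairwise band-power ratios (band_i / band_j for i < j);
* 1 total power (sum of the 7 absolute band powers);
* 3 spectral edge frequencies and 3 spectral edge powers at 50/75/90% of
  the cumulative power in 0.5-90 Hz;
* 1 alpha peak frequency (argmax of the PSD within 8-13 Hz);
* 5 relative wavelet detail energies, Daubechies-4 at 5 levels.

The PSD estimator is an averaged modified periodogram (Welch: 2-s Hann
segments, 50% overlap).  Degenerate windows (constant signal, zero power)
return 0 rather than NaN so downstream training never sees missing values.
All kernels are vectorised over a stack of windows; feature vectors are
flattened channel-major to length ``55 * n_channels``.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from .types import FeatureMatrix, WindowSet

BANDS: list[tuple[str, float, float]] = [
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma1", 30.0, 47.0),
    ("gamma2", 53.0, 75.0),
    ("gamma3", 75.0, 90.0),
]
BAND_NAMES = [b[0] for b in BANDS]
SEF_PERCENTS = (50, 75, 90)
WAVELET = "db4"
WAVELET_LEVELS = 5
_EPS = 1e-12


def _names_per_channel() -> list[str]:
    names = [
        "mean", "variance", "skewness", "kurtosis", "norm_mean_intensity",
        "hjorth_mobility", "hjorth_complexity", "decorrelation_time",
    ]
    names += [f"power_{b}" for b in BAND_NAMES]
    names += [f"rel_power_{b}" for b in BAND_NAMES[:-1]]
    names += [
        f"ratio_{BAND_NAMES[i]}_{BAND_NAMES[j]}"
        for i in range(len(BANDS))
        for j in range(i + 1, len(BANDS))
    ]
    names += ["total_power"]
    names += [f"sef{p}" for p in SEF_PERCENTS]
    names += [f"sep{p}" for p in SEF_PERCENTS]
    names += ["alpha_peak_freq"]
    names += [f"wavelet_d{i}" for i in range(1, WAVELET_LEVELS + 1)]
    return names


FEATURE_NAMES_PER_CHANNEL: list[str] = _names_per_channel()
N_FEATURES_PER_CHANNEL: int = len(FEATURE_NAMES_PER_CHANNEL)
assert N_FEATURES_PER_CHANNEL == 55


def moments(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """(mean, sample variance, skewness, excess kurtosis, mean |x|/max |x|).

    Works on the last axis of any stack.  Constant windows give skewness
    and kurtosis 0 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean(axis=-1)
    xc = x - mu[..., None]
    m2 = (xc ** 2).mean(axis=-1)
    var = x.var(axis=-1, ddof=1)
    ok = m2 > _EPS
    safe = np.where(ok, m2, 1.0)
    skew = np.where(ok, (xc ** 3).mean(axis=-1) / safe ** 1.5, 0.0)
    kurt = np.where(ok, (xc ** 4).mean(axis=-1) / safe ** 2 - 3.0, 0.0)
    amax = np.abs(x).max(axis=-1)
    nmi = np.where(amax > _EPS, np.abs(x).mean(axis=-1)
                   / np.where(amax > _EPS, amax, 1.0), 0.0)
    return mu, var, skew, kurt, nmi


def hjorth(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hjorth mobility and complexity along the last axis.

    mobility(x) = sqrt(var(dx)/var(x)); complexity = mobility(dx)/mobility(x).
    Zero-variance signals return (0, 0).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    d1 = np.diff(x, axis=-1)
    d2 = np.diff(d1, axis=-1)
    v0 = x.var(axis=-1)
    v1 = d1.var(axis=-1)
    v2 = d2.var(axis=-1)
    mob = np.where(v0 > _EPS, np.sqrt(v1 / np.where(v0 > _EPS, v0, 1.0)), 0.0)
    mob_d = np.where(v1 > _EPS, np.sqrt(v2 / np.where(v1 > _EPS, v1, 1.0)),
                     0.0)
    cplx = np.where(mob > _EPS, mob_d / np.where(mob > _EPS, mob, 1.0), 0.0)
    return mob, cplx


def decorrelation_time(x: np.ndarray, fs: float) -> np.ndarray:
    """Lag (s) of the first zero crossing of the sample autocorrelation.

    If the ACF never crosses zero within the window, the maximum searched
    lag (window length - 1 samples) is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean(axis=-1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(xc, n=nfft, axis=-1)
    acf = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=-1)[..., :n]
    a0 = acf[..., :1].copy()
    degenerate = a0[..., 0] <= _EPS
    a0[a0 <= _EPS] = 1.0
    acf = acf / a0
    nonpos = acf <= 0.0
    nonpos[..., 0] = False
    any_cross = nonpos.any(axis=-1)
    first = np.argmax(nonpos, axis=-1)
    lag = np.where(any_cross, first, n - 1).astype(np.float64)
    lag[degenerate] = n - 1  # constant window: no crossing by convention
    return lag / fs


def power_spectrum(x: np.ndarray, fs: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD over the last axis: 2-s Hann segments, 50% overlap."""
    nperseg = min(int(2 * fs), x.shape[-1])
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, axis=-1)


def band_powers(x: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """Spectral features from the Welch PSD of each window.

    Returns a dict with keys ``absolute`` (..., 7), ``relative`` (..., 6),
    ``ratios`` (..., 21), ``total`` (...,), ``sef`` (..., 3), ``sep``
    (..., 3), ``alpha_peak`` (...,).  Zero-power windows yield zeros.
    """
    freqs, psd = power_spectrum(np.asarray(x, dtype=np.float64), fs)
    df = freqs[1] - freqs[0]
    absolute = np.stack(
        [psd[..., (freqs >= lo) & (freqs < hi)].sum(axis=-1) * df
         for _, lo, hi in BANDS],
        axis=-1,
    )
    total = absolute.sum(axis=-1)
    ok = total > _EPS
    safe_tot = np.where(ok, total, 1.0)
    relative = np.where(ok[..., None],
                        absolute[..., :-1] / safe_tot[..., None], 0.0)
    n_b = len(BANDS)
    pairs = [(i, j) for i in range(n_b) for j in range(i + 1, n_b)]
    denom = absolute[..., [j for _, j in pairs]]
    numer = absolute[..., [i for i, _ in pairs]]
    ratios = np.where(denom > _EPS, numer / np.where(denom > _EPS, denom, 1.0),
                      0.0)

    in_band = (freqs >= BANDS[0][1]) & (freqs <= BANDS[-1][2])
    f_sel = freqs[in_band]
    cum = np.cumsum(psd[..., in_band] * df, axis=-1)
    cum_tot = cum[..., -1]
    sefs, seps = [], []
    for p in SEF_PERCENTS:
        target = (p / 100.0) * cum_tot
        idx = np.argmax(cum >= target[..., None] - _EPS, axis=-1)
        sefs.append(np.where(cum_tot > _EPS, f_sel[idx], 0.0))
        seps.append(np.where(cum_tot > _EPS,
                             np.take_along_axis(
                                 cum, idx[..., None], axis=-1)[..., 0], 0.0))
    sef = np.stack(sefs, axis=-1)
    sep = np.stack(seps, axis=-1)

    alpha_sel = (freqs >= 8.0) & (freqs <= 13.0)
    f_alpha = freqs[alpha_sel]
    peak_idx = np.argmax(psd[..., alpha_sel], axis=-1)
    alpha_peak = np.where(psd[..., alpha_sel].max(axis=-1) > _EPS,
                          f_alpha[peak_idx], 0.0)

    return {"absolute": absolute, "relative": relative, "ratios": ratios,
            "total": total, "sef": sef, "sep": sep, "alpha_peak": alpha_peak}


def wavelet_energies(x: np.ndarray) -> np.ndarray:
    """Relative energy of detail levels d1..d5 of a db4 decomposition.

    Energy of each detail level divided by the total energy over d1..d5 and
    the final approximation; each value lies in [0, 1] and the five sum to
    at most 1.  Output shape is input shape with the last axis replaced
    by 5 (ordered d1, d2, ..., d5).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2 ** WAVELET_LEVELS:
        raise ValueError("window too short for 5-level decomposition")
    coeffs = pywt.wavedec(x, WAVELET, level=WAVELET_LEVELS, axis=-1)
    energies = np.stack([(c ** 2).sum(axis=-1) for c in coeffs], axis=-1)
    total = energies.sum(axis=-1)
    ok = total > _EPS
    rel = np.where(ok[..., None], energies / np.where(
        ok, total, 1.0)[..., None], 0.0)
    # coeffs order is [a5, d5, d4, d3, d2, d1] -> reverse details to d1..d5
    return rel[..., :0:-1]


def _features_for_stack(windows: np.ndarray, fs: float) -> np.ndarray:
    """(n_windows, n_channels, L) -> (n_windows, n_channels, 55)."""
    mu, var, skew, kurt, nmi = moments(windows)
    mob, cplx = hjorth(windows)
    dct = decorrelation_time(windows, fs)
    spec = band_powers(windows, fs)
    wav = wavelet_energies(windows)
    cols = [mu, var, skew, kurt, nmi, mob, cplx, dct]
    out = np.concatenate(
        [np.stack(cols, axis=-1), spec["absolute"], spec["relative"],
         spec["ratios"], spec["total"][..., None], spec["sef"], spec["sep"],
         spec["alpha_peak"][..., None], wav],
        axis=-1,
    )
    return out


def extract_features(windows: WindowSet, chunk_size: int = 512
                     ) -> FeatureMatrix:
    """Compute the 55 features per channel for every window.

    Raises if any window contains non-finite samples (preprocessing should
    have removed those windows).  Output rows are flattened channel-major:
    channel 0's 55 features, then channel 1's, and so on.
    """
    n = len(windows)
    n_ch = windows.windows.shape[1] if n else len(windows.channel_labels)
    names = [
        f"{windows.channel_labels[c] if windows.channel_labels else f'ch{c}'}"
        f"/{feat}"
        for c in range(n_ch)
        for feat in FEATURE_NAMES_PER_CHANNEL
    ]
    out = np.empty((n, n_ch * N_FEATURES_PER_CHANNEL), dtype=np.float64)
    for start in range(0, n, chunk_size):
        block = np.asarray(windows.windows[start:start + chunk_size],
                           dtype=np.float64)
        if not np.isfinite(block).all():
            raise ValueError("non-finite samples in window stack")
        feats = _features_for_stack(block, windows.fs)
        out[start:start + len(block)] = feats.reshape(len(block), -1)
    if not np.isfinite(out).all():
        raise ValueError("non-finite feature values produced")
    return FeatureMatrix(out, names, windows.timestamps.copy(),
                         windows.contiguous_with_previous.copy())
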