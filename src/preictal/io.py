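"""Disk formats: EDF signals, CSV annotations, CSV feature matrices.

Signals are written as classic 16-bit EDF with per-channel physical
scaling (a compact writer implemented here); reading goes through
``mne.io.read_raw_edf`` so round trips are checked against an independent
parser.  Seizure annotations travel in a two-column CSV
(``onset_seconds,label``); feature matrices in a CSV with one row per
window (timestamp, contiguity, label, then the flattened features).
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EEGRecord, FeatureMatrix

_DIG_MAX = 32767


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path: str | Path) -> Path:
    """Write a classic EDF file (16-bit, 1-s data records).

    The sampling rate must be an integer; a trailing partial second is
    truncated.  Physical scaling is per channel, symmetric about zero.
    """
    path = Path(path)
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = record.n_samples // spr
    n_sig = record.n_channels
    sig = np.asarray(record.signal[:, : n_records * spr], dtype=np.float64)

    phys_max = np.maximum(np.abs(sig).max(axis=1), 1e-6)
    phys_max = np.ceil(phys_max * 100) / 100

    start = datetime.datetime(2000, 1, 1) + datetime.timedelta(
        seconds=float(record.start_time)
    )
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(256 * (1 + n_sig), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(n_sig, 4),
    ])
    labels = [lab[:16] for lab in record.channel_labels]
    per_sig = b"".join(
        b"".join(_field(v, w) for v in values)
        for values, w in [
            (labels, 16),
            (["" for _ in labels], 80),
            (["uV" for _ in labels], 8),
            ([f"{-m:.8g}"[:8] for m in phys_max], 8),
            ([f"{m:.8g}"[:8] for m in phys_max], 8),
            ([-_DIG_MAX for _ in labels], 8),
            ([_DIG_MAX for _ in labels], 8),
            (["" for _ in labels], 80),
            ([spr for _ in labels], 8),
            (["" for _ in labels], 32),
        ]
    )
    scale = _DIG_MAX / phys_max
    digital = np.clip(
        np.round(sig * scale[:, None]), -_DIG_MAX, _DIG_MAX
    ).astype("<i2")
    # data records: for each second, each signal's samples in sequence
    interleaved = (
        digital[:, : n_records * spr]
        .reshape(n_sig, n_records, spr)
        .transpose(1, 0, 2)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        fh.write(interleaved.tobytes())
    return path


def read_edf(path: str | Path, onsets: np.ndarray | None = None
             ) -> EEGRecord:
    """Read an EDF file through mne and return microvolt signals."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecord(
        signal=signal.astype(np.float32),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        onsets=np.asarray(onsets if onsets is not None else []),
    )


def write_annotations(onsets: np.ndarray, path: str | Path,
                      label: str = "seizure_onset") -> Path:
    path = Path(path)
    pd.DataFrame(
        {"onset_seconds": np.asarray(onsets, dtype=float),
         "label": label}
    ).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["onset_seconds"].to_numpy(dtype=float)


def write_features(
    fm: FeatureMatrix, path: str | Path,
    labels: np.ndarray | None = None,
) -> Path:
    path = Path(path)
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "timestamp", fm.timestamps)
    df.insert(1, "contiguous_with_previous", fm.contiguous_with_previous)
    df.insert(2, "label", labels if labels is not None
              else np.full(len(fm), np.nan))
    df.to_csv(path, index=False)
    return path


def write_windows(windows, path: str | Path) -> Path:
    """Windowed data as an .npz container with a JSON sidecar.

    The sidecar carries timestamps, contiguity flags, channel labels and
    the sampling rate in plain text; the window stack itself is binary.
    """
    import json

    path = Path(path)
    np.savez_compressed(path, windows=np.asarray(windows.windows))
    sidecar = {
        "timestamps": [float(t) for t in windows.timestamps],
        "contiguous_with_previous": [
            bool(c) for c in windows.contiguous_with_previous],
        "channel_labels": list(windows.channel_labels),
        "fs": float(windows.fs),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return path


def read_windows(path: str | Path):
    import json

    from .types import WindowSet

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with np.load(path) as data:
        stack = data["windows"]
    return WindowSet(stack, np.asarray(meta["timestamps"]),
                     np.asarray(meta["contiguous_with_previous"]),
                     meta["channel_labels"], meta["fs"])


def write_series(timestamps: np.ndarray, values: np.ndarray,
                 path: str | Path, value_name: str = "value") -> Path:
    """Prediction/firing-power/alarm series as (timestamp, value) CSV."""
    path = Path(path)
    pd.DataFrame({"timestamp": np.asarray(timestamps, dtype=float),
                  value_name: np.asarray(values)}).to_csv(path, index=False)
    return path


def read_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df["timestamp"].to_numpy(dtype=float),
            df[df.columns[1]].to_numpy())


def read_features(path: str | Path
                  ) -> tuple[FeatureMatrix, np.ndarray]:
    df = pd.read_csv(path)
    meta = ["timestamp", "contiguous_with_previous", "label"]
    names = [c for c in df.columns if c not in meta]
    fm = FeatureMatrix(
        df[names].to_numpy(dtype=float), names,
        df["timestamp"].to_numpy(dtype=float),
        df["contiguous_with_previous"].to_numpy(dtype=bool),
    )
    return fm, df["label"].to_numpy()
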