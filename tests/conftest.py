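import numpy as np
import pytest

from preictal.types import EEGRecord, WindowSet

FS = 256.0
WIN_N = 2560


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on
    # which other tests ran first
    return np.random.default_rng(1234)


def make_record(signal, fs=FS, onsets=(), start=0.0):
    labels = [f"ch{i}" for i in range(signal.shape[0])]
    return EEGRecord(np.asarray(signal, dtype=np.float64), fs, labels,
                     start, np.asarray(onsets, dtype=float))


def make_windowset(stack, fs=FS, t0=0.0):
    stack = np.asarray(stack)
    n = stack.shape[0]
    ts = t0 + 10.0 * np.arange(n)
    contig = np.zeros(n, dtype=bool)
    contig[1:] = True
    labels = [f"ch{i}" for i in range(stack.shape[1])]
    return WindowSet(stack, ts, contig, labels, fs)


@pytest.fixture(scope="session")
def sine_window():
    t = np.arange(WIN_N) / FS
    return np.sin(2 * np.pi * 10.0 * t)


@pytest.fixture(scope="session")
def noise_window():
    return np.random.default_rng(99).standard_normal(WIN_N)
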