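"""Feature kernels against closed forms and Monte-Carlo oracles."""

import numpy as np
import pytest

from preictal import features as F
from tests.conftest import FS, WIN_N, make_windowset


def single(x, fs=FS):
    """Extract the 55 features of one channel-window as a name->value dict."""
    ws = make_windowset(np.asarray(x)[None, None, :], fs=fs)
    fm = F.extract_features(ws)
    return dict(zip([n.split("/", 1)[1] for n in fm.feature_names],
                    fm.values[0]))


class TestComposition:
    def test_55_unique_names_per_channel(self):
        names = F.FEATURE_NAMES_PER_CHANNEL
        assert len(names) == 55
        assert len(set(names)) == 55

    def test_vector_length_scales_with_channels(self, rng):
        stack19 = rng.standard_normal((2, 19, WIN_N))
        fm = F.extract_features(make_windowset(stack19))
        assert fm.values.shape == (2, 1045)
        assert len(set(fm.feature_names)) == 1045
        stack1 = rng.standard_normal((2, 1, WIN_N))
        assert F.extract_features(make_windowset(stack1)).values.shape == \
            (2, 55)

    def test_identical_windows_identical_vectors(self, noise_window):
        stack = np.stack([noise_window[None], noise_window[None]])
        fm = F.extract_features(make_windowset(stack))
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_channel_permutation_permutes_blocks(self, rng):
        stack = rng.standard_normal((1, 3, WIN_N))
        fm = F.extract_features(make_windowset(stack))
        perm = F.extract_features(make_windowset(stack[:, [2, 0, 1]]))
        blocks = fm.values[0].reshape(3, 55)
        assert np.allclose(perm.values[0].reshape(3, 55),
                           blocks[[2, 0, 1]])

    def test_nan_window_rejected(self, noise_window):
        bad = noise_window.copy()
        bad[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            F.extract_features(make_windowset(bad[None, None, :]))

    def test_all_features_finite_on_hard_inputs(self, rng):
        hard = np.stack([
            np.zeros((1, WIN_N)), np.full((1, WIN_N), 7.5),
            rng.standard_normal((1, WIN_N)) * 1e-8,
            np.tile([1e6, -1e6], WIN_N // 2)[None],
        ])
        fm = F.extract_features(make_windowset(hard))
        assert np.isfinite(fm.values).all()


class TestMoments:
    def test_constant_window_conventions(self):
        d = single(np.ones(WIN_N))
        assert d["mean"] == 1.0
        assert d["variance"] == 0.0
        assert d["skewness"] == 0.0
        assert d["kurtosis"] == 0.0
        assert d["norm_mean_intensity"] == 1.0

    def test_alternating_sequence_closed_form(self):
        d = single(np.tile([-1.0, 1.0], WIN_N // 2))
        assert d["mean"] == pytest.approx(0.0, abs=1e-12)
        assert d["variance"] == pytest.approx(WIN_N / (WIN_N - 1))
        assert d["norm_mean_intensity"] == 1.0

    def test_gaussian_shape_within_standard_error(self, rng):
        x = rng.standard_normal(WIN_N)
        d = single(x)
        assert abs(d["skewness"]) < 3 * np.sqrt(6.0 / WIN_N)
        assert abs(d["kurtosis"]) < 3 * np.sqrt(24.0 / WIN_N)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            F.moments(np.array([1.0]))


class TestHjorth:
    def test_sinusoid_mobility_closed_form(self, sine_window):
        d = single(sine_window)
        assert d["hjorth_mobility"] == pytest.approx(
            2 * np.sin(np.pi * 10.0 / FS), rel=1e-3)

    def test_white_noise_mobility(self, rng):
        x = rng.standard_normal(WIN_N)
        mob, cplx = F.hjorth(x)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert mob == pytest.approx(np.sqrt(2 * (1 - r1)), rel=0.02)
        assert cplx > 0

    def test_constant_degenerates_to_zero(self):
        assert F.hjorth(np.full(100, 3.0)) == (0.0, 0.0)


class TestDecorrelationTime:
    def test_white_noise_first_lags(self, rng):
        vals = F.decorrelation_time(rng.standard_normal((200, WIN_N)), FS)
        # iid noise crosses zero at the first negative sample ACF value:
        # lag 1 with probability ~1/2, geometric beyond
        assert np.median(vals) <= 2.5 / FS
        assert vals.mean() < 8.0 / FS

    def test_sinusoid_quarter_period(self, sine_window):
        val = F.decorrelation_time(sine_window, FS)
        assert val == pytest.approx(0.025, abs=2.0 / FS)

    def test_constant_returns_max_lag(self):
        assert F.decorrelation_time(np.ones(256), FS) == \
            pytest.approx(255 / FS)


class TestBandPowers:
    def test_pure_alpha_sine(self, sine_window):
        d = single(sine_window)
        assert d["rel_power_alpha"] > 0.95
        assert d["alpha_peak_freq"] == pytest.approx(10.0, abs=0.5)
        assert d["sef50"] == pytest.approx(10.0, abs=0.5)
        assert d["sef90"] == pytest.approx(10.0, abs=0.5)

    def test_white_noise_band_fractions(self, rng):
        x = rng.standard_normal((64, 1, WIN_N))
        fm = F.extract_features(make_windowset(x))
        names = [n.split("/", 1)[1] for n in fm.feature_names]
        vals = dict(zip(names, fm.values.mean(axis=0)))
        widths = {"delta": 3.5, "theta": 4.0, "alpha": 5.0, "beta": 17.0,
                  "gamma1": 17.0, "gamma2": 22.0}
        total_width = sum(widths.values()) + 15.0  # + gamma3
        for band, w in widths.items():
            assert vals[f"rel_power_{band}"] == pytest.approx(
                w / total_width, rel=0.12), band

    def test_relative_powers_sum_to_one(self, noise_window):
        d = single(noise_window)
        rel6 = sum(d[f"rel_power_{b}"] for b in
                   ["delta", "theta", "alpha", "beta", "gamma1", "gamma2"])
        gamma3_rel = d["power_gamma3"] / d["total_power"]
        assert rel6 + gamma3_rel == pytest.approx(1.0, abs=1e-9)

    def test_ratios_consistent_with_absolutes(self, noise_window):
        d = single(noise_window)
        assert d["ratio_theta_alpha"] == pytest.approx(
            d["power_theta"] / d["power_alpha"], rel=1e-9)
        assert d["ratio_delta_gamma3"] == pytest.approx(
            d["power_delta"] / d["power_gamma3"], rel=1e-9)

    def test_total_is_sum_of_absolutes(self, noise_window):
        d = single(noise_window)
        total = sum(d[f"power_{b}"] for b in
                    ["delta", "theta", "alpha", "beta", "gamma1", "gamma2",
                     "gamma3"])
        assert d["total_power"] == pytest.approx(total, rel=1e-9)

    def test_sep_tracks_cumulative_power(self, noise_window):
        d = single(noise_window)
        assert 0 < d["sep50"] < d["sep75"] < d["sep90"]
        assert d["sef50"] < d["sef75"] < d["sef90"]

    def test_zero_signal_degenerates_to_zero(self):
        d = single(np.zeros(WIN_N))
        assert d["rel_power_alpha"] == 0.0
        assert d["ratio_delta_theta"] == 0.0
        assert d["total_power"] == 0.0


class TestWaveletEnergies:
    def test_constant_lives_in_approximation(self):
        d = single(np.full(WIN_N, 2.0))
        assert all(d[f"wavelet_d{i}"] == pytest.approx(0.0, abs=1e-12)
                   for i in range(1, 6))

    def test_alternating_signal_dominates_d1(self):
        d = single(np.tile([1.0, -1.0], WIN_N // 2))
        assert d["wavelet_d1"] > 0.9

    def test_energies_bounded_and_subunit(self, rng):
        x = rng.standard_normal((32, 1, WIN_N))
        fm = F.extract_features(make_windowset(x))
        cols = [i for i, n in enumerate(fm.feature_names)
                if "/wavelet_d" in n]
        e = fm.values[:, cols]
        assert (e >= 0).all() and (e <= 1).all()
        assert (e.sum(axis=1) <= 1 + 1e-9).all()

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            F.wavelet_energies(np.ones(16))
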