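"""Generator contracts: determinism, planted signature, artefact truth."""

import numpy as np
import pytest
from scipy.signal import periodogram

from preictal.synth import (
    ALPHA_RMS,
    ALPHA_SUPPRESSION,
    PINK_RMS,
    SynthConfig,
    alpha_sos,
    apply_concept_drift,
    band_fraction,
    generate_recording,
    inject_artefacts,
    pink_sos,
    theta_sos,
)
from preictal.types import SOP_S, SPH_S


def hour_config(effect=0.5, onset=3300.0, **kw):
    kw.setdefault("artefact_rates",
                  {"blink": 0, "muscle": 0, "flatline": 0, "saturation": 0})
    return SynthConfig(duration=3600.0, seizure_onsets=[onset],
                       n_channels=2, preictal_effect=effect, **kw)


def rel_band_power(x, fs, lo, hi):
    """Oracle band fraction via a plain periodogram (no feature code)."""
    f, p = periodogram(x, fs=fs)
    sel = (f >= 0.5) & (f <= 90.0)
    band = (f >= lo) & (f < hi)
    return p[band].sum() / p[sel].sum()


class TestConfigValidation:
    def test_onsets_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            SynthConfig(duration=40000, seizure_onsets=[20000, 19000])

    def test_minimum_spacing_enforced(self):
        with pytest.raises(ValueError, match="apart"):
            SynthConfig(duration=40000, seizure_onsets=[10000, 20000])

    def test_preictal_must_fit_inter_onset_gap(self):
        with pytest.raises(ValueError, match="gap"):
            SynthConfig(duration=40000, seizure_onsets=[3000, 19300],
                        preictal_len=16000.0)

    def test_onset_inside_recording(self):
        with pytest.raises(ValueError, match="within"):
            SynthConfig(duration=3600, seizure_onsets=[7200])


class TestGenerateRecording:
    def test_fixed_seed_is_bit_identical(self):
        cfg = hour_config(seed=7)
        rec1, tr1 = generate_recording(cfg)
        rec2, tr2 = generate_recording(cfg)
        assert np.array_equal(rec1.signal, rec2.signal)
        assert np.array_equal(tr1.preictal_mask, tr2.preictal_mask)

    def test_preictal_mask_interval(self):
        cfg = hour_config(onset=3300.0)
        _, truth = generate_recording(cfg)
        fs = cfg.fs
        idx = np.where(truth.preictal_mask)[0]
        assert idx[0] == int((3300 - SPH_S - SOP_S) * fs)
        assert idx[-1] == int((3300 - SPH_S) * fs) - 1
        assert len(idx) == int(SOP_S * fs)

    def test_planted_theta_shift_matches_composition(self):
        """Relative theta rises in preictal windows by the margin the
        component mix predicts, measured with an independent periodogram."""
        effect = 0.5
        cfg = hour_config(effect=effect, seed=3)
        rec, truth = generate_recording(cfg)
        fs = cfg.fs
        win = int(10 * fs)
        rel_theta, is_pre = [], []
        for s in range(0, rec.n_samples - win, win):
            rel_theta.append(rel_band_power(rec.signal[0, s:s + win], fs,
                                            4.0, 8.0))
            is_pre.append(truth.preictal_mask[s:s + win].all())
        rel_theta = np.array(rel_theta)
        is_pre = np.array(is_pre)

        # expected fractions from the shaping filters' transfer functions
        pink_var = PINK_RMS ** 2
        alpha_var = ALPHA_RMS ** 2
        theta_var = (effect * ALPHA_RMS) ** 2
        a_gain = (1 - ALPHA_SUPPRESSION * effect) ** 2
        th_of = lambda sos: band_fraction(sos, fs, 4.0, 8.0)  # noqa: E731

        def expected(pre):
            th = pink_var * th_of(pink_sos(fs))
            tot = pink_var
            if pre:
                th += a_gain * alpha_var * th_of(alpha_sos(fs)) \
                    + theta_var * th_of(theta_sos(fs))
                tot += a_gain * alpha_var + theta_var
            else:
                th += alpha_var * th_of(alpha_sos(fs))
                tot += alpha_var
            return th / tot

        obs_margin = rel_theta[is_pre].mean() - rel_theta[~is_pre].mean()
        exp_margin = expected(True) - expected(False)
        assert obs_margin > 0
        assert obs_margin == pytest.approx(exp_margin, rel=0.35)

    def test_planted_windows_recoverable_auc(self):
        """A threshold on oracle relative theta separates preictal from
        interictal windows with AUC > 0.9 at effect 0.5."""
        from sklearn.metrics import roc_auc_score

        cfg = hour_config(effect=0.5, seed=3)
        rec, truth = generate_recording(cfg)
        fs, win = cfg.fs, int(10 * cfg.fs)
        vals, lab = [], []
        for s in range(0, rec.n_samples - win, win):
            pre = truth.preictal_mask[s:s + win]
            if pre.any() and not pre.all():
                continue
            vals.append(rel_band_power(rec.signal[0, s:s + win], fs, 4, 8))
            lab.append(bool(pre.all()))
        assert roc_auc_score(lab, vals) > 0.9

    def test_zero_effect_leaves_no_trace(self):
        from scipy.stats import ttest_ind

        cfg = hour_config(effect=0.0, seed=5)
        rec, truth = generate_recording(cfg)
        fs, win = cfg.fs, int(10 * cfg.fs)
        rel_alpha, is_pre = [], []
        for s in range(0, rec.n_samples - win, win):
            rel_alpha.append(rel_band_power(rec.signal[0, s:s + win], fs,
                                            8.0, 13.0))
            is_pre.append(truth.preictal_mask[s:s + win].all())
        rel_alpha, is_pre = np.array(rel_alpha), np.array(is_pre)
        p = ttest_ind(rel_alpha[is_pre], rel_alpha[~is_pre]).pvalue
        assert p > 0.01


class TestInjectArtefacts:
    def test_zero_rates_change_nothing(self):
        cfg = hour_config(seed=2)
        rec, truth = generate_recording(cfg)
        noisy, truth2 = inject_artefacts(rec, truth, cfg)
        assert np.array_equal(noisy.signal, rec.signal)
        assert not truth2.artefact_mask.any()

    def test_flatline_produces_constant_runs_where_masked(self):
        cfg = hour_config(seed=2)
        cfg.artefact_rates = {"blink": 0, "muscle": 0, "flatline": 6.0,
                              "saturation": 0}
        rec, truth = generate_recording(cfg)
        noisy, truth2 = inject_artefacts(rec, truth, cfg)
        events = truth2.artefact_events["flatline"]
        assert events, "expected at least one flatline at 6/h over 1 h"
        fs = cfg.fs
        for start, dur in events:
            i, j = int(start * fs), int(start * fs) + int(dur * fs)
            seg = noisy.signal[0, i:j]
            assert dur >= 1.0
            assert np.all(seg == seg[0])
            assert truth2.artefact_mask[:, i:j].all()

    def test_masks_and_events_agree(self):
        cfg = hour_config(seed=4)
        cfg.artefact_rates = {"blink": 30.0, "muscle": 10.0,
                              "flatline": 2.0, "saturation": 2.0}
        rec, truth = generate_recording(cfg)
        noisy, truth2 = inject_artefacts(rec, truth, cfg)
        fs = cfg.fs
        for etype, events in truth2.artefact_events.items():
            for start, dur in events:
                i = int(start * fs)
                j = min(i + max(int(dur * fs), 1), rec.n_samples)
                assert truth2.artefact_mask[:, i:j].any(), etype
        assert np.array_equal(truth2.clean_signal, truth.clean_signal)

    def test_muscle_event_count_is_poisson(self):
        """Homogeneous Poisson types: count within 3 sigma of rate*T."""
        rate = 120.0
        counts = []
        for seed in range(5):
            cfg = hour_config(seed=seed)
            cfg.artefact_rates = {"blink": 0, "muscle": rate,
                                  "flatline": 0, "saturation": 0}
            rec, truth = generate_recording(cfg)
            _, truth2 = inject_artefacts(rec, truth, cfg)
            counts.append(len(truth2.artefact_events["muscle"]))
        mean = np.mean(counts)
        assert abs(mean - rate) < 3 * np.sqrt(rate / len(counts))

    def test_per_type_seed_streams_are_independent(self):
        cfg_a = hour_config(seed=2)
        cfg_a.artefact_rates = {"blink": 30.0, "muscle": 10.0,
                                "flatline": 0, "saturation": 0}
        cfg_b = hour_config(seed=2)
        cfg_b.artefact_rates = {"blink": 0.0, "muscle": 10.0,
                                "flatline": 0, "saturation": 0}
        rec, truth = generate_recording(cfg_a)
        _, tr_a = inject_artefacts(rec, truth, cfg_a)
        rec2, truth2 = generate_recording(cfg_b)
        _, tr_b = inject_artefacts(rec2, truth2, cfg_b)
        assert tr_a.artefact_events["muscle"] == tr_b.artefact_events[
            "muscle"]


class TestConceptDrift:
    def test_zero_rate_is_identity(self):
        cfg = hour_config(seed=1, drift_rate=0.0)
        rec, _ = generate_recording(cfg)
        out = apply_concept_drift(rec, cfg)
        assert out is rec

    def test_alpha_power_declines_monotonically_with_rate(self):
        def alpha_last_vs_first(drift):
            cfg = SynthConfig(duration=7200.0, n_channels=1, seed=9,
                              drift_rate=drift)
            rec, _ = generate_recording(cfg)
            out = apply_concept_drift(rec, cfg)
            fs = int(cfg.fs)
            f1, p1 = periodogram(out.signal[0, : 3600 * fs], fs=cfg.fs)
            f2, p2 = periodogram(out.signal[0, 3600 * fs:], fs=cfg.fs)
            a1 = p1[(f1 >= 8) & (f1 <= 13)].sum()
            a2 = p2[(f2 >= 8) & (f2 <= 13)].sum()
            return a2 / a1

        r0 = alpha_last_vs_first(0.0)
        r1 = alpha_last_vs_first(0.1)
        r2 = alpha_last_vs_first(0.3)
        assert r2 < r1 < r0
        assert r0 == pytest.approx(1.0, rel=0.2)

    def test_drift_deterministic_given_config(self):
        cfg = hour_config(seed=1, drift_rate=0.2)
        rec, _ = generate_recording(cfg)
        out1 = apply_concept_drift(rec, cfg)
        out2 = apply_concept_drift(rec, cfg)
        assert np.array_equal(out1.signal, out2.signal)
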