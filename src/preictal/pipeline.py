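"""End-to-end patient-specific experiments.

Runs one patient through preprocessing, feature extraction (for the
shallow branch), SOP/SPH labeling, ensemble training, firing-power alarm
generation and surrogate-validated evaluation, in either the *standard*
regime (train once on the first 60% of seizures, test the rest) or the
*chronological* regime (after each tested seizure its segment joins the
training set and everything — partitioning, standardisation, the whole
ensemble — is refit).

The eight study approaches are the cross product {Noisy, Denoised} x
{EEG (deep), Features (shallow)} x {Standard, Chronological}.  The default
configuration is the desk-scale profile (5-member ensembles, 2-h training
windows, reduced deep network); :meth:`ExperimentConfig.paper_scale`
restores the full-size settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import alarms as alarms_mod
from . import dataset as ds
from . import evaluation as ev
from . import preprocessing as pp
from .features import extract_features
from .models import DeepEEGClassifier, ShallowNetClassifier, VotingEnsemble
from .synth import MIN_ONSET_SPACING_S, SynthConfig, generate_recording, \
    inject_artefacts, apply_concept_drift
from .types import (
    LABEL_DISCARDED,
    LABEL_INTERICTAL,
    POSTICTAL_S,
    SOP_S,
    SPH_S,
    WINDOW_S,
    EEGRecord,
    EvalReport,
    LabelledWindowSet,
)

logger = logging.getLogger(__name__)

BRANCHES = ("noisy", "denoised")
CLASSIFIERS = ("shallow_features", "deep_timeseries")
REGIMES = ("standard", "chronological")


def approach_label(branch: str, classifier: str, regime: str) -> str:
    """Results-style approach name, e.g. ``"Denoised Features_Standard"``."""
    data = {"noisy": "Noisy", "denoised": "Denoised"}[branch]
    kind = {"shallow_features": "Features", "deep_timeseries": "EEG"}[
        classifier
    ]
    return f"{data} {kind}_{regime.capitalize()}"


ALL_APPROACHES = [
    approach_label(b, c, r)
    for b in BRANCHES for c in CLASSIFIERS for r in REGIMES
]


@dataclass
class ExperimentConfig:
    """All knobs of one approach run (defaults = desk-scale profile)."""

    branch: str = "denoised"
    classifier: str = "shallow_features"
    regime: str = "standard"
    n_members: int = 5
    seed_base: int = 0
    train_window_s: float = 7200.0
    train_fraction: float = 0.6
    sop_s: float = float(SOP_S)
    sph_s: float = float(SPH_S)
    tau: int = alarms_mod.TAU
    threshold: float = alarms_mod.THRESHOLD
    refractory_s: float = float(SOP_S + SPH_S)
    holdout_ratio: float = 0.8
    stratify: bool = True
    n_surrogates: int = ev.N_SURROGATES
    reduced_deep: bool = True
    denoiser: str = "template"
    max_epochs: int = 200
    estimator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"branch must be one of {BRANCHES}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        """Build from a YAML file; top-level sections are flattened so the
        file may group keys per pipeline stage."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in data.items():
            if isinstance(val, dict) and key != "estimator_params":
                flat.update(val)
            else:
                flat[key] = val
        flat.update(overrides)
        return cls(**flat)

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        """Full-size profile: 31 members, 4-h training windows, full CNN."""
        params = dict(n_members=31, train_window_s=14400.0,
                      reduced_deep=False, max_epochs=500)
        params.update(overrides)
        return cls(**params)

    @property
    def approach(self) -> str:
        return approach_label(self.branch, self.classifier, self.regime)


def _preprocess(
    record: EEGRecord, config: ExperimentConfig
) -> tuple["pp.WindowSet", dict]:
    """Filter, mask errors and postictal data, denoise (branch), window."""
    filtered = pp.frequency_filter(record)
    validity = pp.remove_experimental_errors(filtered)
    validity &= pp.discard_postictal(filtered)
    if config.branch == "denoised":
        cleaned = pp.denoise(filtered, config.denoiser)
    else:
        cleaned = pp.denoise(filtered, "identity")
    windows = pp.segment(cleaned, validity)
    n_slots = int(record.n_samples // (WINDOW_S * record.fs))
    log = {
        "n_slots": n_slots,
        "n_windows_kept": len(windows),
        "n_windows_dropped": n_slots - len(windows),
    }
    return windows, log


def _window_values(windows, config: ExperimentConfig) -> np.ndarray:
    """Feature vectors (shallow branch) or raw windows (deep branch)."""
    if config.classifier == "shallow_features":
        return extract_features(windows).values
    return np.asarray(windows.windows, dtype=np.float32)


def prepare_patient(
    record: EEGRecord, config: ExperimentConfig
) -> tuple[LabelledWindowSet, dict]:
    """Filter, mask errors, denoise (branch), window, featurise, label."""
    windows, log = _preprocess(record, config)
    X = _window_values(windows, config)
    labelled = ds.label_windows(
        X, windows.timestamps, record.onsets, config.sop_s, config.sph_s
    )
    counts = {int(k): int(v) for k, v in
              zip(*np.unique(labelled.labels, return_counts=True))}
    log["label_counts"] = counts
    return labelled, log


def _labelled_views(
    record: EEGRecord, config: ExperimentConfig
) -> tuple[LabelledWindowSet, "ds.SplitSpec", dict]:
    """Labelled windows restricted to what train/test views can touch.

    Feature extraction is the dominant cost, so it runs only on windows
    inside some training view (any seizure that is ever trained on) or
    some test segment — the union of everything both regimes consume.
    """
    windows, log = _preprocess(record, config)
    split = ds.chronological_split(record.onsets, config.train_fraction)
    ts = windows.timestamps
    onsets = record.onsets
    needed = np.zeros(len(ts), dtype=bool)
    for i in range(len(onsets)):
        lo = onsets[i] - config.train_window_s
        if i in split.test_seizure_indices:
            lo = min(lo, (onsets[i - 1] + POSTICTAL_S) if i > 0 else 0.0)
        needed |= (ts >= lo) & (ts < onsets[i])
    sub = type(windows)(
        windows.windows[needed], ts[needed],
        np.zeros(needed.sum(), dtype=bool),  # contiguity unused downstream
        windows.channel_labels, windows.fs,
    )
    X = _window_values(sub, config)
    labelled = ds.label_windows(
        X, sub.timestamps, onsets, config.sop_s, config.sph_s
    )
    counts = {int(k): int(v) for k, v in
              zip(*np.unique(labelled.labels, return_counts=True))}
    log["label_counts"] = counts
    return labelled, split, log


def _base_estimator(config: ExperimentConfig):
    params = dict(config.estimator_params)
    params.setdefault("max_epochs", config.max_epochs)
    if config.classifier == "shallow_features":
        return ShallowNetClassifier(**params)
    if config.reduced_deep:
        return DeepEEGClassifier.reduced(**params)
    return DeepEEGClassifier(**params)


def _fit_predict(
    train_lab: LabelledWindowSet,
    test_X: np.ndarray,
    config: ExperimentConfig,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Train one ensemble on the training view; predict every test window."""
    usable = train_lab.labels != LABEL_DISCARDED
    X = train_lab.X[usable]
    y = train_lab.labels[usable]
    X_tr, X_val, y_tr, y_val = ds.holdout_split(
        X, y, ratio=config.holdout_ratio, seed=seed,
        stratify=config.stratify,
    )
    norm = ds.zscore_fit(X_tr, tag=f"train(seed={seed})")
    ensemble = VotingEnsemble(
        _base_estimator(config), n_members=config.n_members, seed_base=seed
    )
    ensemble.fit(
        norm.transform(X_tr), y_tr,
        X_val=norm.transform(X_val), y_val=y_val,
    )
    preds = ensemble.predict(norm.transform(test_X)).astype(np.int64)
    info = {
        "n_train": int(len(y_tr)),
        "n_val": int(len(y_val)),
        "epochs": [m.n_epochs_ for m in ensemble.members_],
        "normaliser_fit_on": norm.fit_tag,
    }
    return preds, info


def _score(
    preds: np.ndarray,
    timestamps: np.ndarray,
    labels: np.ndarray,
    segments: list[tuple[float, float, float]],
    config: ExperimentConfig,
    metadata: dict,
) -> EvalReport:
    fp = alarms_mod.firing_power(preds, timestamps, tau=config.tau)
    alarm_rec = alarms_mod.raise_alarms(
        fp, threshold=config.threshold, refractory_s=config.refractory_s
    )
    interictal_h = float(
        (labels == LABEL_INTERICTAL).sum() * WINDOW_S / 3600.0
    )
    return ev.build_report(
        alarm_rec, segments, interictal_h,
        n_surrogates=config.n_surrogates, seed=config.seed_base,
        sop_s=config.sop_s, sph_s=config.sph_s,
        approach=config.approach, metadata=metadata,
    )


def _run_standard_from(
    labelled: LabelledWindowSet,
    split: "ds.SplitSpec",
    record: EEGRecord,
    config: ExperimentConfig,
    log: dict,
) -> EvalReport:
    train_lab = ds.training_view(
        labelled, record.onsets, split, config.train_window_s
    )
    test_lab, segments = ds.test_view(labelled, record.onsets, split)
    preds, info = _fit_predict(train_lab, test_lab.X, config,
                               config.seed_base)
    meta = {
        "preprocessing": log,
        "train_seizures": list(split.train_seizure_indices),
        "test_seizures": list(split.test_seizure_indices),
        "rounds": [
            {"test_seizures": list(split.test_seizure_indices),
             "train_seizures": list(split.train_seizure_indices), **info}
        ],
    }
    return _score(preds, test_lab.timestamps, test_lab.labels, segments,
                  config, meta)


def run_standard(
    record: EEGRecord, config: ExperimentConfig
) -> EvalReport:
    """Train once on the first 60% of seizures; test on the remainder."""
    labelled, split, log = _labelled_views(record, config)
    return _run_standard_from(labelled, split, record, config, log)


def _run_chronological_from(
    labelled: LabelledWindowSet,
    split: "ds.SplitSpec",
    record: EEGRecord,
    config: ExperimentConfig,
    log: dict,
) -> EvalReport:
    current = list(split.train_seizure_indices)
    all_preds, all_ts, all_labels = [], [], []
    segments: list[tuple[float, float, float]] = []
    rounds = []
    for round_no, i in enumerate(split.test_seizure_indices):
        if i in current:
            raise RuntimeError("test seizure leaked into the training set")
        round_split = ds.SplitSpec(tuple(current), (i,),
                                   config.train_fraction)
        train_lab = ds.training_view(
            labelled, record.onsets, round_split, config.train_window_s
        )
        test_lab, seg = ds.test_view(labelled, record.onsets, round_split)
        seed = config.seed_base + 101 * round_no
        preds, info = _fit_predict(train_lab, test_lab.X, config, seed)
        all_preds.append(preds)
        all_ts.append(test_lab.timestamps)
        all_labels.append(test_lab.labels)
        segments.extend(seg)
        rounds.append(
            {"test_seizures": [i], "train_seizures": list(current), **info}
        )
        current.append(i)
    meta = {
        "preprocessing": log,
        "train_seizures": list(split.train_seizure_indices),
        "test_seizures": list(split.test_seizure_indices),
        "rounds": rounds,
    }
    return _score(
        np.concatenate(all_preds), np.concatenate(all_ts),
        np.concatenate(all_labels), segments, config, meta,
    )


def run_chronological(
    record: EEGRecord, config: ExperimentConfig
) -> EvalReport:
    """Retrain after every tested seizure, concatenating its segment."""
    labelled, split, log = _labelled_views(record, config)
    return _run_chronological_from(labelled, split, record, config, log)


def run_regime_pair(
    record: EEGRecord, config: ExperimentConfig
) -> tuple[EvalReport, EvalReport]:
    """(standard, chronological) reports sharing one preprocessing pass.

    Both regimes consume the same labelled windows, so preprocessing and
    feature extraction — the dominant cost — run once.
    """
    labelled, split, log = _labelled_views(record, config)
    rep_std = _run_standard_from(
        labelled, split, record, replace(config, regime="standard"), log
    )
    rep_chrono = _run_chronological_from(
        labelled, split, record, replace(config, regime="chronological"),
        log,
    )
    return rep_std, rep_chrono


def run_approach(record: EEGRecord, config: ExperimentConfig) -> EvalReport:
    if config.regime == "standard":
        return run_standard(record, config)
    return run_chronological(record, config)


# the three comparison families and the tested direction per metric
_FAMILIES = [
    ("noisy vs denoised", "branch", ("noisy", "denoised"),
     "b_greater", "a_greater"),
    ("standard vs chronological", "regime", ("standard", "chronological"),
     "b_greater", "a_greater"),
    ("deep vs shallow", "classifier", ("deep_timeseries",
                                       "shallow_features"),
     "b_greater", "b_greater"),
]


def compare_approaches(
    reports: dict[str, list[EvalReport]]
) -> pd.DataFrame:
    """Pairwise one-tailed Mann-Whitney tests across the approach families.

    ``reports`` maps approach label -> per-patient EvalReports (same
    patients in the same order for every approach).  Sensitivity is tested
    in the direction "group B greater"; FPR/h in the direction "group B
    lower", except deep vs shallow where the feature models' FPR/h is
    tested as greater, mirroring the reporting convention of the study
    design.
    """
    lengths = {k: len(v) for k, v in reports.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"patient sets mismatch across approaches: "
                         f"{lengths}")
    rows = []
    for family, axis, (val_a, val_b), sens_dir, fpr_dir in _FAMILIES:
        for branch in BRANCHES:
            for clf in CLASSIFIERS:
                for regime in REGIMES:
                    combo = {"branch": branch, "classifier": clf,
                             "regime": regime}
                    if combo[axis] != val_a:
                        continue
                    combo_b = dict(combo)
                    combo_b[axis] = val_b
                    name_a = approach_label(**combo)
                    name_b = approach_label(**combo_b)
                    if name_a not in reports or name_b not in reports:
                        continue
                    rep_a, rep_b = reports[name_a], reports[name_b]
                    sens_a = [r.sensitivity for r in rep_a]
                    sens_b = [r.sensitivity for r in rep_b]
                    fpr_a = [r.fpr_per_h for r in rep_a]
                    fpr_b = [r.fpr_per_h for r in rep_b]
                    rows.append({
                        "family": family,
                        "group_a": name_a,
                        "group_b": name_b,
                        "p_sensitivity": ev.mann_whitney_one_tailed(
                            sens_a, sens_b, sens_dir),
                        "p_fpr": ev.mann_whitney_one_tailed(
                            fpr_a, fpr_b, fpr_dir),
                        "above_chance_a": sum(r.above_chance for r in rep_a),
                        "above_chance_b": sum(r.above_chance for r in rep_b),
                    })
    return pd.DataFrame(rows)


def make_patient(
    n_seizures: int = 3,
    n_channels: int = 2,
    duration_margin_s: float = 120.0,
    first_onset_s: float = 10860.0,
    spacing_s: float = MIN_ONSET_SPACING_S,
    preictal_effect: float = 0.5,
    artefact_rates: dict[str, float] | None = None,
    drift_rate: float = 0.0,
    seed: int = 0,
    fs: float = 256.0,
) -> tuple[EEGRecord, "np.ndarray", SynthConfig]:
    """Generate one desk-scale synthetic patient ready for the pipeline.

    Returns the (possibly artefacted/drifting) record, the ground-truth
    artefact mask, and the config used.  Onsets are evenly spaced at the
    minimum legal separation so total duration stays tractable.
    """
    onsets = [first_onset_s + k * spacing_s for k in range(n_seizures)]
    cfg = SynthConfig(
        duration=onsets[-1] + duration_margin_s,
        seizure_onsets=onsets,
        n_channels=n_channels,
        fs=fs,
        preictal_effect=preictal_effect,
        artefact_rates=artefact_rates or
        {"blink": 0.0, "muscle": 0.0, "flatline": 0.0, "saturation": 0.0},
        drift_rate=drift_rate,
        seed=seed,
    )
    record, truth = generate_recording(cfg)
    if any(v > 0 for v in cfg.artefact_rates.values()):
        record, truth = inject_artefacts(record, truth, cfg)
    if drift_rate > 0:
        record = apply_concept_drift(record, cfg)
    return record, truth.artefact_mask, cfg


__all__ = [
    "ALL_APPROACHES", "BRANCHES", "CLASSIFIERS", "REGIMES",
    "ExperimentConfig", "approach_label", "compare_approaches",
    "make_patient", "prepare_patient", "run_approach", "run_chronological",
    "run_regime_pair", "run_standard",
]
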