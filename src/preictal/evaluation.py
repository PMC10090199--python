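"""Alarm scoring, surrogate chance-level analysis, approach comparison.

An alarm raised at time *t* is a true prediction iff some test-seizure
onset lies in [t + SPH, t + SPH + SOP); at most one alarm (the earliest
qualifying) counts per seizure.  Sensitivity is true alarms over test
seizures; FPR/h divides false alarms by the interictal duration minus the
time blocked by refractory periods after false alarms.

Chance level is assessed with a Monte-Carlo surrogate test: each test
onset is relocated uniformly within its own test segment (leaving room for
SPH + SOP before it) and the *fixed* alarm times are re-scored.  The
default p-value is the exchangeable-rank Monte-Carlo estimate with
randomized tie-breaking, p = (#greater + u + 1) / (n + 1) with u uniform
on {0..#tied}, which is exactly calibrated under the null; a one-sample
t-type alternative is available via ``method="ttest"``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .types import REFRACTORY_S, SOP_S, SPH_S, AlarmRecord, EvalReport

logger = logging.getLogger(__name__)

N_SURROGATES = 39  # p-grid k/40 makes the 0.05 level exactly attainable
ALPHA = 0.05


def classify_alarms(
    alarms: AlarmRecord | np.ndarray,
    onsets: np.ndarray,
    sop_s: float = float(SOP_S),
    sph_s: float = float(SPH_S),
) -> tuple[int, int]:
    """Count (true, false) alarms under SOP/SPH semantics."""
    times = np.asarray(
        alarms.alarm_times if isinstance(alarms, AlarmRecord) else alarms,
        dtype=float,
    )
    onsets = np.asarray(onsets, dtype=float)
    n_true = 0
    claimed = np.zeros(len(onsets), dtype=bool)
    for t in np.sort(times):
        hits = np.where(
            ~claimed
            & (onsets >= t + sph_s)
            & (onsets < t + sph_s + sop_s)
        )[0]
        if hits.size:
            claimed[hits[0]] = True
            n_true += 1
    return n_true, len(times) - n_true


def sensitivity(n_true: int, n_test_seizures: int) -> float:
    """Fraction of test seizures preceded by a true alarm."""
    if n_test_seizures < 1:
        raise ValueError("need at least one test seizure")
    return n_true / n_test_seizures


def fpr_per_hour(
    n_false: int,
    interictal_h: float,
    refractory_h: float = REFRACTORY_S / 3600.0,
) -> float:
    """False alarms per hour of alarm-eligible interictal time."""
    denom = interictal_h - n_false * refractory_h
    if denom <= 0:
        raise ValueError(
            f"non-positive effective interictal time: {interictal_h} h - "
            f"{n_false} x {refractory_h} h = {denom} h"
        )
    return n_false / denom


def geometric_mean_sens_spec(sens: float, spec: float) -> float:
    """sqrt(sensitivity x specificity), the grid-search selection metric."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return float(np.sqrt(sens * spec))


def surrogate_analysis(
    alarms: AlarmRecord | np.ndarray,
    test_segments: list[tuple[float, float, float]],
    n_surrogates: int = N_SURROGATES,
    seed: int = 0,
    sop_s: float = float(SOP_S),
    sph_s: float = float(SPH_S),
    method: str = "rank",
    alpha: float = ALPHA,
) -> tuple[np.ndarray, float, bool]:
    """Monte-Carlo chance level for the observed alarm times.

    ``test_segments`` holds ``(start, end, onset)`` per test seizure; each
    surrogate relocates every onset uniformly within [start + SPH + SOP,
    end] of its own segment (full segment, with a warning, if too short)
    and re-scores the real alarms.  Returns (surrogate sensitivities,
    p-value, above-chance flag); above-chance requires the real sensitivity
    to exceed the surrogate mean at significance ``alpha``.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogate repetitions")
    times = np.asarray(
        alarms.alarm_times if isinstance(alarms, AlarmRecord) else alarms,
        dtype=float,
    )
    n_seiz = len(test_segments)
    real_true = sum(
        classify_alarms(
            times[(times >= s) & (times < e)], [onset], sop_s, sph_s
        )[0]
        for s, e, onset in test_segments
    )
    real_sens = sensitivity(real_true, n_seiz)

    rng = np.random.default_rng(seed)
    lows, highs = [], []
    for start, end, _ in test_segments:
        lo = start + sph_s + sop_s
        if lo >= end:
            logger.warning(
                "test segment [%s, %s) shorter than SPH+SOP; using the "
                "full segment for surrogate onsets", start, end,
            )
            lo = start
        lows.append(lo)
        highs.append(end)
    lows_arr, highs_arr = np.asarray(lows), np.asarray(highs)

    surr = np.empty(n_surrogates)
    for r in range(n_surrogates):
        onsets = rng.uniform(lows_arr, highs_arr)
        hits = 0
        for (start, end, _), onset in zip(test_segments, onsets):
            seg_times = times[(times >= start) & (times < end)]
            hits += classify_alarms(seg_times, [onset], sop_s, sph_s)[0]
        surr[r] = sensitivity(hits, n_seiz)

    if method == "rank":
        greater = int((surr > real_sens + 1e-12).sum())
        ties = int((np.abs(surr - real_sens) <= 1e-12).sum())
        u = int(rng.integers(0, ties + 1))
        p = (greater + u + 1) / (n_surrogates + 1)
    elif method == "ttest":
        sd = surr.std(ddof=1)
        if sd < 1e-12:
            p = 0.5 if abs(real_sens - surr.mean()) < 1e-12 else (
                0.0 if real_sens > surr.mean() else 1.0)
        else:
            t = (real_sens - surr.mean()) / (sd / np.sqrt(n_surrogates))
            p = float(stats.t.sf(t, df=n_surrogates - 1))
    else:
        raise ValueError(f"unknown surrogate test method {method!r}")

    above = bool(real_sens > surr.mean() and p <= alpha)
    return surr, float(p), above


def mann_whitney_one_tailed(
    group_a: np.ndarray,
    group_b: np.ndarray,
    direction: str = "b_greater",
) -> float:
    """One-tailed Mann-Whitney U p-value with midrank tie handling.

    ``direction`` is ``"b_greater"`` (p small when B stochastically
    dominates A) or ``"a_greater"``.  Two identical constant groups have no
    ordering information; p = 0.5 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.info("all values identical across groups; p = 0.5")
        return 0.5
    alternative = {"b_greater": "less", "a_greater": "greater"}[direction]
    return float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)


def build_report(
    alarms: AlarmRecord,
    test_segments: list[tuple[float, float, float]],
    interictal_duration_h: float,
    n_surrogates: int = N_SURROGATES,
    seed: int = 0,
    sop_s: float = float(SOP_S),
    sph_s: float = float(SPH_S),
    approach: str = "",
    metadata: dict | None = None,
) -> EvalReport:
    """Score one patient/approach: alarm counts, rates, surrogate test."""
    times = alarms.alarm_times
    n_true = 0
    n_false = 0
    for start, end, onset in test_segments:
        seg_times = times[(times >= start) & (times < end)]
        t, f = classify_alarms(seg_times, [onset], sop_s, sph_s)
        n_true += t
        n_false += f
    n_seiz = len(test_segments)
    sens = sensitivity(n_true, n_seiz)
    fpr = fpr_per_hour(n_false, interictal_duration_h)
    surr, p, above = surrogate_analysis(
        alarms, test_segments, n_surrogates, seed, sop_s, sph_s
    )
    return EvalReport(
        n_test_seizures=n_seiz,
        n_true_alarms=n_true,
        n_false_alarms=n_false,
        interictal_duration_h=interictal_duration_h,
        sensitivity=sens,
        fpr_per_h=fpr,
        surrogate_sensitivities=[float(s) for s in surr],
        p_value=p,
        above_chance=above,
        approach=approach,
        metadata=metadata or {},
    )
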