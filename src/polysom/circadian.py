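"""Actigraphy rhythms and light/dark masking analyses.

Entrainment and the free-running period are read from 1-min-binned
locomotor counts: the Sokolove–Bushell chi-squared periodogram over a
20–28 h period grid (1-min step), threshold-crossing activity-onset
detection, phase angle of entrainment (onset minus lights-off), onset
variability (SD of residuals around the onset regression line), and
pulse-induced phase shifts (pre/post regression lines extrapolated to
the pulse day).  Masking analyses compare vigilance-state time during
light or dark pulses, ultradian 1h:1h LD, and LD-vs-DD subjective
phases on hypnograms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import (ARTIFACT, DARK, LIGHT, NREM, REM, STATES, WAKE,
                 ActivityTrace, Hypnogram, LightSchedule, PolysomError)
from .architecture import phase_totals

logger = logging.getLogger("polysom")


# ---------------------------------------------------------------------------
# Chi-squared periodogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    df: np.ndarray
    threshold: np.ndarray       # per-period chi-squared line at `alpha`
    alpha: float
    best_period_h: float | None
    peak_excess: float | None   # Qp(best) - threshold(best)
    folded_profile: np.ndarray | None   # column means at the best period
    sig_threshold: np.ndarray | None = None   # Bonferroni line used for the peak


def chi2_periodogram(trace: ActivityTrace,
                     period_min_grid: np.ndarray | None = None,
                     alpha: float = 0.001) -> PeriodogramResult:
    """Sokolove–Bushell statistic over a 20–28 h grid of trial periods.

    For a trial period of P bins the trace is folded into K = floor(N/P)
    complete cycles (the trailing remainder is dropped); with column
    means M_h and grand mean M over the folded block of N' = K*P points,

        Qp = K * N' * sum_h (M_h - M)^2 / sum_i (x_i - M)^2,

    referred to chi-squared with P-1 degrees of freedom.  The stored
    ``threshold`` is the per-period chi-squared line at ``alpha``; a
    rhythm is declared (and the best period chosen, maximizing
    Qp - threshold) only where Qp also clears the Bonferroni-corrected
    line ``alpha / n_periods``, so a flat trace rarely yields a peak
    despite the hundreds of trial periods.
    """
    x = np.asarray(trace.counts, dtype=float)
    if period_min_grid is None:
        period_min_grid = np.arange(20 * 60, 28 * 60 + 1)
    period_min_grid = np.asarray(period_min_grid, dtype=int)
    if len(x) < 3 * period_min_grid.max():
        raise PolysomError("need at least 3 full cycles of the longest period")
    qp = np.empty(len(period_min_grid))
    dfs = np.empty(len(period_min_grid), dtype=int)
    profiles = {}
    for j, p in enumerate(period_min_grid):
        k = len(x) // p
        block = x[: k * p]
        grand = block.mean()
        denom = np.sum((block - grand) ** 2)
        if denom == 0:
            raise PolysomError("constant activity trace: no variance")
        m = block.reshape(k, p).mean(axis=0)
        qp[j] = k * (k * p) * np.sum((m - grand) ** 2) / denom
        dfs[j] = p - 1
        profiles[j] = m
    thr = stats.chi2.ppf(1 - alpha, dfs)
    sig_thr = stats.chi2.ppf(1 - alpha / len(period_min_grid), dfs)
    excess = qp - thr
    sig = qp > sig_thr
    if sig.any():
        best = int(np.argmax(np.where(sig, excess, -np.inf)))
        best_period = float(period_min_grid[best]) / 60.0
        peak_excess = float(excess[best])
        profile = profiles[best]
    else:
        best_period = peak_excess = profile = None
    return PeriodogramResult(period_min_grid / 60.0, qp, dfs, thr, alpha,
                             best_period, peak_excess, profile, sig_thr)


def amplitude(result: PeriodogramResult) -> dict[str, float]:
    """Rhythm amplitude at the periodogram peak, both readings.

    ``peak_excess`` is the Qp height above the chi-squared line (scale
    invariant); ``peak_to_nadir`` is max minus min of the folded mean
    waveform at the best period (count units).  Both are reported
    because "peak-to-nadir extracted from the periodogram peak" admits
    either reading.
    """
    if result.best_period_h is None:
        raise PolysomError("no significant periodogram peak")
    prof = result.folded_profile
    return {"peak_excess": result.peak_excess,
            "peak_to_nadir": float(prof.max() - prof.min())}


# ---------------------------------------------------------------------------
# Activity onsets
# ---------------------------------------------------------------------------

def detect_onsets(trace: ActivityTrace, period_h: float = 24.0,
                  quiescence_min: int = 240, active_min: int = 30,
                  threshold: float | None = None,
                  quiescence_frac: float = 0.9,
                  immediate_min: int = 10,
                  immediate_frac: float = 0.8) -> np.ndarray:
    """Daily activity-onset times (absolute minutes from trace start).

    The onset of a cycle is the first minute above threshold that is
    followed by at least ``active_min`` above-threshold minutes within
    the next 60 (and ``immediate_frac`` of the next ``immediate_min``
    minutes — this rejects isolated pre-onset count spikes) and
    preceded by a ``quiescence_min`` stretch that is at least
    ``quiescence_frac`` below threshold.  The threshold defaults to
    each cycle's median count.  Cycles are ``period_h`` long (24 h
    under LD, the period estimate under DD); cycles without a
    qualifying onset are skipped and logged.
    """
    x = np.asarray(trace.counts, dtype=float)
    p = int(round(period_h * 60))
    n_cycles = len(x) // p
    if n_cycles < 2:
        raise PolysomError("need at least 2 cycles for onset detection")
    if not np.any(x > 0):
        logger.warning("all-zero activity trace: no onsets")
        return np.array([])
    onsets = []
    for c in range(n_cycles):
        a, b = c * p, (c + 1) * p
        thr = float(np.median(x[a:b])) if threshold is None else threshold
        found = None
        for t in range(max(a, quiescence_min), b):
            if x[t] <= thr:
                continue
            nxt = x[t:t + 60]
            if np.sum(nxt > thr) < active_min:
                continue
            imm = x[t:t + immediate_min]
            if np.mean(imm > thr) < immediate_frac:
                continue
            prev = x[t - quiescence_min:t]
            if np.mean(prev <= thr) < quiescence_frac:
                continue
            found = t
            break
        if found is None:
            logger.info("no onset found in cycle %d", c)
        else:
            onsets.append(found)
    return np.asarray(onsets, dtype=float)


def phase_angle(onsets_min: np.ndarray, trace: ActivityTrace) -> tuple[float, float]:
    """Phase angle of entrainment: mean (onset ZT - 12 h) in hours.

    Positive means the onset follows lights-off.  Undefined (error)
    without a light cycle.  Returns ``(mean_h, sd_h)``.
    """
    if trace.dd or trace.schedule is None:
        raise PolysomError("phase angle undefined in constant darkness")
    if len(onsets_min) < 3:
        raise PolysomError("need at least 3 onsets under LD")
    zt_h = (trace.start_zt_s / 3600.0 + np.asarray(onsets_min) / 60.0) % 24.0
    diff = (zt_h - 12.0 + 12.0) % 24.0 - 12.0   # wrap to (-12, 12]
    return float(diff.mean()), float(diff.std(ddof=1))


def onset_variability(onsets_min: np.ndarray, period_h: float = 24.0) -> float:
    """SD (minutes) of onset residuals around the fitted onset line.

    Fitting onset time against cycle index absorbs any free-running
    drift, so the estimate reflects cycle-to-cycle precision only.
    """
    onsets = np.asarray(onsets_min, dtype=float)
    if len(onsets) < 5:
        raise PolysomError("need at least 5 onsets")
    k = np.floor(onsets / (period_h * 60.0))
    fit = stats.linregress(k, onsets)
    resid = onsets - (fit.intercept + fit.slope * k)
    return float(resid.std(ddof=2))


def phase_shift(onsets_pre_min: np.ndarray, onsets_post_min: np.ndarray,
                pulse_day: float, period_h: float = 24.0,
                exclude_days: int = 2) -> float:
    """Phase shift (hours, negative = delay) induced at ``pulse_day``.

    Pre- and post-pulse onset sequences (absolute minutes on a common
    origin) are each fit with a regression line against cycle index;
    both lines are extrapolated to the pulse day and the shift is their
    gap.  The first ``exclude_days`` cycles after the pulse are dropped
    to skip re-entrainment transients.
    """
    pre = np.asarray(onsets_pre_min, dtype=float)
    post = np.asarray(onsets_post_min, dtype=float)
    p = period_h * 60.0
    k_post = np.floor(post / p)
    keep = k_post >= pulse_day + exclude_days
    post, k_post = post[keep], k_post[keep]
    if len(pre) < 4 or len(post) < 4:
        raise PolysomError("need at least 4 onsets on each side of the pulse")
    k_pre = np.floor(pre / p)
    fit_pre = stats.linregress(k_pre, pre)
    fit_post = stats.linregress(k_post, post)
    pred_pre = fit_pre.intercept + fit_pre.slope * pulse_day
    pred_post = fit_post.intercept + fit_post.slope * pulse_day
    return float((pred_pre - pred_post) / 60.0)


# ---------------------------------------------------------------------------
# Masking on hypnograms
# ---------------------------------------------------------------------------

def pulse_masking(hyp_pulse: Hypnogram, hyp_baseline: Hypnogram,
                  window_zt_h: tuple[float, float]) -> dict[str, float]:
    """State-percentage change in a pulse window vs the same baseline window.

    Returns pulse-window % minus baseline-window % per state (e.g. the
    ZT14-15 light pulse raises NREM, the ZT2-3 dark pulse raises wake).
    """
    if (len(hyp_pulse) != len(hyp_baseline)
            or hyp_pulse.epoch_len_s != hyp_baseline.epoch_len_s):
        raise PolysomError("pulse and baseline days must share the epoch grid")
    a, b = (w * 3600.0 for w in window_zt_h)
    out = {}
    for state in STATES:
        pcts = []
        for hyp in (hyp_pulse, hyp_baseline):
            zt = hyp.epoch_zt_s()
            sel = [lab for lab, t in zip(hyp.labels, zt) if a <= t < b
                   and lab != ARTIFACT]
            pcts.append(100.0 * sum(lab == state for lab in sel) / len(sel))
        out[state] = pcts[0] - pcts[1]
    return out


def ultradian_summary(hyp: Hypnogram, schedule: LightSchedule) -> dict:
    """State totals under a 1 h : 1 h LD cycle.

    Minutes per state summed over all light segments and over all dark
    segments, the 24 h totals, and the light-vs-dark share of each
    state.  Errors unless the schedule alternates 1-h segments.
    """
    starts = [s for s, _ in schedule.segments]
    gaps = np.diff(starts + [schedule.duration_s])
    if not np.allclose(gaps, 3600.0):
        raise PolysomError("ultradian analysis needs an alternating 1h:1h schedule")
    light = {s: 0.0 for s in (*STATES, ARTIFACT)}
    dark = {s: 0.0 for s in (*STATES, ARTIFACT)}
    for (a, b), phase in zip(
            [(s, s + 3600.0) for s, _ in schedule.segments],
            [p for _, p in schedule.segments]):
        tot = phase_totals(hyp, schedule, (a, b))
        target = light if phase == LIGHT else dark
        for s, v in tot.items():
            target[s] += v
    total = {s: light[s] + dark[s] for s in light}
    share = {}
    for s in STATES:
        denom = total[s]
        share[s] = (100.0 * light[s] / denom) if denom else math.nan
    return {"light_min": light, "dark_min": dark, "total_min": total,
            "light_share_pct": share}


def sustained_masking(hyp_ld: Hypnogram, schedule_ld: LightSchedule,
                      hyp_dd: Hypnogram, period_h: float | None,
                      subjective_day_start_s: float = 0.0) -> dict:
    """Sustained masking: LD light-phase sleep vs DD subjective day.

    Compares NREM minutes during the light phase of LD with the DD
    subjective day (first half of each free-running cycle, from the
    periodogram period estimate), wake during the dark phase vs the
    subjective night, and the day-night amplitude of each.  Minutes are
    per cycle (averaged across the cycles available).
    """
    if period_h is None:
        raise PolysomError("need a free-running period estimate to align DD")
    ld_light = phase_totals(hyp_ld, schedule_ld, LIGHT)
    ld_dark = phase_totals(hyp_ld, schedule_ld, DARK)
    n_ld_cycles = max(len(schedule_ld.windows(LIGHT)), 1)

    tau_s = period_h * 3600.0
    half = tau_s / 2.0
    day_windows, night_windows = [], []
    t = subjective_day_start_s
    while t + tau_s <= hyp_dd.duration_s:
        day_windows.append((t, t + half))
        night_windows.append((t + half, t + tau_s))
        t += tau_s
    if not day_windows:
        raise PolysomError("DD hypnogram shorter than one free-running cycle")

    def mean_minutes(windows, state):
        vals = [phase_totals(hyp_dd, schedule_ld, w)[state] for w in windows]
        return float(np.mean(vals))

    ld_nrem_light = ld_light[NREM] / n_ld_cycles
    ld_wake_dark = ld_dark[WAKE] / n_ld_cycles
    dd_nrem_day = mean_minutes(day_windows, NREM)
    dd_wake_night = mean_minutes(night_windows, WAKE)
    amp_ld = ld_nrem_light - ld_dark[NREM] / n_ld_cycles
    amp_dd = dd_nrem_day - mean_minutes(night_windows, NREM)
    return {
        "nrem_light_ld_min": ld_nrem_light,
        "nrem_subjective_day_dd_min": dd_nrem_day,
        "nrem_masking_diff_min": ld_nrem_light - dd_nrem_day,
        "wake_dark_ld_min": ld_wake_dark,
        "wake_subjective_night_dd_min": dd_wake_night,
        "wake_masking_diff_min": ld_wake_dark - dd_wake_night,
        "nrem_amplitude_ld_min": amp_ld,
        "nrem_amplitude_dd_min": amp_dd,
        "amplitude_diff_min": amp_ld - amp_dd,
    }
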