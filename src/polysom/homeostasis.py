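"""Sleep-deprivation accounting and the valence-marker analysis.

Implements sleep lost during an enforced-wake window, cumulative NREM
recovery and its rate, the normalized SD-response ratio

    SD response = recovery NREM / lost NREM
                = recovery NREM / (baseline-window NREM - SD-window NREM),

a state-driven Process-S fit recovering the homeostat time constants
from NREM slow-wave activity, and the Spearman analysis linking the
wake [low theta / high theta] ratio during deprivation to subsequent
NREM rebound.

The recovery window runs from the end of the deprivation window to ZT24
of the same day; multi-day recovery is out of scope.  Group inferential
statistics (ANOVA and post-hoc corrections) are equally out of scope:
functions emit tidy per-animal quantities for external tools.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import NREM, REM, Hypnogram, PolysomError
from .spectral import Spectrogram

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class SDExperiment:
    """Paired baseline/test days around an enforced-wake window.

    ``sd_window_zt_h`` is the half-open ``[start, end)`` deprivation
    window in ZT hours of the test day; ``valence`` labels the waking
    context during the window (POSITIVE = appetitive, NEGATIVE =
    aversive, NONE = plain enriched-environment deprivation).
    """

    baseline_hyp: Hypnogram
    test_hyp: Hypnogram
    sd_window_zt_h: tuple[float, float]
    baseline_spec: Spectrogram | None = None
    test_spec: Spectrogram | None = None
    valence: str = "NONE"
    animal_id: str = "animal0"
    group: str = "control"

    def __post_init__(self):
        b, t = self.baseline_hyp, self.test_hyp
        if len(b) != len(t) or b.epoch_len_s != t.epoch_len_s:
            raise PolysomError("baseline and test days must share the epoch grid")
        a, z = self.sd_window_zt_h
        if not (0 <= a < z <= len(t) * t.epoch_len_s / 3600.0):
            raise PolysomError("SD window must lie within the test day")


def _state_minutes(hyp: Hypnogram, window_zt_h: tuple[float, float],
                   state: str) -> float:
    zt_h = hyp.epoch_zt_s() / 3600.0
    a, b = window_zt_h
    sel = (zt_h >= a) & (zt_h < b)
    n = sum(1 for lab, inside in zip(hyp.labels, sel) if inside and lab == state)
    return n * hyp.epoch_len_s / 60.0


def sleep_lost(exp: SDExperiment) -> tuple[float, float]:
    """NREM minutes lost in the SD window, and as % of the window length.

    Lost = baseline-window NREM - test-window NREM.  A non-positive
    value (animal slept as much as baseline) is returned as-is; the
    SD-response normalization refuses it downstream.
    """
    base = _state_minutes(exp.baseline_hyp, exp.sd_window_zt_h, NREM)
    test = _state_minutes(exp.test_hyp, exp.sd_window_zt_h, NREM)
    lost = base - test
    window_min = (exp.sd_window_zt_h[1] - exp.sd_window_zt_h[0]) * 60.0
    return lost, 100.0 * lost / window_min


def recovery_nrem(exp: SDExperiment, recovery_end_h: float = 24.0) -> float:
    """Total test-day NREM minutes from SD end to ``recovery_end_h``."""
    return _state_minutes(exp.test_hyp, (exp.sd_window_zt_h[1], recovery_end_h), NREM)


def sd_response(exp: SDExperiment, recovery_end_h: float = 24.0):
    """Normalized SD response: recovery NREM over NREM lost during SD.

    Returns ``(total, hourly)`` where ``hourly`` is the cumulative
    recovery NREM through the end of each recovery hour divided by the
    lost minutes (the total equals its last element).
    """
    lost, _ = sleep_lost(exp)
    if lost <= 0:
        raise PolysomError(
            f"SD removed no sleep (lost = {lost:g} min); response undefined")
    start = exp.sd_window_zt_h[1]
    hours = np.arange(math.floor(start) + 1, math.floor(recovery_end_h) + 1, dtype=float)
    cum = np.array([_state_minutes(exp.test_hyp, (start, h), NREM) for h in hours])
    hourly = cum / lost
    total = recovery_nrem(exp, recovery_end_h) / lost
    return total, pd.Series(hourly, index=hours, name="sd_response")


def cumulative_recovery(exp: SDExperiment, recovery_end_h: float = 24.0):
    """Cumulative (test - baseline) NREM difference and its linear rate.

    The series holds, for each whole hour from SD end to ``recovery_end_h``,
    the accumulated NREM difference expressed as % of the 24 h day; the
    recovery rate (% per hour) is the least-squares slope of that series
    against hours since SD end.
    """
    start = exp.sd_window_zt_h[1]
    hours = np.arange(math.floor(start) + 1, math.floor(recovery_end_h) + 1, dtype=float)
    if len(hours) < 3:
        raise PolysomError("need at least 3 recovery hours for a rate")
    diff = np.array([
        _state_minutes(exp.test_hyp, (start, h), NREM)
        - _state_minutes(exp.baseline_hyp, (start, h), NREM)
        for h in hours
    ]) / MINUTES_PER_DAY * 100.0
    fit = stats.linregress(hours - start, diff)
    return pd.Series(diff, index=hours, name="cum_recovery_pct"), float(fit.slope)


def rem_suppression(exp: SDExperiment) -> pd.DataFrame:
    """Hourly REM percentages on test and baseline days plus their difference."""
    n_hours = int(exp.test_hyp.duration_s // 3600)
    rows = []
    for h in range(n_hours):
        window = (float(h), float(h + 1))
        t = _state_minutes(exp.test_hyp, window, REM) / 60.0 * 100.0
        b = _state_minutes(exp.baseline_hyp, window, REM) / 60.0 * 100.0
        rows.append((h, t, b, t - b))
    df = pd.DataFrame(rows, columns=["hour", "test_rem_pct", "baseline_rem_pct",
                                     "diff_pct"])
    return df.set_index("hour")


# ---------------------------------------------------------------------------
# Process-S fit
# ---------------------------------------------------------------------------

def simulate_process_s(labels, epoch_len_s: float, tau_rise_h: float,
                       tau_decay_h: float, s0: float) -> np.ndarray:
    """Saturating-exponential sleep homeostat driven by a label sequence.

    S rises toward 1 during WAKE/REM with time constant ``tau_rise_h``
    and decays toward 0 during NREM with ``tau_decay_h``; the returned
    value is S at the *end* of each epoch.
    """
    dt_rise = epoch_len_s / (tau_rise_h * 3600.0)
    dt_decay = epoch_len_s / (tau_decay_h * 3600.0)
    s = float(s0)
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab == NREM:
            s -= s * dt_decay
        else:  # WAKE, REM and ARTIFACT all accrue sleep pressure
            s += (1.0 - s) * dt_rise
        out[i] = s
    return out


def fit_homeostat(hyp: Hypnogram, swa: np.ndarray,
                  init=(8.0, 2.0, 0.8, 0.5)) -> dict:
    """Fit Process-S time constants to per-epoch NREM slow-wave activity.

    The observation model mirrors how sleep pressure expresses in the
    EEG: NREM delta power density scales as ``A * (1 + g*S)**2`` (an
    amplitude effect, squared into power).  Given the scored hypnogram,
    S is simulated per epoch and ``(tau_rise_h, tau_decay_h, g, s0, A)``
    are found by bounded least squares on the NREM epochs of ``swa``
    (any units; NaN entries ignored).

    A naive exponential fit to the hourly SWA curve conflates the decay
    constant with wake interruptions during recovery; the state-driven
    fit does not.
    """
    labels = hyp.labels
    mask = np.asarray([l == NREM for l in labels]) & np.isfinite(swa)
    if mask.sum() < 30:
        raise PolysomError("too few NREM epochs with SWA to fit the homeostat")
    y = np.asarray(swa, dtype=float)[mask]
    scale0 = float(np.median(y))

    def residuals(theta):
        tau_r, tau_d, g, s0, amp = theta
        s = simulate_process_s(labels, hyp.epoch_len_s, tau_r, tau_d, s0)
        pred = amp * (1.0 + g * s[mask]) ** 2
        return pred - y

    x0 = np.array([init[0], init[1], init[2], init[3], scale0 / (1 + init[2] * 0.5) ** 2])
    res = optimize.least_squares(
        residuals, x0,
        bounds=([0.5, 0.1, 0.0, 0.0, 1e-9], [48.0, 24.0, 10.0, 1.0, np.inf]))
    tau_r, tau_d, g, s0, amp = res.x
    return {"tau_rise_h": float(tau_r), "tau_decay_h": float(tau_d),
            "gain": float(g), "s0": float(s0), "scale": float(amp),
            "cost": float(res.cost)}


# ---------------------------------------------------------------------------
# Valence marker
# ---------------------------------------------------------------------------

def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with average ranks; two-sided p.

    The p-value is by exact permutation of one margin when ``n`` is at
    most ``exact_max_n``, and the usual t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise PolysomError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PolysomError("Spearman rho undefined for a constant margin")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float((rx_c * ry_c[list(perm)]).sum()) / denom
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = hits / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def valence_marker_analysis(cohort: pd.DataFrame) -> dict:
    """Rank correlation between the wake theta-ratio marker and rebound.

    ``cohort`` needs columns ``theta_ratio`` (wake [low/high theta]
    during the SD window), ``recovery_nrem_min`` and ``valence``; one
    row per animal x condition.  Returns per-valence mean ratios plus
    Spearman rho/p over all rows.
    """
    required = {"theta_ratio", "recovery_nrem_min", "valence"}
    if not required.issubset(cohort.columns):
        raise PolysomError(f"cohort needs columns {sorted(required)}")
    if len(cohort) < 5:
        raise PolysomError("need at least 5 animal-condition pairs")
    if (cohort["theta_ratio"] <= 0).any():
        raise PolysomError("theta ratios must be positive")
    rho, p = spearman(cohort["theta_ratio"], cohort["recovery_nrem_min"])
    means = cohort.groupby("valence")["theta_ratio"].mean().to_dict()
    return {"rho": rho, "p": p, "n": len(cohort),
            "mean_ratio_by_valence": means}
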