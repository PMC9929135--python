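"""Sleep-architecture metrics: time-in-state, episodes, transitions, latency.

Fragmentation is captured by run-length episodes (an episode is a
maximal run of one state), their duration histogram with a named
"<8 min" aggregate of short episodes, and the ordered transition table.
ARTIFACT epochs break episodes rather than bridging them — conservative
for fragmentation — and are excluded from percentage denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (ARTIFACT, DARK, LIGHT, NREM, REM, STATES, WAKE, Hypnogram,
                 LightSchedule, PolysomError)


@dataclass(frozen=True)
class Bout:
    state: str
    start_epoch: int
    n_epochs: int
    duration_s: float


def episodes(hyp: Hypnogram) -> list[Bout]:
    """Run-length episodes; ARTIFACT epochs split runs and join no bout."""
    bouts = []
    start = None
    current = None
    for i, lab in enumerate(list(hyp.labels) + [None]):  # sentinel flush
        if lab != current:
            if current is not None and current != ARTIFACT:
                n = i - start
                bouts.append(Bout(current, start, n, n * hyp.epoch_len_s))
            start, current = i, lab
    return bouts


def episode_stats(bouts: list[Bout]) -> pd.DataFrame:
    """Per-state episode count and mean duration (minutes)."""
    rows = []
    for state in STATES:
        durs = [b.duration_s for b in bouts if b.state == state]
        rows.append((state, len(durs),
                     np.mean(durs) / 60.0 if durs else np.nan))
    return pd.DataFrame(rows, columns=["state", "n_episodes",
                                       "mean_duration_min"]).set_index("state")


def episode_histogram(bouts: list[Bout], state: str,
                      edges_min=(0.5, 1, 2, 4, 8, 16, 32)) -> dict:
    """Episode counts per duration class, plus the "<8 min" aggregate.

    Classes are ``[0, e0), [e0, e1), ..., [e_last, inf)``; their counts
    sum to the state's total episode count.
    """
    edges = list(edges_min)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise PolysomError("histogram edges must be strictly increasing")
    bounds = [0.0] + edges + [math.inf]
    counts = [0] * (len(bounds) - 1)
    short = 0
    for b in bouts:
        if b.state != state:
            continue
        d = b.duration_s / 60.0
        for j in range(len(counts)):
            if bounds[j] <= d < bounds[j + 1]:
                counts[j] += 1
                break
        if d < 8.0:
            short += 1
    labels = [f"[{bounds[j]:g},{bounds[j+1]:g})" for j in range(len(counts))]
    return {"classes": labels, "counts": counts, "short_lt_8min": short}


def transitions(hyp: Hypnogram) -> pd.DataFrame:
    """Ordered transition counts between adjacent non-ARTIFACT epochs."""
    table = {(a, b): 0 for a in STATES for b in STATES if a != b}
    labs = hyp.labels
    for i in range(1, len(labs)):
        a, b = labs[i - 1], labs[i]
        if a != b and a != ARTIFACT and b != ARTIFACT:
            table[(a, b)] += 1
    df = pd.DataFrame(0, index=list(STATES), columns=list(STATES))
    for (a, b), c in table.items():
        df.loc[a, b] = c
    return df


def hourly_state_percent(hyp: Hypnogram) -> pd.DataFrame:
    """Per ZT-aligned hour: % of non-ARTIFACT epochs in each state.

    The three states sum to 100 per hour; an hour that is entirely
    ARTIFACT is missing (NaN).
    """
    if hyp.duration_s < 3600:
        raise PolysomError("hypnogram must span at least one whole hour")
    hours = (hyp.epoch_zt_s() // 3600).astype(int)
    rows = {}
    for h in range(hours[0], hours[-1] + 1):
        sel = [lab for lab, hh in zip(hyp.labels, hours) if hh == h]
        if len(sel) * hyp.epoch_len_s < 3600:
            continue  # partial trailing hour
        valid = [lab for lab in sel if lab != ARTIFACT]
        if not valid:
            rows[h] = {s: np.nan for s in STATES}
        else:
            rows[h] = {s: 100.0 * sum(lab == s for lab in valid) / len(valid)
                       for s in STATES}
    return pd.DataFrame.from_dict(rows, orient="index")[list(STATES)]


@dataclass(frozen=True)
class SleepLatency:
    latency_s: float           # inf when censored
    censored: bool
    total_sleep_pct: float     # NREM+REM % of the scoring window
    total_nrem_pct: float


def sleep_latency(hyp: Hypnogram, stimulus_time_s: float,
                  window_s: float = 3600.0) -> SleepLatency:
    """Latency from a stimulus to consolidated NREM onset.

    Consolidated onset is the first run of at least two consecutive
    NREM epochs (a 20-s criterion realized on the 10-s epoch grid) at
    or after the stimulus; an isolated single NREM epoch does not
    count.  The onset epoch must start inside the scoring window; its
    consolidating second epoch may extend past it.  If no onset occurs
    the latency is censored (+inf) but the window's sleep percentages
    are still reported.
    """
    if hyp.epoch_len_s != 10.0:
        raise PolysomError("the 20-s onset criterion requires 10-s epochs")
    if not (0 <= stimulus_time_s <= hyp.duration_s):
        raise PolysomError("stimulus time outside hypnogram")
    first = math.ceil(stimulus_time_s / hyp.epoch_len_s)
    last = min(len(hyp), int((stimulus_time_s + window_s) / hyp.epoch_len_s))
    window = hyp.labels[first:last]
    latency = math.inf
    for i in range(first, min(last, len(hyp) - 1)):
        if hyp.labels[i] == NREM and hyp.labels[i + 1] == NREM:
            latency = i * hyp.epoch_len_s - stimulus_time_s
            break
    n = len(window)
    sleep = sum(lab in (NREM, REM) for lab in window)
    nrem = sum(lab == NREM for lab in window)
    return SleepLatency(latency, math.isinf(latency),
                        100.0 * sleep / n if n else math.nan,
                        100.0 * nrem / n if n else math.nan)


def phase_totals(hyp: Hypnogram, schedule: LightSchedule,
                 phase) -> dict[str, float]:
    """Minutes per state within a light phase or explicit time window.

    ``phase`` is ``"LIGHT"``, ``"DARK"``, or a ``(start_s, end_s)``
    window in recording time.  State minutes plus ARTIFACT minutes sum
    to the covered span.
    """
    if phase in (LIGHT, DARK):
        windows = schedule.windows(phase)
    else:
        windows = [tuple(phase)]
    counts = {s: 0 for s in (*STATES, ARTIFACT)}   # integer epochs: exact
    times = hyp.epoch_times_s()
    for a, b in windows:
        for lab, t in zip(hyp.labels, times):
            if a <= t < b:
                counts[lab] += 1
    return {s: n * hyp.epoch_len_s / 60.0 for s, n in counts.items()}
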