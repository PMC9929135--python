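"""Synthetic polysomnography and actigraphy with known ground truth.

The generator produces the statistical structure the downstream analyses
assume, so every pipeline stage is testable without animal data:

* a semi-Markov vigilance chain (explicit exponential-like bout-length
  draws, so bout-duration histograms are directly controllable) with
  light-phase-dependent and circadian-modulated propensities, REM
  entered only from NREM;
* a saturating-exponential sleep homeostat S in [0, 1] (rising during
  wake/REM, decaying during NREM) that scales NREM delta amplitude by
  ``1 + gain * S``;
* EEG/EMG signals built per epoch from 1/f^alpha background noise plus
  band-limited state components, or, for cohort-scale experiments,
  per-epoch spectrograms drawn parametrically around the same expected
  power densities;
* enforced-wake (sleep deprivation) windows with residual-sleep leak,
  valence-dependent wake theta composition and rebound gain;
* free-running rest/activity rhythms with configurable period and onset
  jitter, and acute light/dark masking of vigilance states.

Identical seed and config give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import (ARTIFACT, DARK, LIGHT, NREM, REM, WAKE, ActivityTrace,
                 Hypnogram, LightSchedule, PolysomError, Recording,
                 SECONDS_PER_HOUR)
from .homeostasis import SDExperiment, simulate_process_s
from .spectral import Spectrogram

logger = logging.getLogger("polysom")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of the synthetic sleep study.

    Defaults emulate an adult laboratory mouse entrained to 12:12 LD:
    roughly half the day awake (mostly in the dark phase), ~45% NREM,
    ~4% REM, minutes-scale bouts, a two-process homeostat with fast
    dissipation, and nocturnal locomotor activity.
    """

    epoch_len_s: float = 10.0
    fs: float = 128.0

    # mean bout lengths (s) per state and light phase of the entrained cycle
    bout_mean_s: dict = field(default_factory=lambda: {
        WAKE: {LIGHT: 300.0, DARK: 900.0},
        NREM: {LIGHT: 480.0, DARK: 300.0},
        REM: {LIGHT: 100.0, DARK: 100.0},
    })
    #: circadian modulation of wake-bout length (unitless, >= 0);
    #: multiplier 1 + amp*sin(2*pi*(zt-12)/24) peaks mid-dark (ZT18)
    circadian_amp: float = 0.3
    rem_entry_prob: float = 0.35       # NREM -> REM, else NREM -> WAKE
    rem_to_wake_prob: float = 0.6      # REM -> WAKE, else REM -> NREM

    # genotype multipliers (hypodopaminergic phenotype: shorter wake
    # bouts, fewer REM entries, more transitions)
    wake_bout_factor: float = 1.0
    rem_entry_factor: float = 1.0
    transition_rate_factor: float = 1.0

    # homeostat
    tau_rise_h: float = 8.0
    tau_decay_h: float = 2.0
    s0: float = 0.5
    gain: float = 0.8                  # NREM delta amplitude = base*(1+gain*S)

    # spectral templates: state -> list of (name, center Hz, bandwidth Hz,
    # amplitude uV); plus a shared 1/f^alpha background
    templates: dict = field(default_factory=lambda: {
        WAKE: [("low_theta", 6.0, 1.5, 18.0), ("high_theta", 9.5, 1.5, 18.0)],
        NREM: [("delta", 2.0, 1.5, 45.0)],
        REM: [("theta", 7.0, 1.0, 35.0)],
    })
    background_alpha: float = 1.0
    background_amp_uv: float = 10.0    # RMS of the 1/f^alpha background

    emg_rms_uv: dict = field(default_factory=lambda: {
        WAKE: 25.0, NREM: 8.0, REM: 3.0, ARTIFACT: 8.0,
    })

    # sleep deprivation / valence
    sd_leak: float = 0.05              # residual-sleep probability per epoch
    pos_high_theta_mult: float = 1.6   # appetitive wake boosts high theta
    neg_low_theta_mult: float = 1.6    # aversive wake boosts low theta
    rebound_gain_pos: float = 1.2
    rebound_gain_neg: float = 1.8
    rebound_gain_none: float = 1.4
    rem_rebound_factor_neg: float = 0.4   # aversive SD suppresses REM after

    # masking
    p_light_to_sleep: float = 0.6      # P(wake epoch -> NREM | light pulse)
    p_dark_to_wake: float = 0.6        # P(sleep epoch -> WAKE | dark pulse)

    # actigraphy
    tau_dd_h: float = 23.8             # free-running period in DD
    onset_jitter_sd_min: float = 10.0
    phase_angle_h: float = 0.25        # activity onset this long after lights-off
    activity_amp: float = 12.0         # Poisson rate in the active phase
    activity_base: float = 0.5         # Poisson rate in the rest phase
    pulse_delta_phi_h: float = -0.8    # phase shift applied by a light pulse

    seed: int = 0

    def __post_init__(self):
        for p in (self.rem_entry_prob, self.rem_to_wake_prob, self.sd_leak,
                  self.p_light_to_sleep, self.p_dark_to_wake):
            if not 0 <= p <= 1:
                raise PolysomError("probabilities must lie in [0, 1]")
        for state, phases in self.bout_mean_s.items():
            for mean in phases.values():
                if mean <= self.epoch_len_s:
                    raise PolysomError(
                        f"{state} mean bout length must exceed one epoch")
        if self.tau_rise_h <= 0 or self.tau_decay_h <= 0:
            raise PolysomError("homeostat time constants must be positive")
        if not 0 <= self.s0 <= 1:
            raise PolysomError("s0 must lie in [0, 1]")
        if self.circadian_amp < 0:
            raise PolysomError("circadian amplitude must be >= 0")

    def mitopark(self) -> "SimConfig":
        """Hypodopaminergic preset: fragmented wake, hypersomnia, less REM."""
        return replace(self, wake_bout_factor=0.55, rem_entry_factor=0.5,
                       transition_rate_factor=1.3)


# ---------------------------------------------------------------------------
# Hypnogram chain
# ---------------------------------------------------------------------------

def _bout_mean_epochs(config: SimConfig, state: str, zt_h: float,
                      nrem_gain: float) -> float:
    phase = LIGHT if (zt_h % 24.0) < 12.0 else DARK
    mean_s = config.bout_mean_s[state][phase]
    if state == WAKE:
        mean_s *= config.wake_bout_factor
        mean_s *= 1.0 + config.circadian_amp * np.sin(
            2 * np.pi * ((zt_h % 24.0) - 12.0) / 24.0)
        mean_s /= config.transition_rate_factor * nrem_gain
    elif state == NREM:
        mean_s *= nrem_gain / config.transition_rate_factor
    return max(mean_s, config.epoch_len_s) / config.epoch_len_s


def _simulate_labels(config: SimConfig, n_epochs: int, rng: np.random.Generator,
                     start_zt_h: float = 0.0,
                     nrem_gain_fn=None) -> list[str]:
    """Semi-Markov chain over {WAKE, NREM, REM} with bout-length draws."""
    p_rem = min(config.rem_entry_prob * config.rem_entry_factor, 1.0)
    if all(v == 0 for ph in config.bout_mean_s.values() for v in ph.values()):
        raise PolysomError("degenerate config: all propensities zero")
    labels: list[str] = []
    state = WAKE
    i = 0
    while i < n_epochs:
        zt = start_zt_h + i * config.epoch_len_s / SECONDS_PER_HOUR
        gain = nrem_gain_fn(zt) if nrem_gain_fn is not None else 1.0
        mean_ep = _bout_mean_epochs(config, state, zt, gain)
        length = int(rng.geometric(min(1.0, 1.0 / mean_ep)))
        length = min(length, n_epochs - i)
        labels.extend([state] * length)
        i += length
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if rng.random() < p_rem else WAKE
        else:
            state = WAKE if rng.random() < config.rem_to_wake_prob else NREM
    return labels


def apply_masking(labels: list[str], schedule: LightSchedule,
                  config: SimConfig, rng: np.random.Generator,
                  epoch_len_s: float, start_zt_s: float = 0.0) -> list[str]:
    """Acute masking: resample epochs where light contradicts the entrained phase.

    A lit epoch falling in the entrained dark phase (a light pulse) turns
    WAKE into NREM with probability ``p_light_to_sleep``; a dark epoch in
    the entrained light phase (a dark pulse) turns sleep into WAKE with
    probability ``p_dark_to_wake``.
    """
    out = list(labels)
    for i, lab in enumerate(out):
        t = i * epoch_len_s
        zt = ((start_zt_s + t) / SECONDS_PER_HOUR) % 24.0
        entrained = LIGHT if zt < 12.0 else DARK
        actual = schedule.state_at(min(t, schedule.duration_s))
        if actual == entrained:
            continue
        if actual == LIGHT and lab == WAKE:
            if rng.random() < config.p_light_to_sleep:
                out[i] = NREM
        elif actual == DARK and lab in (NREM, REM):
            if rng.random() < config.p_dark_to_wake:
                out[i] = WAKE
    return out


def simulate_hypnogram(config: SimConfig, n_hours: float, seed: int | None = None,
                       start_zt_h: float = 0.0,
                       schedule: LightSchedule | None = None):
    """Ground-truth hypnogram plus the latent homeostat trajectory.

    Returns ``(Hypnogram, S)`` where ``S[i]`` is sleep pressure at the
    end of epoch ``i``.  If ``schedule`` deviates from the entrained
    12:12 cycle (light or dark pulses, ultradian LD), acute masking is
    applied epoch-wise before S is computed.
    """
    if n_hours < 1:
        raise PolysomError("simulate at least 1 hour")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_epochs = int(round(n_hours * SECONDS_PER_HOUR / config.epoch_len_s))
    labels = _simulate_labels(config, n_epochs, rng, start_zt_h)
    if schedule is not None:
        labels = apply_masking(labels, schedule, config, rng,
                               config.epoch_len_s,
                               start_zt_s=start_zt_h * SECONDS_PER_HOUR)
    s = simulate_process_s(labels, config.epoch_len_s, config.tau_rise_h,
                           config.tau_decay_h, config.s0)
    hyp = Hypnogram(tuple(labels), config.epoch_len_s,
                    start_zt_s=start_zt_h * SECONDS_PER_HOUR)
    return hyp, s


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------

def _pink_background(n: int, fs: float, alpha: float, rms: float,
                     rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def simulate_signals(hyp: Hypnogram, s_traj: np.ndarray, config: SimConfig,
                     seed: int | None = None,
                     component_scale: dict[str, np.ndarray] | None = None,
                     xfade_s: float = 0.5) -> Recording:
    """EEG/EMG signals realizing a hypnogram.

    Per epoch the EEG is the shared 1/f^alpha Gaussian background plus
    the state template's band-limited sinusoidal components (frequency
    jittered within the component bandwidth, random phase), with the
    NREM delta amplitude scaled by ``1 + gain*S``.  Components and the
    EMG envelope are faded in/out over ``xfade_s`` at epoch boundaries
    so the trace stays continuous.  ``component_scale`` optionally maps
    a component name to a per-epoch amplitude multiplier (used for the
    valence theta shifts).
    """
    if len(hyp) == 0:
        raise PolysomError("empty hypnogram")
    nyq = config.fs / 2.0
    for comps in config.templates.values():
        for _, center, bw, _amp in comps:
            if center + bw / 2.0 >= nyq:
                raise PolysomError(
                    f"fs={config.fs} Hz too low for a component at "
                    f"{center}+-{bw / 2} Hz")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spe = int(round(hyp.epoch_len_s * config.fs))
    n = spe * len(hyp)
    eeg = _pink_background(n, config.fs, config.background_alpha,
                           config.background_amp_uv, rng)

    taper = sps.windows.tukey(spe, alpha=min(1.0, 2 * xfade_s / hyp.epoch_len_s))
    t = np.arange(spe) / config.fs
    env = np.empty(n)
    for i, lab in enumerate(hyp.labels):
        sl = slice(i * spe, (i + 1) * spe)
        for name, center, bw, amp in config.templates.get(lab, ()):
            if lab == NREM and name == "delta":
                amp = amp * (1.0 + config.gain * s_traj[i])
            if component_scale and name in component_scale:
                amp = amp * component_scale[name][i]
            f = center + (rng.random() - 0.5) * bw
            phase = rng.random() * 2 * np.pi
            eeg[sl] += amp * np.sin(2 * np.pi * f * (t + i * hyp.epoch_len_s)
                                    + phase) * taper
        env[sl] = config.emg_rms_uv[lab]
    w = max(int(round(xfade_s * config.fs)), 1)
    env = np.convolve(env, np.ones(w) / w, mode="same")
    emg = rng.standard_normal(n) * env
    schedule = LightSchedule.ld_12_12(n / config.fs, start_zt_s=hyp.start_zt_s)
    return Recording(eeg=eeg, emg=emg, fs=config.fs, schedule=schedule,
                     start_zt_s=hyp.start_zt_s)


# ---------------------------------------------------------------------------
# Parametric spectrograms
# ---------------------------------------------------------------------------

def _expected_psd(config: SimConfig, state: str, s: float,
                  centers: np.ndarray,
                  comp_mults: dict[str, float] | None = None) -> np.ndarray:
    # background: PSD = c / f^alpha with total variance background_amp^2
    # over the simulated band
    f = centers
    alpha = config.background_alpha
    weight = f ** (-alpha)
    c = config.background_amp_uv ** 2 / np.sum(weight * 0.5)
    psd = c * weight
    for name, center, bw, amp in config.templates.get(state, ()):
        if state == NREM and name == "delta":
            amp = amp * (1.0 + config.gain * s)
        if comp_mults and name in comp_mults:
            amp = amp * comp_mults[name]
        sel = (f >= center - bw / 2.0 - 0.25) & (f <= center + bw / 2.0 + 0.25)
        width = max(sel.sum() * 0.5, 0.5)
        psd[sel] += (amp ** 2 / 2.0) / width
    return psd


def spectrogram_from_templates(hyp: Hypnogram, s_traj: np.ndarray,
                               config: SimConfig, seed: int | None = None,
                               fmax: float = 50.0,
                               comp_mults_per_epoch=None) -> Spectrogram:
    """Draw per-epoch spectra around the template expectation.

    Each 0.5 Hz bin of a 10-s Hann periodogram is the mean of five
    chi-squared(2) native bins, so bins are drawn as the expected PSD
    times Gamma(k=5, scale=1/5) multiplicative noise.  This is the fast
    cohort-scale path; it matches the statistics of the signal-synthesis
    plus FFT route that downstream analyses consume.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    centers = np.arange(1, int(round(2 * fmax)) + 1) * 0.5
    power = np.empty((len(hyp), len(centers)))
    for i, lab in enumerate(hyp.labels):
        state = lab if lab != ARTIFACT else WAKE
        mults = comp_mults_per_epoch(i) if comp_mults_per_epoch else None
        mean = _expected_psd(config, state, s_traj[i], centers, mults)
        power[i] = mean * rng.gamma(5.0, 1.0 / 5.0, size=len(centers))
    return Spectrogram(power, centers, hyp.epoch_len_s)


# ---------------------------------------------------------------------------
# Sleep-deprivation experiments
# ---------------------------------------------------------------------------

def simulate_sd_experiment(config: SimConfig, sd_start_zt_h: float = 0.0,
                           sd_len_h: float = 6.0, valence: str = "NONE",
                           seed: int | None = None, fmax: float = 64.0,
                           with_spectra: bool = True) -> SDExperiment:
    """Two-day experiment: baseline day, then a day with enforced wake.

    During the deprivation window any sleep epoch is resampled as WAKE
    with probability ``1 - sd_leak``; afterwards the NREM propensity is
    multiplied by the valence's rebound gain.  Wake EEG during the
    window uses the valence-shifted theta composition; under NEGATIVE
    valence REM entry is additionally suppressed during recovery.
    """
    if valence not in ("POSITIVE", "NEGATIVE", "NONE"):
        raise PolysomError(f"unknown valence {valence!r}")
    if not (0 <= sd_start_zt_h < sd_start_zt_h + sd_len_h <= 24):
        raise PolysomError("SD window must lie within the test day")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_epochs_day = int(round(24 * SECONDS_PER_HOUR / config.epoch_len_s))

    base_labels = _simulate_labels(config, n_epochs_day, rng)

    gain = {"POSITIVE": config.rebound_gain_pos,
            "NEGATIVE": config.rebound_gain_neg,
            "NONE": config.rebound_gain_none}[valence]
    sd_end = sd_start_zt_h + sd_len_h

    def nrem_gain_fn(zt_h):
        return gain if zt_h >= sd_end else 1.0

    cfg_test = config
    if valence == "NEGATIVE":
        cfg_test = replace(config,
                           rem_entry_factor=config.rem_entry_factor
                           * config.rem_rebound_factor_neg)
    test_labels = _simulate_labels(cfg_test, n_epochs_day, rng,
                                   nrem_gain_fn=nrem_gain_fn)

    epoch_h = config.epoch_len_s / SECONDS_PER_HOUR
    in_window = np.array([sd_start_zt_h <= i * epoch_h < sd_end
                          for i in range(n_epochs_day)])
    for i in np.flatnonzero(in_window):
        if test_labels[i] in (NREM, REM) and rng.random() >= config.sd_leak:
            test_labels[i] = WAKE

    # S runs continuously across the two days
    s_all = simulate_process_s(base_labels + test_labels, config.epoch_len_s,
                               config.tau_rise_h, config.tau_decay_h, config.s0)
    s_base, s_test = s_all[:n_epochs_day], s_all[n_epochs_day:]

    base_hyp = Hypnogram(tuple(base_labels), config.epoch_len_s)
    test_hyp = Hypnogram(tuple(test_labels), config.epoch_len_s)

    base_spec = test_spec = None
    if with_spectra:
        theta_mults = {}
        if valence == "POSITIVE":
            theta_mults = {"high_theta": config.pos_high_theta_mult}
        elif valence == "NEGATIVE":
            theta_mults = {"low_theta": config.neg_low_theta_mult}

        def mults_fn(i):
            if in_window[i] and test_labels[i] == WAKE:
                return theta_mults
            return None

        base_spec = spectrogram_from_templates(
            base_hyp, s_base, config, seed=int(rng.integers(2 ** 31)), fmax=fmax)
        test_spec = spectrogram_from_templates(
            test_hyp, s_test, config, seed=int(rng.integers(2 ** 31)), fmax=fmax,
            comp_mults_per_epoch=mults_fn)

    return SDExperiment(base_hyp, test_hyp, (sd_start_zt_h, sd_end),
                        baseline_spec=base_spec, test_spec=test_spec,
                        valence=valence)


def simulate_marker_cohort(n: int = 17, intercept_min: float = 250.0,
                           slope_min: float = 200.0, noise_sd_min: float = 20.0,
                           ratio_mean: float = 1.2, ratio_sd: float = 0.3,
                           seed: int = 0, group: str = "control") -> pd.DataFrame:
    """Statistical cohort: rebound = a + b * theta_ratio + noise.

    Direct generator of per-animal marker/rebound pairs for calibrating
    the Spearman analysis (a flat cohort is obtained with ``slope_min=0``).
    Ratios are lognormal around ``ratio_mean``; the lower half of the
    cohort is labelled POSITIVE and the upper half NEGATIVE, mirroring
    the ratio separation between appetitive and aversive deprivation.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p((ratio_sd / ratio_mean) ** 2))
    mu = np.log(ratio_mean) - sigma ** 2 / 2
    ratios = rng.lognormal(mu, sigma, size=n)
    rebound = intercept_min + slope_min * ratios + rng.normal(0, noise_sd_min, n)
    valence = np.where(ratios < np.median(ratios), "POSITIVE", "NEGATIVE")
    return pd.DataFrame({
        "animal_id": [f"{group}{i:02d}" for i in range(n)],
        "theta_ratio": ratios,
        "recovery_nrem_min": rebound,
        "valence": valence,
        "group": group,
    })


# ---------------------------------------------------------------------------
# Actigraphy
# ---------------------------------------------------------------------------

def simulate_activity(config: SimConfig, n_days: int, regime: str = "LD",
                      seed: int | None = None, pulse_day: int | None = None,
                      n_ld_days: int | None = None) -> ActivityTrace:
    """1-min-binned locomotor counts under LD, DD, LD->DD or a pulse regime.

    Counts are Poisson around a rest/active square profile (duty cycle
    one half period); the daily activity onset is jittered with the
    configured SD.  Under ``LIGHT_PULSE`` a light pulse on ``pulse_day``
    applies the configured phase shift to all subsequent cycles.
    """
    if n_days < 3:
        raise PolysomError("simulate at least 3 days of activity")
    if not (20.0 < config.tau_dd_h < 28.0):
        raise PolysomError("tau_dd_h must lie in (20, 28) h for the periodogram")
    if regime not in ("LD", "DD", "LD_then_DD", "LIGHT_PULSE"):
        raise PolysomError(f"unknown activity regime {regime!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_min = n_days * 1440
    lam = np.full(n_min, config.activity_base, dtype=float)

    if regime == "LD_then_DD":
        n_ld = n_ld_days if n_ld_days is not None else n_days // 2
    elif regime == "DD":
        n_ld = 0
    else:
        n_ld = n_days

    onset0 = (12.0 + config.phase_angle_h) * 60.0
    onset = onset0
    cycle_start = 0.0
    k = 0
    while cycle_start < n_min:
        period_min = (24.0 if k < n_ld else config.tau_dd_h) * 60.0
        jitter = rng.normal(0.0, config.onset_jitter_sd_min)
        shift = 0.0
        if regime == "LIGHT_PULSE" and pulse_day is not None and k > pulse_day:
            shift = -config.pulse_delta_phi_h * 60.0  # delay -> later onset
        a = int(round(onset + jitter + shift))
        b = int(round(a + period_min / 2.0))
        lam[max(a, 0):min(b, n_min)] += config.activity_amp
        onset += period_min
        cycle_start += period_min
        k += 1

    counts = rng.poisson(lam)
    if regime in ("LD", "LIGHT_PULSE"):
        schedule = LightSchedule.ld_12_12(n_min * 60.0)
        dd = False
    elif regime == "DD":
        schedule = None
        dd = True
    else:
        schedule = LightSchedule.ld_12_12(n_ld * 1440 * 60.0)
        dd = False
    return ActivityTrace(counts, schedule=schedule, dd=dd)
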