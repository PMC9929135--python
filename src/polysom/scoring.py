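"""Rule-based three-state vigilance scoring of 10-s EEG/EMG epochs.

Wakefulness shows desynchronized low-amplitude EEG with high muscle
tone; NREM sleep shows high-amplitude slow (delta) waves with reduced
tone; REM sleep shows a dominant theta rhythm with muscle atonia.  The
classifier is an explicit, auditable decision cascade over per-epoch
features:

1. ``emg_rms >= emg_wake_thresh``                       -> WAKE
2. else ``delta/total >= delta_frac_nrem_thresh``       -> NREM
3. else ``theta/delta >= theta_delta_rem_thresh`` and
        ``emg_rms <= emg_rem_max``                      -> REM
4. else NREM (flagged ambiguous, count logged)

followed by minimal post-smoothing: a single epoch flanked by two
identical states takes the flanking state, and REM immediately after
WAKE becomes NREM (REM is entered from NREM in rodents).  Smoothing is
limited to single-epoch islands so genuinely short bouts — the object
of the fragmentation analysis — survive.

Thresholds may be fixed or calibrated per animal from feature
quantiles; accuracy against simulated ground truth is the module's
validation contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import NREM, REM, WAKE, Hypnogram, PolysomError, Recording
from . import spectral

logger = logging.getLogger("polysom")

FIXED = "FIXED"
PER_ANIMAL_QUANTILE = "PER_ANIMAL_QUANTILE"

#: scoring bands (Hz): delta and the 6-9 Hz theta convention
DELTA = spectral.band("delta")
THETA = spectral.band("theta")
TOTAL = spectral.BandDefinition("total", 0.75, 50.0)


def compute_epoch_features(recording: Recording,
                           epoch_len_s: float = 10.0) -> pd.DataFrame:
    """Per-epoch scoring features.

    Band powers come from the spectral module's per-epoch spectra
    (delta 0.75-4 Hz, theta 6-9 Hz, total 0.75-50 Hz); the EMG is
    band-passed 5-30 Hz before the per-epoch RMS; ``eeg_amplitude``
    is a robust SD (1.4826 * median absolute deviation).
    """
    rec = recording.truncated_to_epochs(epoch_len_s)
    fmax = min(50.0, rec.fs / 2.0)
    spec = spectral.epoch_spectrogram(rec, epoch_len_s, fmax=fmax)
    total_band = spectral.BandDefinition("total", 0.75, fmax)
    delta = spectral.band_power(spec.power, DELTA, spec.bin_centers)
    theta = spectral.band_power(spec.power, THETA, spec.bin_centers)
    total = spectral.band_power(spec.power, total_band, spec.bin_centers)

    hi = min(30.0, rec.fs / 2.0 * 0.95)
    sos = sps.butter(4, [5.0, hi], btype="bandpass", fs=rec.fs, output="sos")
    emg_f = sps.sosfiltfilt(sos, rec.emg)
    spe = int(round(epoch_len_s * rec.fs))
    n = len(emg_f) // spe
    emg_ep = emg_f[: n * spe].reshape(n, spe)
    emg_rms = np.sqrt(np.mean(emg_ep ** 2, axis=1))

    eeg_ep = np.asarray(rec.eeg[: n * spe]).reshape(n, spe)
    mad = np.median(np.abs(eeg_ep - np.median(eeg_ep, axis=1, keepdims=True)),
                    axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.nan)
    return pd.DataFrame({
        "delta_power": delta,
        "theta_power": theta,
        "total_power": total,
        "theta_delta_ratio": ratio,
        "emg_rms": emg_rms,
        "eeg_amplitude": 1.4826 * mad,
    })


@dataclass(frozen=True)
class ScoringThresholds:
    emg_wake_thresh: float = 10.0
    delta_frac_nrem_thresh: float = 2.0
    theta_delta_rem_thresh: float = 1.5
    emg_rem_max: float = 3.5
    mode: str = FIXED

    def __post_init__(self):
        vals = (self.emg_wake_thresh, self.delta_frac_nrem_thresh,
                self.theta_delta_rem_thresh, self.emg_rem_max)
        if any(v <= 0 for v in vals):
            raise PolysomError("scoring thresholds must be strictly positive")
        if self.emg_rem_max >= self.emg_wake_thresh:
            raise PolysomError(
                "REM rule unreachable: emg_rem_max must be below emg_wake_thresh")


def score_epochs(features: pd.DataFrame,
                 thresholds: ScoringThresholds | None = None,
                 epoch_len_s: float = 10.0,
                 start_zt_s: float = 0.0) -> Hypnogram:
    """Score features into a WAKE/NREM/REM hypnogram (cascade + smoothing)."""
    if thresholds is None:
        thresholds = ScoringThresholds()
    if len(features) == 0:
        raise PolysomError("no epochs to score")
    emg = features["emg_rms"].to_numpy()
    delta_frac = features["delta_power"].to_numpy() / features["total_power"].to_numpy()
    ratio = features["theta_delta_ratio"].to_numpy()

    labels = np.full(len(features), NREM, dtype=object)
    ambiguous = 0
    for i in range(len(features)):
        if emg[i] >= thresholds.emg_wake_thresh:
            labels[i] = WAKE
        elif delta_frac[i] >= thresholds.delta_frac_nrem_thresh:
            labels[i] = NREM
        elif (np.isfinite(ratio[i]) and ratio[i] >= thresholds.theta_delta_rem_thresh
              and emg[i] <= thresholds.emg_rem_max):
            labels[i] = REM
        else:
            labels[i] = NREM
            ambiguous += 1
    if ambiguous:
        logger.info("scoring: %d/%d epochs ambiguous, defaulted to NREM",
                    ambiguous, len(features))

    # isolated single-epoch islands take the flanking state
    for i in range(1, len(labels) - 1):
        if labels[i - 1] == labels[i + 1] != labels[i]:
            labels[i] = labels[i - 1]
    # REM cannot follow WAKE directly
    for i in range(1, len(labels)):
        if labels[i] == REM and labels[i - 1] == WAKE:
            labels[i] = NREM
    return Hypnogram(tuple(labels), epoch_len_s, start_zt_s=start_zt_s)


def _two_means_split(values: np.ndarray) -> tuple[float, float]:
    """Exact 1-D two-class k-means: the split minimizing within-class SSE.

    Returns ``(threshold, separation)`` where the threshold is the
    midpoint of the two class means and separation is their gap in
    units of the pooled within-class SD.  Splitting a unimodal Gaussian
    yields a separation near 2.7 whatever its scale; clearly bimodal
    data scores far higher.
    """
    x = np.sort(values[np.isfinite(values)])
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x ** 2)
    best, best_cost = None, np.inf
    for k in range(1, n):  # left class = x[:k]
        left = csq[k - 1] - csum[k - 1] ** 2 / k
        right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        cost = left + right
        if cost < best_cost:
            best_cost, best = cost, k
    m1 = csum[best - 1] / best
    m2 = (csum[-1] - csum[best - 1]) / (n - best)
    within_sd = max(np.sqrt(best_cost / n), 1e-12)
    return (m1 + m2) / 2.0, (m2 - m1) / within_sd


def calibrate_thresholds(features: pd.DataFrame,
                         mode: str = PER_ANIMAL_QUANTILE,
                         epoch_len_s: float = 10.0) -> ScoringThresholds:
    """Per-animal thresholds from feature quantiles.

    Both the EMG wake threshold and the delta-fraction threshold are
    two-class 1-D k-means splits (of log epoch RMS and of delta/total
    respectively — quantile-equivariant, so doubling all EMG doubles
    the threshold); the REM EMG ceiling is half the muscle-quiet class
    mean.  Degenerate (unimodal) features fall back to fixed defaults
    with a warning.  Deterministic given features.
    """
    if mode == FIXED:
        return ScoringThresholds()
    if len(features) * epoch_len_s < 6 * 3600:
        raise PolysomError("calibration needs at least 6 h of features")
    emg = features["emg_rms"].to_numpy()
    delta_frac = (features["delta_power"] / features["total_power"]).to_numpy()
    df_thresh, separation = _two_means_split(np.log(delta_frac))
    df_thresh = float(np.exp(df_thresh))
    if separation < 3.5:
        logger.warning("calibration: delta fraction looks unimodal "
                       "(separation %.2f SD); using fixed defaults", separation)
        return ScoringThresholds()
    log_split, emg_sep = _two_means_split(np.log(emg[emg > 0]))
    if emg_sep < 3.5:
        logger.warning("calibration: EMG looks unimodal; fixed defaults")
        return ScoringThresholds()
    emg_wake = float(np.exp(log_split))
    quiet = emg[emg < emg_wake]
    emg_rem = float(0.5 * quiet.mean()) if len(quiet) else emg_wake / 4.0
    if emg_rem >= emg_wake:
        logger.warning("calibration: EMG quantiles degenerate; fixed defaults")
        return ScoringThresholds()
    # REM ratio threshold: clearly above what low-EMG NREM epochs show
    low_emg = emg <= emg_rem
    nremish = low_emg & (delta_frac >= df_thresh)
    ratio = features["theta_delta_ratio"].to_numpy()
    floor = 1.5
    if nremish.any():
        floor = max(floor, 3.0 * float(np.nanmedian(ratio[nremish])))
    return ScoringThresholds(
        emg_wake_thresh=emg_wake,
        delta_frac_nrem_thresh=float(df_thresh),
        theta_delta_rem_thresh=floor,
        emg_rem_max=emg_rem,
        mode=PER_ANIMAL_QUANTILE,
    )


def score_recording(recording: Recording, thresholds=None,
                    epoch_len_s: float = 10.0, calibrate: bool = True) -> Hypnogram:
    """Convenience: features -> (optional) calibration -> hypnogram."""
    feats = compute_epoch_features(recording, epoch_len_s)
    if thresholds is None:
        thresholds = (calibrate_thresholds(feats, epoch_len_s=epoch_len_s)
                      if calibrate else ScoringThresholds())
    return score_epochs(feats, thresholds, epoch_len_s,
                        start_zt_s=recording.start_zt_s)


def epoch_agreement(scored: Hypnogram, truth: Hypnogram) -> float:
    """Fraction of epochs on which two hypnograms agree."""
    if len(scored) != len(truth):
        raise PolysomError("hypnograms differ in length")
    return float(np.mean([a == b for a, b in zip(scored.labels, truth.labels)]))
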