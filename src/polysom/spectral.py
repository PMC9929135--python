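"""Per-epoch EEG spectra, state-dependent baseline normalization, and bands.

Spectra are one-sided power densities (uV^2/Hz) computed by a single
Hann-tapered FFT per epoch (no Welch sub-windows) and aggregated onto a
0.5 Hz grid.  A 10-s epoch has 0.1 Hz native resolution, so each 0.5 Hz
bin is the mean of five native bins.

Bin-membership convention (documented because the underlying grid
convention is ambiguous): a band ``[lo, hi]`` selects the 0.5 Hz bins
whose *centers* lie in the closed interval.  Under this rule the delta
band 0.75-4 Hz selects centers 1.0, 1.5, ..., 4.0 (the grid has no 0.75
center).  Band summaries are means over selected bins (power density),
not sums, so bands of unequal width stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ARTIFACT, Hypnogram, PolysomError, Recording

# Power bands used throughout: delta indexes slow-wave activity; the low
# vs high theta split carries the valence marker; 6-9 Hz theta tracks
# wake quality; gamma tracks active/motivated wakefulness.
BANDS = {
    "delta": (0.75, 4.0),
    "low_theta": (3.5, 7.5),
    "high_theta": (8.0, 11.5),
    "theta": (6.0, 9.0),
    "gamma": (30.0, 50.0),
}


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise PolysomError(f"band {self.name}: need 0 < lo < hi")


def band(name: str) -> BandDefinition:
    lo, hi = BANDS[name]
    return BandDefinition(name, lo, hi)


@dataclass(frozen=True)
class Spectrogram:
    """Epochs x 0.5 Hz bins of absolute one-sided power density."""

    power: np.ndarray          # (n_epochs, n_bins), uV^2/Hz
    bin_centers: np.ndarray    # Hz, 0.5 Hz spacing
    epoch_len_s: float = 10.0

    def __post_init__(self):
        power = np.asarray(self.power, dtype=float)
        centers = np.asarray(self.bin_centers, dtype=float)
        if power.ndim != 2 or power.shape[1] != len(centers):
            raise PolysomError("power must be (epochs x bins)")
        if np.any(power < 0):
            raise PolysomError("power density must be non-negative")
        if len(centers) > 1 and not np.allclose(np.diff(centers), 0.5):
            raise PolysomError("bin centers must be on a 0.5 Hz grid")
        object.__setattr__(self, "power", power)
        object.__setattr__(self, "bin_centers", centers)

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    @property
    def fmax(self) -> float:
        return float(self.bin_centers[-1])


def epoch_spectrogram(recording: Recording, epoch_len_s: float = 10.0,
                      fmax: float = 50.0, channel: str = "eeg") -> Spectrogram:
    """Per-epoch Hann-tapered FFT power density on the 0.5 Hz grid.

    fmax defaults to 50 Hz; pass 64 for the wide-band (valence) analysis.
    """
    if recording.fs < 2 * fmax:
        raise PolysomError(
            f"fs={recording.fs} Hz cannot resolve fmax={fmax} Hz; "
            f"use fmax <= {recording.fs / 2:g}")
    x = getattr(recording, channel)
    spe = int(round(epoch_len_s * recording.fs))
    n_epochs = len(x) // spe
    if n_epochs == 0:
        raise PolysomError("recording shorter than one epoch")
    epochs = np.asarray(x[: n_epochs * spe]).reshape(n_epochs, spe)
    freqs, pxx = sps.periodogram(epochs, fs=recording.fs, window="hann",
                                 detrend="constant", axis=1)
    centers = np.arange(1, int(round(2 * fmax)) + 1) * 0.5
    power = np.empty((n_epochs, len(centers)))
    for k, c in enumerate(centers):
        sel = (freqs > c - 0.25) & (freqs <= c + 0.25)
        power[:, k] = pxx[:, sel].mean(axis=1)
    return Spectrogram(power, centers, epoch_len_s)


def state_mean_spectrum(spec: Spectrogram, hyp: Hypnogram, state: str) -> np.ndarray:
    """Mean per-bin power over epochs labelled ``state`` (ARTIFACT excluded)."""
    _check_aligned(spec, hyp)
    mask = np.asarray([l == state for l in hyp.labels])
    if not mask.any():
        raise PolysomError(f"no epochs of state {state} to average")
    return spec.power[mask].mean(axis=0)


def baseline_state_means(spec: Spectrogram, hyp: Hypnogram,
                         states=("WAKE", "NREM", "REM")) -> dict[str, np.ndarray]:
    """Per-state mean spectra of a baseline day, for normalization."""
    return {s: state_mean_spectrum(spec, hyp, s) for s in states
            if any(l == s for l in hyp.labels)}


def normalize_to_baseline(spec: Spectrogram, hyp: Hypnogram,
                          baseline_means: dict[str, np.ndarray]) -> np.ndarray:
    """Each epoch's bins as % of that animal's baseline state mean.

    State-dependent normalization: a NREM epoch is divided by the
    baseline NREM mean spectrum, a wake epoch by the wake mean, etc.
    ARTIFACT epochs (and bins with zero baseline) come out as NaN.
    """
    _check_aligned(spec, hyp)
    out = np.full_like(spec.power, np.nan)
    for state, ref in baseline_means.items():
        mask = np.asarray([l == state for l in hyp.labels])
        if not mask.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * spec.power[mask] / ref
        vals[:, np.asarray(ref) <= 0] = np.nan
        out[mask] = vals
    present = {l for l in hyp.labels if l != ARTIFACT}
    missing = present - set(baseline_means)
    if missing:
        raise PolysomError(f"no baseline mean for states {sorted(missing)}")
    return out


def band_power(values: np.ndarray, bdef: BandDefinition,
               bin_centers: np.ndarray) -> np.ndarray | float:
    """Mean of the bins whose centers lie in [lo, hi] (inclusive)."""
    centers = np.asarray(bin_centers)
    sel = (centers >= bdef.lo - 1e-9) & (centers <= bdef.hi + 1e-9)
    if not sel.any():
        raise PolysomError(f"band {bdef.name} selects no bins")
    vals = np.asarray(values, dtype=float)
    return vals[..., sel].mean(axis=-1)


def band_timecourse(spec: Spectrogram, hyp: Hypnogram, bdef: BandDefinition,
                    state: str, baseline_means: dict[str, np.ndarray],
                    bin_h: float = 1.0) -> np.ndarray:
    """Hourly normalized band power within one state (% of baseline mean).

    Hours with no epochs of the state are NaN (missing), never 0.
    """
    _check_aligned(spec, hyp)
    norm = normalize_to_baseline(spec, hyp, baseline_means)
    bp = band_power(norm, bdef, spec.bin_centers)
    hours = (hyp.epoch_times_s() // (bin_h * 3600)).astype(int)
    n_bins = int(hours[-1]) + 1
    out = np.full(n_bins, np.nan)
    state_mask = np.asarray([l == state for l in hyp.labels])
    for h in range(n_bins):
        sel = state_mask & (hours == h)
        if sel.any():
            out[h] = np.nanmean(bp[sel])
    return out


def theta_ratio(wake_spectrum: np.ndarray, bin_centers: np.ndarray) -> float:
    """[low theta (3.5-7.5 Hz)] / [high theta (8-11.5 Hz)] power-density ratio.

    Computed on wake spectra; high values accompany negatively-valenced
    (aversive) wakefulness and predict larger subsequent NREM rebound.
    """
    hi = band_power(wake_spectrum, band("high_theta"), bin_centers)
    if np.any(np.asarray(hi) <= 0):
        raise PolysomError("high-theta power must be positive for the ratio")
    lo = band_power(wake_spectrum, band("low_theta"), bin_centers)
    return lo / hi


def _check_aligned(spec: Spectrogram, hyp: Hypnogram) -> None:
    if spec.n_epochs != len(hyp) or spec.epoch_len_s != hyp.epoch_len_s:
        raise PolysomError(
            f"spectrogram ({spec.n_epochs} x {spec.epoch_len_s}s) and hypnogram "
            f"({len(hyp)} x {hyp.epoch_len_s}s) are not on the same epoch grid")
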