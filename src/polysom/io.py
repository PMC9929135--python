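"""Data model and file formats shared by all pipeline stages.

Time base is seconds from recording start everywhere inside the package;
Zeitgeber time (ZT, hours after lights-on) appears only at reporting
boundaries.  Epochs are 0-based and half-open: epoch ``i`` covers
``[start + i*epoch_len, start + (i+1)*epoch_len)``.  A partial trailing
epoch is dropped on load, never padded.

Signal CSV dialect (the commercial acquisition formats are proprietary):
two comment-style header lines ``#fs=<Hz>`` and ``#start_zt_s=<s>``,
then one ``eeg,emg`` sample pair (microvolts) per row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("polysom")

#: Canonical vigilance-state labels.
WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
ARTIFACT = "ARTIFACT"
STATES = (WAKE, NREM, REM)
ALL_LABELS = (WAKE, NREM, REM, ARTIFACT)

LIGHT = "LIGHT"
DARK = "DARK"

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


class PolysomError(RuntimeError):
    """Fatal error in pipeline input handling."""


# ---------------------------------------------------------------------------
# Light schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightSchedule:
    """Lighting condition over a recording.

    Parameters
    ----------
    segments
        Ordered ``(start_time_s, state)`` pairs, ``state`` in
        ``{"LIGHT", "DARK"}``.  Segments are contiguous and cover the
        recording from the first start to ``duration_s``.
    duration_s
        Total schedule span in seconds from recording start.
    zt0_offset_s
        Seconds from recording start to the reference lights-on (ZT0)
        of the entrained 12:12 cycle.  ZT0 = lights-on, ZT12 = lights-off.
    """

    segments: tuple[tuple[float, str], ...]
    duration_s: float
    zt0_offset_s: float = 0.0

    def __post_init__(self):
        if not self.segments:
            raise PolysomError("LightSchedule needs at least one segment")
        starts = [s for s, _ in self.segments]
        if starts != sorted(starts):
            raise PolysomError("schedule segments must be ordered by start time")
        merged = []
        for start, state in self.segments:
            if state not in (LIGHT, DARK):
                raise PolysomError(f"unknown light state {state!r}")
            if merged and merged[-1][1] == state:
                continue  # repeated segments merge on load
            merged.append((float(start), state))
        object.__setattr__(self, "segments", tuple(merged))

    @classmethod
    def ld_12_12(cls, duration_s: float, zt0_offset_s: float = 0.0,
                 start_zt_s: float = 0.0) -> "LightSchedule":
        """Standard entrained 12 h light : 12 h dark schedule."""
        segs = []
        t = 0.0
        while t < duration_s:
            zt = ((t + start_zt_s) / SECONDS_PER_HOUR) % 24.0
            state = LIGHT if zt < 12.0 else DARK
            segs.append((t, state))
            # jump to the next phase boundary
            next_zt = 12.0 if zt < 12.0 else 24.0
            t += (next_zt - zt) * SECONDS_PER_HOUR
        return cls(tuple(segs), float(duration_s), zt0_offset_s)

    @classmethod
    def constant_dark(cls, duration_s: float, zt0_offset_s: float = 0.0) -> "LightSchedule":
        return cls(((0.0, DARK),), float(duration_s), zt0_offset_s)

    @classmethod
    def ultradian_1h(cls, duration_s: float, zt0_offset_s: float = 0.0,
                     first: str = LIGHT) -> "LightSchedule":
        """Alternating 1 h light / 1 h dark segments."""
        other = DARK if first == LIGHT else LIGHT
        segs = [(i * SECONDS_PER_HOUR, first if i % 2 == 0 else other)
                for i in range(int(np.ceil(duration_s / SECONDS_PER_HOUR)))]
        return cls(tuple(segs), float(duration_s), zt0_offset_s)

    def state_at(self, t_s: float) -> str:
        if t_s < self.segments[0][0] or t_s > self.duration_s:
            raise PolysomError(f"time {t_s} s outside schedule span")
        state = self.segments[0][1]
        for start, s in self.segments:
            if start <= t_s:
                state = s
            else:
                break
        return state

    def windows(self, state: str) -> list[tuple[float, float]]:
        """Half-open ``[start, end)`` windows in the given light state."""
        out = []
        for i, (start, s) in enumerate(self.segments):
            end = (self.segments[i + 1][0] if i + 1 < len(self.segments)
                   else self.duration_s)
            if s == state and end > start:
                out.append((start, end))
        return out


def zt_of(schedule: LightSchedule, t_s: float) -> float:
    """Zeitgeber time (hours, in [0, 24)) of recording time ``t_s``."""
    if t_s < 0 or t_s > schedule.duration_s:
        raise PolysomError(f"time {t_s} s outside recording span")
    zt = ((t_s - schedule.zt0_offset_s) / SECONDS_PER_HOUR) % 24.0
    # a tiny negative argument can make float mod round up to exactly 24
    return zt if zt < 24.0 else 0.0


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch vigilance labels at fixed epoch length."""

    labels: tuple[str, ...]
    epoch_len_s: float = 10.0
    start_zt_s: float = 0.0

    def __post_init__(self):
        if self.epoch_len_s <= 0:
            raise PolysomError("epoch_len_s must be positive")
        if not self.labels:
            raise PolysomError("hypnogram has no epochs")
        bad = set(self.labels) - set(ALL_LABELS)
        if bad:
            raise PolysomError(f"unknown state labels {sorted(bad)}")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_len_s

    @property
    def artifact_fraction(self) -> float:
        return sum(l == ARTIFACT for l in self.labels) / len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def epoch_times_s(self) -> np.ndarray:
        """Start time (s from recording start) of each epoch."""
        return np.arange(len(self.labels)) * self.epoch_len_s

    def epoch_zt_s(self) -> np.ndarray:
        """ZT (seconds, unwrapped) at the start of each epoch."""
        return self.start_zt_s + self.epoch_times_s()


def read_hypnogram(path) -> Hypnogram:
    """Read a hypnogram TSV with columns epoch_index, zt_start_s, state."""
    df = pd.read_csv(path, sep="\t")
    required = {"epoch_index", "zt_start_s", "state"}
    if not required.issubset(df.columns):
        raise PolysomError(f"{path}: hypnogram TSV needs columns {sorted(required)}")
    idx = df["epoch_index"].to_numpy()
    expected = np.arange(len(idx))
    if not np.array_equal(idx, expected):
        bad = int(np.argmax(idx != expected))
        raise PolysomError(
            f"{path}: gap or duplicate epoch_index at row {bad} "
            f"(found {idx[bad]}, expected {expected[bad]})")
    states = df["state"].tolist()
    for row, s in enumerate(states):
        if s not in ALL_LABELS:
            raise PolysomError(f"{path}: unknown state {s!r} at row {row}")
    zt = df["zt_start_s"].to_numpy(dtype=float)
    epoch_len = float(zt[1] - zt[0]) if len(zt) > 1 else 10.0
    return Hypnogram(tuple(states), epoch_len_s=epoch_len, start_zt_s=float(zt[0]))


def write_hypnogram(hyp: Hypnogram, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "epoch_index": np.arange(len(hyp)),
        "zt_start_s": hyp.epoch_zt_s(),
        "state": list(hyp.labels),
    })
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Recording:
    """Paired EEG + EMG signal (microvolts) with its light context."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    schedule: LightSchedule
    start_zt_s: float = 0.0
    animal_id: str = "animal0"
    group: str = "control"

    def __post_init__(self):
        if self.fs <= 0:
            raise PolysomError("sampling rate must be positive")
        eeg = np.asarray(self.eeg, dtype=float)
        emg = np.asarray(self.emg, dtype=float)
        if eeg.shape != emg.shape or eeg.ndim != 1:
            raise PolysomError("eeg and emg must be 1-D arrays of equal length")
        object.__setattr__(self, "eeg", eeg)
        object.__setattr__(self, "emg", emg)

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def truncated_to_epochs(self, epoch_len_s: float = 10.0) -> "Recording":
        """Drop the partial trailing epoch, if any (logged)."""
        spe = int(round(epoch_len_s * self.fs))
        n = (self.n_samples // spe) * spe
        if n == self.n_samples:
            return self
        logger.info("truncating %s: %d -> %d samples (whole %g s epochs)",
                    self.animal_id, self.n_samples, n, epoch_len_s)
        return replace(self, eeg=self.eeg[:n], emg=self.emg[:n])


def write_recording(rec: Recording, path, fmt: str = "CSV") -> Path:
    """Write a recording as CSV (documented dialect) or EDF."""
    path = Path(path)
    if fmt.upper() == "CSV":
        with open(path, "w") as fh:
            fh.write(f"#fs={rec.fs:g}\n")
            fh.write(f"#start_zt_s={rec.start_zt_s:g}\n")
            np.savetxt(fh, np.column_stack([rec.eeg, rec.emg]),
                       fmt="%.4f", delimiter=",")
    elif fmt.upper() == "EDF":
        from . import _edf
        _edf.write_edf(path, {"EEG": rec.eeg, "EMG": rec.emg}, rec.fs,
                       start_zt_s=rec.start_zt_s)
    else:
        raise PolysomError(f"unknown recording format {fmt!r}")
    return path


def load_recording(path, fmt: str | None = None,
                   channel_map: dict[str, str] | None = None,
                   schedule: LightSchedule | None = None,
                   epoch_len_s: float = 10.0,
                   start_zt_s: float | None = None,
                   animal_id: str = "animal0",
                   group: str = "control") -> Recording:
    """Load an EEG+EMG recording from EDF or the documented CSV dialect.

    Channels are identified as EEG/EMG either through ``channel_map``
    (``{"eeg": label, "emg": label}``) or by case-insensitive label
    prefix.  The recording is truncated to whole epochs.
    """
    path = Path(path)
    if fmt is None:
        fmt = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    if fmt.upper() == "CSV":
        eeg, emg, fs, zt = _load_csv_recording(path)
    elif fmt.upper() == "EDF":
        eeg, emg, fs, zt = _load_edf_recording(path, channel_map)
    else:
        raise PolysomError(f"unknown recording format {fmt!r}")
    if start_zt_s is not None:
        zt = start_zt_s
    if schedule is None:
        schedule = LightSchedule.ld_12_12(len(eeg) / fs, start_zt_s=zt)
    rec = Recording(eeg=eeg, emg=emg, fs=fs, schedule=schedule,
                    start_zt_s=zt, animal_id=animal_id, group=group)
    return rec.truncated_to_epochs(epoch_len_s)


def _load_csv_recording(path):
    fs = None
    zt = 0.0
    try:
        with open(path) as fh:
            header_rows = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                header_rows += 1
                key, _, val = line[1:].strip().partition("=")
                if key == "fs":
                    fs = float(val)
                elif key == "start_zt_s":
                    zt = float(val)
        data = np.loadtxt(path, delimiter=",", skiprows=header_rows, ndmin=2)
    except OSError as exc:
        raise PolysomError(f"unreadable recording file {path}") from exc
    if fs is None:
        raise PolysomError(f"{path}: missing '#fs=' header line")
    if data.shape[1] < 2:
        raise PolysomError(f"{path}: need eeg,emg column pairs")
    return data[:, 0], data[:, 1], fs, zt


def _load_edf_recording(path, channel_map):
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several concrete types
        raise PolysomError(f"unreadable EDF file {path}: {exc}") from exc
    labels = raw.ch_names
    if channel_map:
        mapping = {k.lower(): v for k, v in channel_map.items()}
        eeg_label, emg_label = mapping.get("eeg"), mapping.get("emg")
    else:
        eeg_label = next((l for l in labels if l.lower().startswith("eeg")), None)
        emg_label = next((l for l in labels if l.lower().startswith("emg")), None)
        logger.info("EDF %s: auto channel mapping eeg=%s emg=%s", path,
                    eeg_label, emg_label)
    if eeg_label not in labels or emg_label not in labels:
        raise PolysomError(
            f"{path}: cannot identify EEG/EMG channels; available labels: {labels}")
    fs = float(raw.info["sfreq"])
    # mne scales EDF physical units to SI (volts for eeg/emg channel types);
    # signals are stored here in microvolts.
    data = raw.get_data(picks=[eeg_label, emg_label])
    scale = 1e6 if np.max(np.abs(data)) < 1.0 else 1.0
    return data[0] * scale, data[1] * scale, fs, 0.0


# ---------------------------------------------------------------------------
# Activity traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityTrace:
    """1-min-binned locomotor counts spanning several days."""

    counts: np.ndarray
    start_zt_s: float = 0.0
    schedule: LightSchedule | None = None
    dd: bool = False

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise PolysomError("activity counts must be a 1-D series")
        if np.any(counts < 0):
            raise PolysomError("activity counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(float))

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration_h(self) -> float:
        return len(self.counts) / 60.0


def read_activity(path) -> ActivityTrace:
    df = pd.read_csv(path)
    if "counts" not in df.columns:
        raise PolysomError(f"{path}: activity CSV needs a 'counts' column")
    start = float(df["minute"].iloc[0]) * 60.0 if "minute" in df.columns else 0.0
    return ActivityTrace(df["counts"].to_numpy(), start_zt_s=start)


def write_activity(trace: ActivityTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "minute": np.arange(len(trace)) + trace.start_zt_s / 60.0,
        "counts": trace.counts.astype(int),
    }).to_csv(path, index=False)
    return path


def actogram_matrix(trace: ActivityTrace) -> np.ndarray:
    """Double-plotted actogram as a (days x 2880) matrix of counts."""
    n_days = len(trace) // 1440
    days = trace.counts[: n_days * 1440].reshape(n_days, 1440)
    doubled = np.full((n_days, 2880), np.nan)
    doubled[:, :1440] = days
    doubled[:-1, 1440:] = days[1:]
    return doubled


# ---------------------------------------------------------------------------
# Experiment manifests
# ---------------------------------------------------------------------------

PROTOCOLS = ("BASELINE", "SD", "LIGHT_PULSE", "DARK_PULSE", "ULTRADIAN_LD", "DD")
VALENCES = ("POSITIVE", "NEGATIVE", "NONE")


@dataclass(frozen=True)
class ExperimentManifest:
    """Paths and protocol parameters for one experiment."""

    protocol: str
    recordings: dict = field(default_factory=dict)
    window_start_zt_h: float | None = None
    window_len_h: float | None = None
    valence: str = "NONE"

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise PolysomError(f"unknown protocol {self.protocol!r}")
        if self.valence not in VALENCES:
            raise PolysomError(f"unknown valence {self.valence!r}")


def read_manifest(path) -> ExperimentManifest:
    with open(path) as fh:
        data = json.load(fh)
    mf = ExperimentManifest(
        protocol=data["protocol"],
        recordings=data.get("recordings", {}),
        window_start_zt_h=data.get("window_start_zt_h"),
        window_len_h=data.get("window_len_h"),
        valence=data.get("valence", "NONE"),
    )
    for animal, paths in mf.recordings.items():
        for day, p in paths.items():
            if not Path(p).exists():
                raise PolysomError(f"manifest {path}: missing file {p} "
                                   f"({animal}/{day})")
    return mf


def write_manifest(mf: ExperimentManifest, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({
            "protocol": mf.protocol,
            "recordings": mf.recordings,
            "window_start_zt_h": mf.window_start_zt_h,
            "window_len_h": mf.window_len_h,
            "valence": mf.valence,
        }, fh, indent=2)
    return path
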