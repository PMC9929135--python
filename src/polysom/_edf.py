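"""Minimal EDF (European Data Format) writer.

Reading goes through :mod:`mne`; no pre-installed library exposes EDF
*writing*, so this module implements the small subset needed to persist
simulated EEG/EMG recordings: one fixed-length 256-byte global header,
one 256-byte header per signal, then contiguous data records of 16-bit
little-endian integers.  Physical units are microvolts; each channel is
scaled to use the full digital range.
"""

from __future__ import annotations

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    b = str(value)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def write_edf(path, channels: dict[str, np.ndarray], fs: float,
              start_zt_s: float = 0.0, record_len_s: float = 1.0) -> None:
    """Write named channels (equal length, common sampling rate) to EDF."""
    names = list(channels)
    data = [np.asarray(channels[n], dtype=float) for n in names]
    n = len(data[0])
    if any(len(d) != n for d in data):
        raise ValueError("all channels must have equal length")
    spr = int(round(fs * record_len_s))  # samples per record per channel
    n_records = n // spr
    if n_records == 0:
        raise ValueError("recording shorter than one data record")
    n = n_records * spr
    ns = len(names)

    phys_min, phys_max, scaled = [], [], []
    for d in data:
        d = d[:n]
        lo, hi = float(np.min(d)), float(np.max(d))
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((d - lo) / (hi - lo) * (_DIG_MAX - _DIG_MIN) + _DIG_MIN)
        scaled.append(dig.astype("<i2"))

    header = b"".join([
        _field("0", 8),                       # version
        _field("X X X X", 80),                # patient id
        _field(f"startzt {start_zt_s:g}s", 80),  # recording id
        _field("01.01.00", 8),                # start date (synthetic)
        _field("00.00.00", 8),                # start time
        _field(str(256 * (1 + ns)), 8),       # header bytes
        _field("", 44),                       # reserved
        _field(str(n_records), 8),
        _field(f"{record_len_s:g}", 8),
        _field(str(ns), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(nm, 16) for nm in names),
        b"".join(_field("synthetic", 80) for _ in names),      # transducer
        b"".join(_field("uV", 8) for _ in names),
        b"".join(_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(ns)),
        b"".join(_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(ns)),
        b"".join(_field(str(_DIG_MIN), 8) for _ in names),
        b"".join(_field(str(_DIG_MAX), 8) for _ in names),
        b"".join(_field("", 80) for _ in names),               # prefiltering
        b"".join(_field(str(spr), 8) for _ in names),
        b"".join(_field("", 32) for _ in names),               # reserved
    ])

    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_records):
            for c in range(ns):
                fh.write(scaled[c][r * spr:(r + 1) * spr].tobytes())
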