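"""EDF (European Data Format) adapter and clip annotation tables.

Reading goes through mne's EDF reader.  Writing uses a minimal EDF writer
implemented here: EDF is a fixed-layout ASCII-header + 16-bit little-endian
format, and only the subset needed to round-trip generated clips (one data
record per second, uniform rate, physical scaling per channel) is emitted.
The writer is validated in the test suite by reading its output back with
mne and comparing samples.

Annotations travel as a CSV table with columns ``clip_id, start_s, stop_s,
label`` (one row per seizure interval; interval-free clips get a single row
with empty start/stop and label 0).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import EEGClip

__all__ = ["write_edf", "read_edf", "write_annotations", "read_annotations"]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, samples: np.ndarray, sample_rate: float,
              channel_names: list[str] | tuple[str, ...]) -> None:
    """Write (n_channels, n_samples) float data as a 16-bit EDF file.

    Uses 1-s data records, so ``sample_rate`` must be a positive integer and
    the signal an integer number of seconds long.
    """
    samples = np.asarray(samples, dtype=np.float64)
    fs = int(round(sample_rate))
    if fs <= 0 or abs(fs - sample_rate) > 1e-9:
        raise ValueError("sample_rate must be a positive integer for EDF export")
    n_ch, n_samp = samples.shape
    if n_ch != len(channel_names):
        raise ValueError("channel_names length does not match samples")
    if n_samp % fs != 0:
        raise ValueError("signal must span an integer number of seconds")
    n_rec = n_samp // fs

    phys_max = np.maximum(np.abs(samples).max(axis=1), 1e-6)
    dig_max = 32767
    scale = phys_max / dig_max
    digital = np.round(samples / scale[:, None]).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(str(c), 16) for c in channel_names),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{-p:.6g}"[:8], 8) for p in phys_max),
        b"".join(_field(f"{p:.6g}"[:8], 8) for p in phys_max),
        b"".join(_field(str(-dig_max), 8) for _ in range(n_ch)),
        b"".join(_field(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        # record-major layout: per second, all channels back to back
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path, seizure_intervals=None) -> EEGClip:
    """Read an EDF file into an :class:`EEGClip` (thin mne adapter)."""
    import mne
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    # mne scales EDF voltages to SI volts; restore the uV-like scale
    return EEGClip(samples=data * 1e6,
                   sample_rate=float(raw.info["sfreq"]),
                   channel_names=tuple(raw.ch_names),
                   seizure_intervals=list(seizure_intervals or []))


def write_annotations(path, rows: list[dict]) -> None:
    """CSV of clip annotations: clip_id, start_s, stop_s, label."""
    import pandas as pd
    pd.DataFrame(rows, columns=["clip_id", "start_s", "stop_s", "label"]
                 ).to_csv(path, index=False)


def read_annotations(path) -> dict[str, dict]:
    """Inverse of :func:`write_annotations`; returns
    ``{clip_id: {"intervals": [(start, stop), ...], "label": int}}``."""
    import pandas as pd
    df = pd.read_csv(path)
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry = out.setdefault(str(row["clip_id"]),
                               {"intervals": [], "label": 0})
        if np.isfinite(row.get("start_s", np.nan)) and \
                np.isfinite(row.get("stop_s", np.nan)):
            entry["intervals"].append((float(row["start_s"]),
                                       float(row["stop_s"])))
        entry["label"] = max(entry["label"], int(row["label"]))
    return out
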