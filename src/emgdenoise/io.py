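"""Reading and writing multichannel signals.

Primary format: delimited text with a header row of channel names, one
column per channel, and the sampling rate supplied either explicitly or via
a JSON sidecar ("<file>.json" containing at least {"fs": <Hz>}).  A minimal
read-only EDF (European Data Format) parser is included for recorded data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import Signal


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def read_signals(path, fs: float | None = None, delimiter=None):
    """Read a delimited text file into (signals, channel_names).

    ``fs`` overrides the sidecar; one of the two must be available.
    """
    path = Path(path)
    if fs is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"sampling rate not given and no sidecar {sidecar} found"
            )
        fs = float(json.loads(sidecar.read_text())["fs"])
    # sep=None sniffing mis-detects single-column files; default to comma
    frame = pd.read_csv(path, sep="," if delimiter is None else delimiter)
    names = [str(c) for c in frame.columns]
    signals = [Signal(frame[c].to_numpy(dtype=float), fs) for c in frame.columns]
    return signals, names


def write_signals(path, signals, names=None, extra_sidecar: dict | None = None):
    """Write channels as delimited text plus a JSON sidecar with the rate."""
    path = Path(path)
    signals = list(signals)
    if not signals:
        raise ValueError("nothing to write")
    fs = signals[0].fs
    if any(s.fs != fs for s in signals):
        raise ValueError("all channels must share the sampling rate")
    if names is None:
        names = [f"ch{i}" for i in range(len(signals))]
    frame = pd.DataFrame({n: s.data for n, s in zip(names, signals)})
    frame.to_csv(path, index=False)
    sidecar = {"fs": fs}
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_edf(path):
    """Minimal EDF reader: returns (signals, channel_names).

    Supports uncompressed EDF with a uniform record layout; annotations
    channels are skipped.  Physical values are reconstructed from the
    per-channel calibration fields.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError("truncated EDF header")
        n_records = int(header[236:244].decode("ascii").strip())
        record_duration = float(header[244:252].decode("ascii").strip())
        n_channels = int(header[252:256].decode("ascii").strip())
        ch_header = fh.read(256 * n_channels)

        def fields(offset, width):
            base = offset * n_channels
            return [
                ch_header[base + i * width : base + (i + 1) * width]
                .decode("ascii")
                .strip()
                for i in range(n_channels)
            ]

        labels = fields(0, 16)
        phys_min = [float(v) for v in fields(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dig_min = [float(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dig_max = [float(v) for v in fields(16 + 80 + 8 + 24, 8)]
        units = fields(16 + 80, 8)
        samples_per_record = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]

        per_record = sum(samples_per_record)
        raw = np.fromfile(fh, dtype="<i2", count=per_record * n_records)
    if raw.size != per_record * n_records:
        raise ValueError("truncated EDF data section")
    raw = raw.reshape(n_records, per_record)
    signals, names = [], []
    offset = 0
    for i in range(n_channels):
        nspr = samples_per_record[i]
        chunk = raw[:, offset : offset + nspr].reshape(-1).astype(float)
        offset += nspr
        if labels[i].startswith("EDF Annotations"):
            continue
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        physical = (chunk - dig_min[i]) * scale + phys_min[i]
        fs = nspr / record_duration
        signals.append(Signal(physical, fs, units[i] or "uV"))
        names.append(labels[i])
    return signals, names
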