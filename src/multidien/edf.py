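"""Minimal EDF (European Data Format) reader/writer for 4-channel clips.

Plain EDF: ASCII header, 16-bit little-endian samples, 1-second data
records.  Channel labels encode the lead/channel map (``L1C1`` = lead 1,
channel 1).  Only what the clip container needs is implemented; physical
units are microvolts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import EEGClip

_DIG_MIN, _DIG_MAX = -32768, 32767
CHANNEL_LABELS = ("L1C1", "L1C2", "L2C1", "L2C2")


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, clip: EEGClip) -> None:
    """Write a clip as plain EDF with 1-s records (zero-padded tail)."""
    fs = clip.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(clip.n_samples / spr))
    data = np.zeros((4, n_rec * spr))
    data[:, : clip.n_samples] = clip.samples
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax[flat] = pmin[flat] + 1.0
    ts = pd.Timestamp(clip.timestamp)
    header = b"".join(
        [
            _field(0, 8),
            _field("synthetic RNS-style clip", 80),
            _field(f"clip type {clip.clip_type}", 80),
            _field(ts.strftime("%d.%m.%y"), 8),
            _field(ts.strftime("%H.%M.%S"), 8),
            _field(256 * (1 + 4), 8),
            _field("", 44),
            _field(n_rec, 8),
            _field(1, 8),
            _field(4, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in CHANNEL_LABELS),
            b"".join(_field("simulated", 80) for _ in range(4)),
            b"".join(_field("uV", 8) for _ in range(4)),
            b"".join(_field(f"{pmin[c]:.6g}"[:8], 8) for c in range(4)),
            b"".join(_field(f"{pmax[c]:.6g}"[:8], 8) for c in range(4)),
            b"".join(_field(_DIG_MIN, 8) for _ in range(4)),
            b"".join(_field(_DIG_MAX, 8) for _ in range(4)),
            b"".join(_field("none", 80) for _ in range(4)),
            b"".join(_field(spr, 8) for _ in range(4)),
            b"".join(_field("", 32) for _ in range(4)),
        ]
    )
    # re-read the rounded physical range so the scaling matches the header
    pmin_h = np.array([float(f"{pmin[c]:.6g}"[:8]) for c in range(4)])
    pmax_h = np.array([float(f"{pmax[c]:.6g}"[:8]) for c in range(4)])
    gain = (pmax_h - pmin_h) / (_DIG_MAX - _DIG_MIN)
    dig = np.round(
        (data - pmin_h[:, None]) / gain[:, None] + _DIG_MIN
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr: (r + 1) * spr].tobytes())


def read_edf(path) -> EEGClip:
    """Read a 4-channel EDF written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        ns = int(head[252:256])
        if ns != 4:
            raise ValueError(f"expected 4 channels, EDF holds {ns}")
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        sig = fh.read(256 * ns)
        raw = fh.read()

    # per-signal header layout: each field stored contiguously for all signals
    pos = 0
    fields = {}
    for name, width in (
        ("label", 16), ("transducer", 80), ("dim", 8), ("pmin", 8),
        ("pmax", 8), ("dmin", 8), ("dmax", 8), ("prefilter", 80),
        ("spr", 8), ("reserved", 32),
    ):
        fields[name] = [
            sig[pos + i * width: pos + (i + 1) * width].decode().strip()
            for i in range(ns)
        ]
        pos += width * ns
    spr = [int(s) for s in fields["spr"]]
    if len(set(spr)) != 1:
        raise ValueError("heterogeneous samples-per-record unsupported")
    spr = spr[0]
    pmin = np.array([float(v) for v in fields["pmin"]])
    pmax = np.array([float(v) for v in fields["pmax"]])
    dmin = np.array([float(v) for v in fields["dmin"]])
    dmax = np.array([float(v) for v in fields["dmax"]])
    dig = np.frombuffer(raw, dtype="<i2", count=n_rec * ns * spr)
    dig = dig.reshape(n_rec, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (dig - dmin[:, None]) * gain[:, None] + pmin[:, None]
    date = head[168:176].decode().strip()
    time = head[176:184].decode().strip()
    ts = pd.to_datetime(f"{date} {time}", format="%d.%m.%y %H.%M.%S")
    return EEGClip(
        samples=data,
        fs=spr / rec_dur,
        timestamp=ts,
        clip_type="SE",
    )
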