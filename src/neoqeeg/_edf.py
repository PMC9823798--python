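"""Minimal EDF+C writer.

Writes 16-bit European Data Format files with an ``EDF Annotations``
signal carrying time-stamped text markers (one TAL block per 1-second
data record). Only the subset of EDF+ needed by this package is
implemented: continuous recordings, a single fixed physical range per
file, integer samples-per-second rates.
"""

from __future__ import annotations

import datetime as _dt
import math
from pathlib import Path
from typing import Sequence

import numpy as np

# Fixed gain: 0.1 uV per digital unit over the full 16-bit range.
PHYS_MIN = -3276.8
PHYS_MAX = 3276.7
DIG_MIN = -32768
DIG_MAX = 32767
LSB_UV = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)

_ANNOT_SAMPLES_PER_RECORD = 32  # 64 bytes of TAL space per record


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def _tal(onset: float, text: str = "", duration: float | None = None) -> bytes:
    out = f"+{onset:g}"
    if duration is not None:
        out += f"\x15{duration:g}"
    out += "\x14" + text + "\x14"
    return out.encode("ascii") + b"\x00"


def write_edf(
    path: str | Path,
    samples_uv: np.ndarray,
    sampling_rate: float,
    channel_labels: Sequence[str],
    subject_id: str = "X",
    start_time: _dt.datetime | None = None,
    annotations: Sequence[tuple[float, float | None, str]] = (),
) -> Path:
    """Write ``samples_uv`` (channels x time, microvolts) as EDF+C.

    Values outside +/-3276.7 uV are clipped to the physical range.
    ``annotations`` is a sequence of (onset_s, duration_s or None, text).
    """
    path = Path(path)
    samples_uv = np.asarray(samples_uv, dtype=float)
    if samples_uv.ndim != 2 or samples_uv.shape[0] != len(channel_labels):
        raise ValueError("samples_uv must be channels x time matching labels")
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9 or fs <= 0:
        raise ValueError("sampling_rate must be a positive integer in Hz")

    n_ch, n_samp = samples_uv.shape
    n_records = math.ceil(n_samp / fs)
    if start_time is None:
        start_time = _dt.datetime(2000, 1, 1, 0, 0, 0)

    # digital conversion, zero-padded to whole records
    dig = np.round(np.clip(samples_uv, PHYS_MIN, PHYS_MAX) / LSB_UV)
    dig = dig.astype(np.int16)
    padded = np.zeros((n_ch, n_records * fs), dtype=np.int16)
    padded[:, :n_samp] = dig

    ns = n_ch + 1  # plus annotation signal
    header = b""
    header += _field("0", 8)
    header += _field(f"{subject_id} X X X", 80)
    header += _field("Startdate X X X X", 80)
    header += _field(start_time.strftime("%d.%m.%y"), 8)
    header += _field(start_time.strftime("%H.%M.%S"), 8)
    header += _field(str(256 * (ns + 1)), 8)
    header += _field("EDF+C", 44)
    header += _field(str(n_records), 8)
    header += _field("1", 8)
    header += _field(str(ns), 4)

    labels = [str(lab) for lab in channel_labels] + ["EDF Annotations"]
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field("uV", 8) for _ in range(n_ch)) + _field("", 8)
    header += b"".join(_field(f"{PHYS_MIN}", 8) for _ in range(n_ch)) + _field("-1", 8)
    header += b"".join(_field(f"{PHYS_MAX}", 8) for _ in range(n_ch)) + _field("1", 8)
    header += b"".join(_field(str(DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_field(str(DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field(str(fs), 8) for _ in range(n_ch))
    header += _field(str(_ANNOT_SAMPLES_PER_RECORD), 8)
    header += b"".join(_field("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    # group annotations by the record whose span contains their onset
    per_record: dict[int, list[bytes]] = {}
    for onset, dur, text in annotations:
        rec = min(max(int(onset), 0), n_records - 1)
        per_record.setdefault(rec, []).append(_tal(onset, text, dur))

    annot_bytes_per_record = 2 * _ANNOT_SAMPLES_PER_RECORD
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = padded[:, rec * fs : (rec + 1) * fs]
            fh.write(block.astype("<i2").tobytes())
            tal = _tal(float(rec)) + b"".join(per_record.get(rec, []))
            if len(tal) > annot_bytes_per_record:
                raise ValueError("too many annotations in one record")
            fh.write(tal.ljust(annot_bytes_per_record, b"\x00"))
    return path
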