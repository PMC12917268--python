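"""Minimal European Data Format (EDF) reader and writer.

EDF stores a 256-byte ASCII master header, 256 ASCII bytes per signal,
and little-endian int16 samples scaled between a per-signal physical
and digital range.  Only the plain-EDF subset the pipeline needs is
implemented: continuous records, one common sampling rate, no EDF+
annotations.  Files whose channels disagree on samples-per-record are
rejected rather than resampled.
"""

from __future__ import annotations

import os
from datetime import datetime

import numpy as np

from .record import EEGRecord

__all__ = ["read_edf", "write_edf", "EDFFormatError"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EDFFormatError(ValueError):
    """Raised when a file does not parse as the supported EDF subset."""


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise EDFFormatError(f"header field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(value: float) -> str:
    """Format a physical bound into <= 8 ASCII chars."""
    for fmt in ("%.8g", "%.6g", "%.4g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise EDFFormatError(f"cannot encode {value} in 8 bytes")


def write_edf(record: EEGRecord, path: str | os.PathLike) -> None:
    """Write a record as a single-data-record EDF file.

    Samples are quantised to int16 over each channel's observed physical
    range; the stored physical bounds are the ASCII-truncated values, so
    a read-back reproduces the samples to within one 16-bit step of that
    range.  Segment labels are not part of EDF and are not written.
    """
    ns = record.n_channels
    n_samples = record.n_samples
    now = datetime(2000, 1, 1)

    phys_min_s, phys_max_s = [], []
    for ch in range(ns):
        lo = float(np.min(record.signal[ch]))
        hi = float(np.max(record.signal[ch]))
        if hi <= lo:
            hi = lo + 1.0
        phys_min_s.append(_fmt_float(lo))
        phys_max_s.append(_fmt_float(hi))

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field("1", 8),
            _field(_fmt_float(record.duration), 8),
            _field(str(ns), 4),
        ]
    )
    header += b"".join(_field(name, 16) for name in record.channel_names)
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field("uV", 8) for _ in range(ns))
    header += b"".join(_field(s, 8) for s in phys_min_s)
    header += b"".join(_field(s, 8) for s in phys_max_s)
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field(str(n_samples), 8) for _ in range(ns))
    header += b"".join(_field("", 32) for _ in range(ns))

    payload = np.empty((ns, n_samples), dtype="<i2")
    for ch in range(ns):
        # scale with the truncated bounds actually stored in the header
        lo, hi = float(phys_min_s[ch]), float(phys_max_s[ch])
        scaled = (record.signal[ch] - lo) / (hi - lo) * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
        payload[ch] = np.clip(np.round(scaled), _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(payload.tobytes())


def _read_fields(buf: bytes, offset: int, width: int, count: int) -> tuple[list[str], int]:
    out = []
    for _ in range(count):
        out.append(buf[offset : offset + width].decode("ascii", errors="replace").strip())
        offset += width
    return out, offset


def read_edf(path: str | os.PathLike) -> EEGRecord:
    """Read an EDF file into a record (segment labels empty).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    EDFFormatError
        On a malformed header or when channels carry different
        sampling rates (mixed-rate files are rejected, not resampled).
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise EDFFormatError(f"{path}: file shorter than an EDF header")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        record_duration = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise EDFFormatError(f"{path}: malformed EDF header ({exc})") from None
    if ns < 1 or n_records < 1:
        raise EDFFormatError(f"{path}: invalid signal/record counts")

    offset = 256
    labels, offset = _read_fields(raw, offset, 16, ns)
    _, offset = _read_fields(raw, offset, 80, ns)  # transducer
    _, offset = _read_fields(raw, offset, 8, ns)  # physical dimension
    pmin_s, offset = _read_fields(raw, offset, 8, ns)
    pmax_s, offset = _read_fields(raw, offset, 8, ns)
    dmin_s, offset = _read_fields(raw, offset, 8, ns)
    dmax_s, offset = _read_fields(raw, offset, 8, ns)
    _, offset = _read_fields(raw, offset, 80, ns)  # prefiltering
    spr_s, offset = _read_fields(raw, offset, 8, ns)
    _, offset = _read_fields(raw, offset, 32, ns)

    try:
        pmin = [float(s) for s in pmin_s]
        pmax = [float(s) for s in pmax_s]
        dmin = [int(s) for s in dmin_s]
        dmax = [int(s) for s in dmax_s]
        spr = [int(s) for s in spr_s]
    except ValueError as exc:
        raise EDFFormatError(f"{path}: malformed signal header ({exc})") from None

    if len(set(spr)) != 1:
        raise EDFFormatError(
            f"{path}: channels carry different samples-per-record {sorted(set(spr))}; "
            "mixed-rate EDF files are rejected"
        )
    samples_per_record = spr[0]
    fs = samples_per_record / record_duration

    expected = offset + 2 * ns * samples_per_record * n_records
    if len(raw) < expected:
        raise EDFFormatError(f"{path}: truncated payload")

    data = np.frombuffer(raw[offset:expected], dtype="<i2")
    data = data.reshape(n_records, ns, samples_per_record)
    signal = np.concatenate([data[r] for r in range(n_records)], axis=1).astype(np.float64)
    for ch in range(ns):
        span_d = dmax[ch] - dmin[ch]
        if span_d == 0:
            raise EDFFormatError(f"{path}: zero digital span on channel {ch}")
        signal[ch] = (signal[ch] - dmin[ch]) / span_d * (pmax[ch] - pmin[ch]) + pmin[ch]

    return EEGRecord(signal=signal, fs=fs, channel_names=labels)
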