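"""Minimal EDF (European Data Format) writer.

Writes plain 16-bit EDF with one-second data records, sufficient to
round-trip multichannel EEG through standard readers.  Physical min/max are
taken per channel from the data; the ASCII header fields are formatted
first and parsed back so the quantisation uses exactly the values a reader
will see.  The recording length must be a whole number of seconds and the
sampling rate an integer (one record per second).
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> tuple[bytes, float]:
    """Format a number into a fixed-width field; return (bytes, parsed value)."""
    for fmt in (f"{{:.{p}g}}" for p in range(10, 0, -1)):
        s = fmt.format(float(value))
        if len(s) <= width:
            return s.ljust(width).encode("ascii"), float(s)
    raise ValueError(f"cannot format {value} in {width} characters")


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    channel_labels: list[str],
    physical_dim: str = "uV",
) -> None:
    """Write a channels x samples array as a plain EDF file.

    Raises if ``fs`` is not an integer or the number of samples is not a
    whole multiple of ``fs`` (EDF stores an integral number of fixed-length
    records; this writer uses one-second records and refuses to pad).
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    fs_i = int(round(fs))
    if abs(fs - fs_i) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    if n_samp % fs_i != 0:
        raise ValueError(
            f"{n_samp} samples is not a whole number of 1 s records at {fs_i} Hz"
        )
    n_records = n_samp // fs_i
    if len(channel_labels) != n_ch:
        raise ValueError("one label per channel required")

    pmins, pmaxs = [], []
    digital = np.empty_like(data, dtype=np.int16)
    header_sig = {k: [] for k in ("pmin", "pmax")}
    for c in range(n_ch):
        lo, hi = float(data[c].min()), float(data[c].max())
        if hi <= lo:
            hi = lo + 1.0  # constant channel: avoid zero physical span
        pmin_b, pmin = _num(lo)
        pmax_b, pmax = _num(hi)
        if pmax <= pmin:  # formatting collapsed the span
            pmax_b, pmax = _num(pmin + 1.0)
        header_sig["pmin"].append(pmin_b)
        header_sig["pmax"].append(pmax_b)
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        digital[c] = np.clip(
            np.round((data[c] - pmin) * scale) + _DIG_MIN, _DIG_MIN, _DIG_MAX
        ).astype(np.int16)
        pmins.append(pmin)
        pmaxs.append(pmax)

    header = b""
    header += _ascii("0", 8)  # version
    header += _ascii("X X X X", 80)  # patient id
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)  # recording id
    header += _ascii("01.01.00", 8)  # start date
    header += _ascii("00.00.00", 8)  # start time
    header += _ascii(256 * (n_ch + 1), 8)  # header bytes
    header += _ascii("", 44)  # reserved
    header += _ascii(n_records, 8)
    header += _ascii("1", 8)  # record duration (s)
    header += _ascii(n_ch, 4)
    header += b"".join(_ascii(lbl, 16) for lbl in channel_labels)
    header += b"".join(_ascii("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_ascii(physical_dim, 8) for _ in range(n_ch))
    header += b"".join(header_sig["pmin"])
    header += b"".join(header_sig["pmax"])
    header += b"".join(_ascii(_DIG_MIN, 8) for _ in range(n_ch))
    header += b"".join(_ascii(_DIG_MAX, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_ascii(fs_i, 8) for _ in range(n_ch))  # samples per record
    header += b"".join(_ascii("", 32) for _ in range(n_ch))  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        rec = digital.reshape(n_ch, n_records, fs_i)
        for r in range(n_records):
            fh.write(rec[:, r, :].astype("<i2").tobytes())
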