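"""Minimal EDF (European Data Format) reader/writer.

Implements the plain 16-bit EDF container: a 256-byte fixed header,
256 bytes of per-signal header, and contiguous little-endian int16 data
records.  Signals are stored in physical units (µV here) via the standard
linear digital→physical mapping; writing therefore quantizes each channel
onto a 16-bit grid spanning its physical min/max.  Reading a file written
by :func:`write_edf` recovers the quantized signal exactly.

Only equal-rate signals and a single data-record duration are supported,
which covers laboratory electrophysiology exports.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

HEADER_BYTES = 256
SIGNAL_HEADER_BYTES = 256
DIG_MIN = -32768
DIG_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width and isinstance(value, float):
        s = _float_str(value, width)
    return s[:width].ljust(width).encode("ascii")


def _float_str(value: float, width: int) -> str:
    """Shortest-precision decimal that fits the fixed-width field."""
    for prec in range(10, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    return f"{value:.0e}"[:width]


def _channel_scaling(x: np.ndarray) -> tuple[float, float]:
    """Physical (min, max) for a channel; degenerate ranges are widened."""
    pmin = float(np.min(x)) if x.size else -1.0
    pmax = float(np.max(x)) if x.size else 1.0
    if not (math.isfinite(pmin) and math.isfinite(pmax)):
        raise ValueError("signal contains non-finite values")
    if pmax <= pmin:
        pmax = pmin + 1.0
    # integer-valued channels: a unit-step grid stores them exactly
    if (x.size and np.array_equal(x, np.rint(x))
            and pmax - pmin <= DIG_MAX - DIG_MIN
            and abs(pmin) < 1e7 and abs(pmin + DIG_MAX - DIG_MIN) < 1e7):
        return float(int(pmin)), float(int(pmin) + DIG_MAX - DIG_MIN)
    # round-trip through the 8-char header fields so the digitization
    # uses exactly the scaling a reader will parse back
    pmin = float(_float_str(pmin, 8))
    pmax = float(_float_str(pmax, 8))
    if pmax <= pmin:
        pmax = pmin + 1.0
    return pmin, pmax


def write_edf(
    path,
    signals: np.ndarray,
    sample_rate: float,
    labels: list[str] | None = None,
    physical_dimension: str = "uV",
) -> Path:
    """Write ``signals`` (channels × samples) to a plain EDF file.

    Data are chunked into 1-second records; the final record is
    zero-padded when the length is not an integer number of seconds
    (the true sample count travels in the caller's sidecar).
    """
    path = Path(path)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = signals.shape
    if n_samp == 0:
        raise ValueError("cannot write zero-length signals")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if labels is None:
        labels = [f"CH{i + 1:02d}" for i in range(n_ch)]

    # 1 s records; integer samples per record required by the format
    if float(sample_rate).is_integer():
        record_dur = 1.0
        spr = int(sample_rate)
    else:  # non-integer rates: one record spanning the whole signal
        record_dur = n_samp / sample_rate
        spr = n_samp
    n_records = int(math.ceil(n_samp / spr))

    scalings = [_channel_scaling(signals[c]) for c in range(n_ch)]
    header_len = HEADER_BYTES + SIGNAL_HEADER_BYTES * n_ch

    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))
        fh.write(_ascii_field("X X X X", 80))          # patient id
        fh.write(_ascii_field("Startdate X X X X", 80))  # recording id
        fh.write(_ascii_field("01.01.00", 8))
        fh.write(_ascii_field("00.00.00", 8))
        fh.write(_ascii_field(header_len, 8))
        fh.write(_ascii_field("", 44))
        fh.write(_ascii_field(n_records, 8))
        fh.write(_ascii_field(record_dur if record_dur != int(record_dur)
                              else int(record_dur), 8))
        fh.write(_ascii_field(n_ch, 4))

        for c in range(n_ch):
            fh.write(_ascii_field(labels[c], 16))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 80))             # transducer
        for _ in range(n_ch):
            fh.write(_ascii_field(physical_dimension, 8))
        for c in range(n_ch):
            fh.write(_ascii_field(scalings[c][0], 8))
        for c in range(n_ch):
            fh.write(_ascii_field(scalings[c][1], 8))
        for _ in range(n_ch):
            fh.write(_ascii_field(DIG_MIN, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field(DIG_MAX, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 80))             # prefiltering
        for _ in range(n_ch):
            fh.write(_ascii_field(spr, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 32))

        # digitize once per channel, then interleave by record
        digital = np.empty((n_ch, n_records * spr), dtype=np.int16)
        for c in range(n_ch):
            pmin, pmax = scalings[c]
            gain = (DIG_MAX - DIG_MIN) / (pmax - pmin)
            padded = np.zeros(n_records * spr)
            padded[:n_samp] = signals[c]
            dig = np.rint((padded - pmin) * gain) + DIG_MIN
            digital[c] = np.clip(dig, DIG_MIN, DIG_MAX).astype(np.int16)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(digital[:, sl].astype("<i2").tobytes())
    return path


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read a plain EDF file → (channels × samples in physical units,
    sample_rate, labels).  Trailing zero-padding is *not* trimmed here."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(HEADER_BYTES)
        if len(head) < HEADER_BYTES:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        n_ch = int(head[252:256].decode("ascii").strip())

        sig_head = fh.read(SIGNAL_HEADER_BYTES * n_ch)

        def field(offset, width, c):
            start = offset * n_ch + width * c
            return sig_head[start:start + width].decode("ascii").strip()

        labels = [field(0, 16, c) for c in range(n_ch)]
        pmins = [float(field(16 + 80 + 8, 8, c).replace(" ", ""))
                 for c in range(n_ch)]
        pmaxs = [float(field(16 + 80 + 8 + 8, 8, c).replace(" ", ""))
                 for c in range(n_ch)]
        dmins = [int(field(16 + 80 + 8 + 16, 8, c)) for c in range(n_ch)]
        dmaxs = [int(field(16 + 80 + 8 + 24, 8, c)) for c in range(n_ch)]
        sprs = [int(field(16 + 80 + 8 + 32 + 80, 8, c))
                for c in range(n_ch)]
        if len(set(sprs)) != 1:
            raise ValueError(f"{path}: per-channel sample rates differ")
        spr = sprs[0]
        if record_dur <= 0:
            raise ValueError(f"{path}: non-positive record duration")
        sample_rate = spr / record_dur

        raw = np.frombuffer(fh.read(), dtype="<i2")
    expected = n_records * spr * n_ch
    if raw.size < expected:
        raise ValueError(f"{path}: truncated data records")
    raw = raw[:expected].reshape(n_records, n_ch, spr)
    signals = np.empty((n_ch, n_records * spr))
    for c in range(n_ch):
        gain = (pmaxs[c] - pmins[c]) / (dmaxs[c] - dmins[c])
        signals[c] = (raw[:, c, :].reshape(-1).astype(float) - dmins[c]) \
            * gain + pmins[c]
    return signals, sample_rate, labels
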