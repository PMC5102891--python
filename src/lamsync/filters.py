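"""Band splitting and line-noise removal.

The acquisition chain band-passes 1–10 000 Hz with a 60 Hz notch; offline,
the broadband signal is split into the local field potential (LFP,
1–100 Hz) and multi-unit activity (MUA, 300–3000 Hz) bands.  All filters
here are zero-phase (forward–backward) so that synchrony lags downstream
are not filter artifacts: a 4th-order Butterworth is applied with
``sosfiltfilt``, whose odd-reflection padding (3 section lengths) confines
edge effects to roughly the first/last 100 ms at the default orders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

LFP_BAND = (1.0, 100.0)
MUA_BAND = (300.0, 3000.0)
#: minimum sampling rate at which the MUA band can be extracted
MUA_MIN_RATE = 2.0 * MUA_BAND[1]


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification plus the mains notch."""

    low_hz: float
    high_hz: float
    notch_hz: float = 60.0
    notch_q: float = 30.0
    order: int = 4

    def validate(self, rate: float):
        nyq = rate / 2.0
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low < high")
        if self.high_hz >= nyq:
            raise ValueError(
                f"high edge {self.high_hz} Hz ≥ Nyquist {nyq} Hz")


def bandpass(x, rate: float, low_hz: float, high_hz: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input."""
    BandSpec(low_hz, high_hz, order=order).validate(rate)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def notch(x, rate: float, f0: float = 60.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``f0`` (quality factor ``q``)."""
    if f0 >= rate / 2.0:
        raise ValueError(f"notch frequency {f0} Hz ≥ Nyquist {rate / 2} Hz")
    x = np.asarray(x, dtype=float)
    b, a = sps.iirnotch(f0, q, fs=rate)
    return sps.filtfilt(b, a, x, axis=-1)


def split_bands(x, rate: float) -> dict:
    """Split a broadband signal into LFP and MUA bands.

    Returns ``{"lfp": array, "mua": array | None, "mua_available": bool}``;
    the MUA band needs ``rate ≥ 6000 Hz`` and is flagged unavailable below
    that.
    """
    x = np.asarray(x, dtype=float)
    lfp = bandpass(x, rate, *LFP_BAND)
    if rate >= MUA_MIN_RATE:
        mua = bandpass(x, rate, *MUA_BAND)
        return {"lfp": lfp, "mua": mua, "mua_available": True}
    return {"lfp": lfp, "mua": None, "mua_available": False}


def acquisition_chain(x, rate: float, low_hz: float = 1.0,
                      high_hz: float = 10_000.0,
                      notch_hz: float = 60.0) -> np.ndarray:
    """Emulate the on-board chain: wide band-pass plus mains notch."""
    high = min(high_hz, 0.45 * rate)  # keep the edge below Nyquist
    return notch(bandpass(x, rate, low_hz, high), rate, notch_hz)
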