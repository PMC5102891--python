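"""Lag-resolved cross-correlograms and laminar synchrony profiles.

Synchrony between simultaneously recorded channels is measured with
normalized cross-correlograms over a ±0.3 s offset at the native sampling
resolution (one bin per sample).  Each lag's value is the Pearson
correlation of the overlapping extents, so values lie in [−1, 1]:
in-phase signals give values near +1 at zero lag, and a negative zero-lag
value marks a phase reversal — the biomarker of disrupted
cortico–subcortical coupling near a cortical malformation.

The per-channel profile is referenced to cortical channel 5 (the
approximate granular layer).  The group-level "cross-correlation value"
of a channel is its zero-lag correlation; the peak value and its lag are
reported alongside.  A positive peak lag means the test channel lags the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bursts import BurstEvent
from .core import RecordingSession
from . import stats as _stats


@dataclass
class Correlogram:
    lags_s: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.values) > 1.0 + 1e-6):
            raise ValueError("correlation values outside [−1, 1]")

    @property
    def zero_lag_value(self) -> float:
        return float(self.values[np.argmin(np.abs(self.lags_s))])

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.values))

    @property
    def peak_value(self) -> float:
        return float(self.values[self.peak_index])

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags_s[self.peak_index])


@dataclass
class SynchronyProfile:
    ref_channel: int
    channels: np.ndarray          # 1-based ids
    zero_lag: np.ndarray          # per channel
    peak: np.ndarray
    peak_lag_s: np.ndarray
    window: str = "full"          # "bursts" when burst-gated

    def value(self, channel_id: int) -> float:
        return float(self.zero_lag[list(self.channels).index(channel_id)])


def _validate_xy(x, y, rate, max_lag_s):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    max_lag = int(round(max_lag_s * rate))
    if len(x) <= 2 * max_lag:
        raise ValueError(
            f"series length {len(x)} too short for ±{max_lag} sample lags")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant series have no defined correlation")
    return x, y, max_lag


def crosscorrelogram(x, y, rate: float, max_lag_s: float = 0.3,
                     method: str = "fft") -> Correlogram:
    """Per-lag Pearson correlogram of x(t) against y(t + τ).

    ``method="fft"`` computes the cross-products with an FFT correlation
    and the per-lag means/variances with cumulative sums;
    ``method="direct"`` is the brute-force per-lag computation kept as an
    independent cross-check.
    """
    x, y, max_lag = _validate_xy(x, y, rate, max_lag_s)
    n = len(x)
    lags = np.arange(-max_lag, max_lag + 1)

    if method == "direct":
        vals = np.empty(len(lags))
        for i, k in enumerate(lags):
            if k >= 0:
                a, b = x[:n - k], y[k:]
            else:
                a, b = x[-k:], y[:n + k]
            vals[i] = np.corrcoef(a, b)[0, 1]
    elif method == "fft":
        cx = np.concatenate(([0.0], np.cumsum(x)))
        cy = np.concatenate(([0.0], np.cumsum(y)))
        cxx = np.concatenate(([0.0], np.cumsum(x * x)))
        cyy = np.concatenate(([0.0], np.cumsum(y * y)))
        full = sps.correlate(x, y, mode="full", method="fft")
        # full[n−1−k] = Σ_i x[i]·y[i+k]
        sxy = full[n - 1 - lags]
        m = (n - np.abs(lags)).astype(float)
        pos = lags >= 0
        sx = np.where(pos, cx[n - lags * pos], cx[n] - cx[-lags * ~pos])
        sy = np.where(pos, cy[n] - cy[lags * pos], cy[n + lags * ~pos])
        sxx = np.where(pos, cxx[n - lags * pos],
                       cxx[n] - cxx[-lags * ~pos])
        syy = np.where(pos, cyy[n] - cyy[lags * pos],
                       cyy[n + lags * ~pos])
        varx = sxx - sx * sx / m
        vary = syy - sy * sy / m
        denom = np.sqrt(np.maximum(varx, 0.0) * np.maximum(vary, 0.0))
        num = sxy - sx * sy / m
        vals = np.divide(num, denom, out=np.zeros_like(num),
                         where=denom > 0)
    else:
        raise ValueError(f"unknown method {method!r}")

    vals = np.clip(vals, -1.0, 1.0)
    return Correlogram(lags_s=lags / rate, values=vals)


def _burst_concat(signal: np.ndarray, rate: float,
                  intervals) -> np.ndarray:
    segs = []
    for iv in intervals:
        s, e = (iv.start_s, iv.end_s) if isinstance(iv, BurstEvent) else iv
        segs.append(signal[..., int(round(s * rate)):int(round(e * rate))])
    return np.concatenate(segs, axis=-1)


def synchrony_profile(session: RecordingSession, ref_channel: int = 5,
                      burst_intervals=None,
                      max_lag_s: float = 0.3) -> SynchronyProfile:
    """Zero-lag/peak correlation of every channel against the reference.

    When burst intervals are given, correlograms are computed on the
    concatenated burst segments (the analysis focus); otherwise on the
    whole recording.
    """
    sig = session.signal
    rate = session.sample_rate
    window = "full"
    if burst_intervals:
        sig = _burst_concat(sig, rate, burst_intervals)
        window = "bursts"
    ref = sig[ref_channel - 1]
    if np.std(ref) == 0:
        raise ValueError(f"reference channel {ref_channel} is constant")

    ids = session.channel_ids
    zero = np.empty(len(ids))
    peak = np.empty(len(ids))
    plag = np.empty(len(ids))
    for i, ch in enumerate(ids):
        cg = crosscorrelogram(ref, sig[ch - 1], rate, max_lag_s)
        zero[i], peak[i], plag[i] = (cg.zero_lag_value, cg.peak_value,
                                     cg.peak_lag_s)
    return SynchronyProfile(ref_channel=ref_channel, channels=ids,
                            zero_lag=zero, peak=peak, peak_lag_s=plag,
                            window=window)


def phase_reversal_channels(profile: SynchronyProfile,
                            threshold: float = -0.3) -> set:
    """Channels whose zero-lag correlation is ≤ threshold (phase
    reversed); contiguity is not required."""
    return {int(ch) for ch, v in zip(profile.channels, profile.zero_lag)
            if v <= threshold}


def distance_synchrony_correlation(points) -> dict:
    """Pearson association between lesion distance and the cortical vs.
    subcortical zero-lag correlation; ``points`` is a sequence of
    (distance_um, correlation) pairs."""
    pts = np.asarray(list(points), dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    return _stats.pearson(pts[:, 0], pts[:, 1])
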