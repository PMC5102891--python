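"""Multi-unit spike detection and burst-coupled firing.

Spikes are the large negative-going deflections of the 300–3000 Hz band.
The noise level is estimated robustly as ``σ = median(|x|)/0.6745`` (the
MAD estimate, insensitive to the spikes themselves); a deflection
crossing ``−4.5 σ`` is a spike, aligned to its negative peak, with a 1 ms
refractory interval.  No spike sorting is attempted — the analysis is of
multi-unit deflections, not isolated units.

Burst coupling is quantified as the ratio of the firing rate inside
detected LFP bursts to the rate outside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

MIN_MUA_RATE = 6000.0
REFRACTORY_S = 0.001


@dataclass
class SpikeTrain:
    channel: int
    spike_times_s: np.ndarray
    threshold_uV: float
    sigma_estimate_uV: float

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if np.any(np.diff(self.spike_times_s) < REFRACTORY_S - 1e-12):
            raise ValueError("spike times violate the refractory interval")

    def __len__(self):
        return len(self.spike_times_s)


def mad_sigma(x) -> float:
    """Robust noise SD: median absolute deviation scaled to Gaussian."""
    return float(np.median(np.abs(np.asarray(x, dtype=float))) / 0.6745)


def detect_spikes(mua, rate: float, channel: int = 1,
                  threshold_mult: float = 4.5) -> SpikeTrain:
    """Negative-threshold, peak-aligned spike detection on the MUA band."""
    if rate < MIN_MUA_RATE:
        raise ValueError(
            f"rate {rate} Hz below the {MIN_MUA_RATE:.0f} Hz minimum for "
            "the 300–3000 Hz band")
    mua = np.asarray(mua, dtype=float)
    sigma = mad_sigma(mua)
    thr = threshold_mult * sigma
    if sigma == 0:
        return SpikeTrain(channel, np.array([]), thr, sigma)
    peaks, _ = sps.find_peaks(-mua, height=thr,
                              distance=max(int(REFRACTORY_S * rate), 1))
    return SpikeTrain(channel, peaks / rate, thr, sigma)


def burst_spike_modulation(train: SpikeTrain, burst_intervals,
                           total_duration_s: float) -> dict:
    """In-burst vs. out-of-burst firing rates and their ratio."""
    if len(train) == 0:
        raise ValueError("empty spike train: modulation undefined")
    iv = [(b.start_s, b.end_s) if hasattr(b, "start_s") else (b[0], b[1])
          for b in burst_intervals]
    t_in = sum(e - s for s, e in iv)
    t_out = total_duration_s - t_in
    if t_in <= 0 or t_out <= 0:
        raise ValueError("need positive in-burst and out-of-burst time")
    times = train.spike_times_s
    in_mask = np.zeros(len(times), dtype=bool)
    for s, e in iv:
        in_mask |= (times >= s) & (times < e)
    rate_in = in_mask.sum() / t_in
    rate_out = (~in_mask).sum() / t_out
    return {"rate_in_hz": float(rate_in), "rate_out_hz": float(rate_out),
            "modulation_ratio": float(rate_in / rate_out)
            if rate_out > 0 else np.inf}


def spike_histogram(train: SpikeTrain, bin_s: float,
                    duration_s: float | None = None) -> tuple:
    """(bin_edges_s, counts); bins are half-open [edge, next_edge)."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    times = train.spike_times_s
    end = duration_s if duration_s is not None else bin_s
    if len(times):
        end = max(end, float(times[-1]) + 1e-9)   # counts always conserve
    n_bins = int(np.ceil(end / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    idx = np.floor(times / bin_s).astype(int)
    counts = np.bincount(idx, minlength=len(edges) - 1)[:len(edges) - 1]
    return edges, counts
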