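"""Power spectral density and band powers over 1–20 Hz.

The PSD is a Welch average of Hann-windowed 2-s segments with 50% overlap,
zero-padded so the frequency grid is ≲0.01 Hz, density-normalized
(µV²/Hz) so the integral over [0, Nyquist] approximates the signal
variance.  Band powers integrate the density over the conventional rodent
EEG bands, which tile [1, 20) Hz:

    δ 1–4, θ 4–8, α 8–12, σ 12–15, β 15–20 Hz

and ``total_1_20`` is their sum — the "total power (1–20 Hz)" used for
state/group contrasts.  All group comparisons downstream are ratio-based,
so the density-vs-amplitude normalization choice cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: (low, high) in Hz; half-open bands tiling [1, 20)
DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 15.0),
    "beta": (15.0, 20.0),
}
TOTAL_BAND = (1.0, 20.0)


@dataclass
class PSDResult:
    freqs: np.ndarray          # Hz, strictly increasing
    power: np.ndarray          # µV²/Hz, ≥ 0
    sample_len_s: float = 2.0
    overlap: float = 0.5
    window: str = "hann"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("PSD must be non-negative")


@dataclass
class BandPowers:
    """Integrated band powers in µV² plus their 1–20 Hz total."""

    delta: float
    theta: float
    alpha: float
    sigma: float
    beta: float
    total_1_20: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("delta", "theta", "alpha", "sigma", "beta",
                          "total_1_20")}


def _nfft_for(rate: float, nperseg: int, freq_resolution_hz: float) -> int:
    nfft = int(2 ** np.ceil(np.log2(max(rate / freq_resolution_hz,
                                        nperseg))))
    return nfft


def psd(x, rate: float, sample_len_s: float = 2.0, overlap: float = 0.5,
        freq_resolution_hz: float = 0.01) -> PSDResult:
    """Welch PSD (Hann window, 50% overlap, zero-padded fine grid)."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(sample_len_s * rate))
    if len(x) < nperseg:
        raise ValueError(
            f"signal ({len(x)} samples) shorter than one analysis window "
            f"({nperseg} samples)")
    noverlap = int(round(nperseg * overlap))
    nfft = _nfft_for(rate, nperseg, freq_resolution_hz)
    freqs, power = sps.welch(x, fs=rate, window="hann", nperseg=nperseg,
                             noverlap=noverlap, nfft=nfft,
                             detrend="constant", scaling="density")
    return PSDResult(freqs=freqs, power=power, sample_len_s=sample_len_s,
                     overlap=overlap)


def band_power(result: PSDResult, low_hz: float, high_hz: float) -> float:
    """Trapezoidal integral of the density over [low, high] Hz."""
    f, p = result.freqs, result.power
    if low_hz < f[0] - 1e-9 or high_hz > f[-1] + 1e-9:
        raise ValueError(
            f"PSD grid [{f[0]:.3g}, {f[-1]:.3g}] Hz does not cover "
            f"band [{low_hz}, {high_hz}] Hz")
    # interpolate the density at the exact band edges so bands tile exactly
    grid = np.concatenate(([low_hz], f[(f > low_hz) & (f < high_hz)],
                           [high_hz]))
    dens = np.interp(grid, f, p)
    return float(np.trapezoid(dens, grid))


def band_powers(result: PSDResult,
                bands: dict | None = None) -> BandPowers:
    """Integrate the PSD over the δ/θ/α/σ/β bands; total is their sum."""
    bands = DEFAULT_BANDS if bands is None else bands
    vals = {name: band_power(result, lo, hi)
            for name, (lo, hi) in bands.items()}
    return BandPowers(total_1_20=float(sum(vals.values())), **vals)


def total_power(result: PSDResult) -> float:
    """Integral over the full 1–20 Hz range."""
    return band_power(result, *TOTAL_BAND)


def spectrogram(x, rate: float, step_s: float,
                window_s: float = 2.0,
                freq_resolution_hz: float = 0.05):
    """Sliding-window PSD: (times, freqs, power[time, freq]).

    Columns are single Hann-windowed periodograms of successive windows;
    the number of windows is floor((len − window)/step) + 1.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    x = np.asarray(x, dtype=float)
    nwin = int(round(window_s * rate))
    if len(x) < nwin:
        raise ValueError("signal shorter than one window")
    step = max(int(round(step_s * rate)), 1)
    starts = np.arange(0, len(x) - nwin + 1, step)
    nfft = _nfft_for(rate, nwin, freq_resolution_hz)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    out = np.empty((len(starts), len(freqs)))
    for i, s in enumerate(starts):
        f, p = sps.periodogram(x[s:s + nwin], fs=rate, window="hann",
                               nfft=nfft, detrend="constant",
                               scaling="density")
        out[i] = p
    times = (starts + nwin / 2.0) / rate
    return times, freqs, out
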