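"""Synthetic recordings with ground truth.

Emulates the signal structure the analysis assumes, with known labels:

* three anesthetic states — *suppression* (near-flat noise),
  *burst/suppression* (1–3 s bursts of 4–12 Hz content recurring 1–12
  times per 60 s on a low-amplitude 1–4 Hz background), and *slow-wave*
  (continuous high-amplitude 1–4 Hz activity);
* a laminar amplitude jump at the cortex/subcortex boundary (first
  subcortical channel, default 13);
* cortico–subcortical phase inversion: subcortical channels carry
  ``inversion_alpha × source`` (α = −1 is a full zero-lag phase reversal),
  with α optionally a monotone function of the distance to the lesion;
* burst-coupled multi-unit spiking (Poisson, elevated inside bursts);
* a staged EEG day whose slow-wave-sleep epochs carry spike-wave
  discharges at ~8 spikes/s.

Bursts are a single shared latent source (a sum of 2–4 random-frequency
4–12 Hz sinusoids under a tapered envelope) mixed into every channel —
bursts in real laminar recordings appear near-simultaneously across the
whole probe with no focal layer of origin, and a shared source reproduces
that.  Inter-burst intervals are gamma-distributed with the configured
mean rate; burst durations are lognormal.  Phase inversion is
instantaneous sign-mixing rather than a time delay, so the anti-phase
relation holds exactly at zero lag.

Identical ``(config, seed)`` give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import EEGSession, RecordingSession

STATES = ("suppression", "burst_suppression", "slow_wave")
SLEEP_STAGES = ("ActiveWake", "QuietWake", "NREM", "REM")


def default_alpha_of_distance(distance_um: float) -> float:
    """Monotone map lesion distance → subcortical mixing coefficient.

    Full phase reversal (α = −1) at the lesion, crossing zero at
    1200 µm — the range over which strong negative cortico–subcortical
    correlations are seen — and saturating at +1 by 2400 µm.
    """
    return float(np.clip(distance_um / 1200.0 - 1.0, -1.0, 1.0))


@dataclass
class SynthConfig:
    """Generator parameters; defaults encode the emulated study regime."""

    n_channels: int = 16
    spacing_um: float = 100.0
    cortex_boundary_channel: int | None = None   # None → 13 or last
    sample_rate: float = 1000.0        # 20 kHz supported, 1 kHz for speed
    state_schedule: tuple = (("burst_suppression", 60.0),)

    # burst/suppression structure
    burst_rate_per_min: float = 7.0    # mid-range of 1–12 per 60 s
    burst_dur_mean_s: float = 2.0      # bursts typically last 1–3 s
    burst_dur_sd_s: float = 0.5
    burst_band: tuple = (4.0, 12.0)
    background_band: tuple = (1.0, 4.0)
    suppression_noise_uV: float = 5.0
    background_gain: float = 0.3       # low-amp delta background, × noise SD
    burst_gain: float = 10.0           # burst amplitude, × noise SD
    slow_wave_gain: float = 8.0        # slow-wave amplitude, × noise SD

    # laminar structure
    laminar_profile: tuple | None = None   # per-channel gain; None → built
    subcortical_gain: float = 2.0          # the laminar jump when built
    inversion_alpha: float | None = None   # None → from distance, else ±…
    channel_alpha: tuple | None = None     # per-channel mixing override
    distance_to_lesion_um: float | None = None

    # multi-unit spiking (waveforms injected only when rate ≥ 6 kHz)
    spike_rate_in_burst_hz: float = 20.0
    spike_rate_out_burst_hz: float = 2.0
    spike_amp_uV: float = 60.0

    # EEG day / sleep / SWD
    eeg_sample_rate: float = 100.0
    eeg_duration_s: float = 7200.0
    epoch_s: float = 2.0
    stage_dwell_s: float = 120.0
    eeg_noise_uV: float = 10.0
    swd_rate_per_hour: float = 3.0
    swd_spike_hz: float = 8.0          # inside the observed 7–9 spikes/s
    swd_dur_s: float = 2.0
    swd_amp_uV: float = 200.0     # ≈ 6× the slow-wave-sleep background SD

    group: str = "control"
    isoflurane_pct: float = 1.0
    animal_id: str = "synthetic"
    session_id: str = "synthetic"

    def __post_init__(self):
        for name in ("burst_rate_per_min", "spike_rate_in_burst_hz",
                     "spike_rate_out_burst_hz", "swd_rate_per_hour"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.inversion_alpha is not None \
                and not -1.0 <= self.inversion_alpha <= 1.0:
            raise ValueError("inversion_alpha must lie in [−1, 1]")
        for state, dur in self.state_schedule:
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            if dur <= 0:
                raise ValueError("schedule durations must be positive")
        if self.cortex_boundary_channel is None:
            self.cortex_boundary_channel = min(13, self.n_channels)

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.state_schedule))

    def resolved_alpha(self) -> float:
        if self.inversion_alpha is not None:
            return self.inversion_alpha
        if self.distance_to_lesion_um is not None:
            return default_alpha_of_distance(self.distance_to_lesion_um)
        return 1.0   # no lesion: subcortex in phase with cortex

    def resolved_laminar_profile(self) -> np.ndarray:
        if self.laminar_profile is not None:
            prof = np.asarray(self.laminar_profile, dtype=float)
            if len(prof) != self.n_channels:
                raise ValueError("laminar_profile length ≠ n_channels")
            return prof
        prof = np.ones(self.n_channels)
        prof[self.cortex_boundary_channel - 1:] = self.subcortical_gain
        return prof


@dataclass
class GroundTruth:
    """Labels the generator guarantees; all times in s, half-open."""

    burst_intervals: list = field(default_factory=list)
    state_labels: list = field(default_factory=list)    # per epoch
    state_epoch_s: float = 10.0
    inverted_channels: set = field(default_factory=set)
    spike_times: dict = field(default_factory=dict)     # channel → array
    hypnogram: list = field(default_factory=list)       # per EEG epoch
    swd_intervals: list = field(default_factory=list)   # (start, end, n)
    alpha: float | None = None


# ---------------------------------------------------------------------------
# multielectrode recording

def _burst_waveform(n: int, rate: float, band: tuple,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS burst: 2–4 sinusoids in ``band`` under a tapered envelope
    with mild slow modulation.  Carriers stay 1 Hz inside the band edges so
    modulation sidebands remain within the band."""
    from scipy.signal.windows import tukey

    t = np.arange(n) / rate
    k = rng.integers(2, 5)
    lo, hi = band[0] + 1.0, band[1] - 1.0
    # one dominant carrier plus weak partials: rich spectrum without the
    # deep beat nulls that would fragment an envelope detector
    w = np.sin(2 * np.pi * rng.uniform(lo, hi) * t
               + rng.uniform(0, 2 * np.pi))
    for _ in range(k - 1):
        f = rng.uniform(lo, hi)
        w += rng.uniform(0.1, 0.25) * np.sin(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    env = tukey(n, 0.3)          # flat top, brief tapers
    fmod = rng.uniform(1.0, 2.0)
    env = env * (1.0 + 0.25 * np.sin(2 * np.pi * fmod * t
                                     + rng.uniform(0, 2 * np.pi)))
    w *= env
    rms = np.sqrt(np.mean(w ** 2))
    return w / rms if rms > 0 else w


def _bandlimited_noise(n: int, rate: float, band: tuple,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to ``band`` (FFT masking)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _draw_burst_intervals(t0: float, t1: float, cfg: SynthConfig,
                          rng: np.random.Generator) -> list:
    """Gamma inter-onset intervals (shape 2) with the configured mean rate;
    lognormal durations clipped to [0.5, 4] s; no overlaps."""
    if cfg.burst_rate_per_min <= 0:
        return []
    mean_ioi = 60.0 / cfg.burst_rate_per_min
    mu = math.log(cfg.burst_dur_mean_s ** 2
                  / math.sqrt(cfg.burst_dur_mean_s ** 2
                              + cfg.burst_dur_sd_s ** 2))
    sig = math.sqrt(math.log(1.0 + (cfg.burst_dur_sd_s
                                    / cfg.burst_dur_mean_s) ** 2))
    out = []
    t = t0 + rng.gamma(2.0, mean_ioi / 2.0)
    prev_end = t0
    while t < t1:
        t = max(t, prev_end + 0.3)   # keep a detectable suppression gap
        dur = float(np.clip(rng.lognormal(mu, sig), 0.5, 4.0))
        end = min(t + dur, t1)
        if end - t >= 0.5:
            out.append((t, end))
            prev_end = end
        # gamma draws are inter-onset intervals, so the mean rate holds
        t = t + rng.gamma(2.0, mean_ioi / 2.0)
    return out


def generate_recording(config: SynthConfig,
                       seed: int) -> tuple[RecordingSession, GroundTruth]:
    """Simulate a laminar recording and its ground truth."""
    cfg = config
    rate = cfg.sample_rate
    n = int(round(cfg.duration_s * rate))
    if cfg.duration_s < cfg.epoch_s:
        raise ValueError("schedule shorter than one epoch")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EC]))

    source = np.zeros(n)
    gt = GroundTruth(alpha=cfg.resolved_alpha())
    noise_sd = cfg.suppression_noise_uV
    # amplitude reference: gains are multiples of the suppressed floor;
    # a nominal 5 µV floor applies when sensor noise is disabled
    ref = noise_sd if noise_sd > 0 else 5.0

    t_cursor = 0.0
    for state, dur in cfg.state_schedule:
        i0 = int(round(t_cursor * rate))
        i1 = int(round((t_cursor + dur) * rate))
        if state == "burst_suppression":
            if cfg.background_gain > 0:
                source[i0:i1] += (cfg.background_gain * ref
                                  * _bandlimited_noise(
                                      i1 - i0, rate, cfg.background_band,
                                      rng))
            for (bs, be) in _draw_burst_intervals(
                    t_cursor, t_cursor + dur, cfg, rng):
                j0, j1 = int(round(bs * rate)), int(round(be * rate))
                source[j0:j1] += (cfg.burst_gain * ref
                                  * _burst_waveform(j1 - j0, rate,
                                                    cfg.burst_band, rng))
                gt.burst_intervals.append((bs, be))
        elif state == "slow_wave":
            source[i0:i1] += (cfg.slow_wave_gain * ref
                              * _bandlimited_noise(i1 - i0, rate,
                                                   cfg.background_band,
                                                   rng))
        t_cursor += dur

    # per-epoch ground-truth state labels (dominant scheduled state)
    ep = gt.state_epoch_s
    n_epochs = int(cfg.duration_s / ep)
    for e in range(n_epochs):
        mid = (e + 0.5) * ep
        t_cursor = 0.0
        for state, dur in cfg.state_schedule:
            if t_cursor <= mid < t_cursor + dur:
                gt.state_labels.append(state)
                break
            t_cursor += dur

    alpha = gt.alpha
    prof = cfg.resolved_laminar_profile()
    sub0 = cfg.cortex_boundary_channel - 1
    if cfg.channel_alpha is not None:
        mix = np.asarray(cfg.channel_alpha, dtype=float)
        if len(mix) != cfg.n_channels:
            raise ValueError("channel_alpha length ≠ n_channels")
    else:
        mix = np.ones(cfg.n_channels)
        mix[sub0:] = alpha
    gt.inverted_channels = {int(c + 1) for c in range(cfg.n_channels)
                            if mix[c] < 0}

    signal = (prof * mix)[:, None] * source[None, :]
    if noise_sd > 0:
        signal = signal + noise_sd * rng.standard_normal(
            (cfg.n_channels, n))

    # burst-coupled multi-unit spiking
    in_burst = np.zeros(n, dtype=bool)
    for (bs, be) in gt.burst_intervals:
        in_burst[int(round(bs * rate)):int(round(be * rate))] = True
    frac_in = in_burst.mean() if n else 0.0
    inject = rate >= 6000.0
    if inject:
        half = max(int(round(0.0003 * rate)), 1)   # ±0.3 ms biphasic lobe
        tt = np.arange(-half, half + 1) / rate
        wf = -np.exp(-(tt / 0.0002) ** 2) + 0.4 * np.exp(
            -((tt - 0.0004) / 0.0003) ** 2)
        wf *= cfg.spike_amp_uV
    for c in range(cfg.n_channels):
        n_in = rng.poisson(cfg.spike_rate_in_burst_hz
                           * frac_in * cfg.duration_s)
        n_out = rng.poisson(cfg.spike_rate_out_burst_hz
                            * (1 - frac_in) * cfg.duration_s)
        idx_in = np.flatnonzero(in_burst)
        idx_out = np.flatnonzero(~in_burst)
        picks = []
        if n_in and len(idx_in):
            picks.append(rng.choice(idx_in, size=min(n_in, len(idx_in)),
                                    replace=False))
        if n_out and len(idx_out):
            picks.append(rng.choice(idx_out, size=min(n_out, len(idx_out)),
                                    replace=False))
        idx = np.sort(np.concatenate(picks)) if picks else np.array([], int)
        # enforce the 1 ms refractory interval
        if len(idx):
            keep = np.concatenate(([True],
                                   np.diff(idx) >= max(int(0.001 * rate),
                                                       1)))
            idx = idx[keep]
        gt.spike_times[c + 1] = idx / rate
        if inject:
            for i in idx:
                j0, j1 = i - half, i + half + 1
                if j0 >= 0 and j1 <= n:
                    signal[c, j0:j1] += wf

    session = RecordingSession(
        signal=signal, sample_rate=rate, group=cfg.group,
        isoflurane_pct=cfg.isoflurane_pct, spacing_um=cfg.spacing_um,
        cortex_boundary_channel=cfg.cortex_boundary_channel,
        distance_to_lesion_um=cfg.distance_to_lesion_um,
        animal_id=cfg.animal_id, session_id=cfg.session_id)
    return session, gt


# ---------------------------------------------------------------------------
# EEG day with sleep stages and SWDs

#: stage transition structure of the synthetic day (semi-Markov)
_STAGE_NEXT = {
    "ActiveWake": [("QuietWake", 1.0)],
    "QuietWake": [("NREM", 0.7), ("ActiveWake", 0.3)],
    "NREM": [("REM", 0.4), ("QuietWake", 0.3), ("NREM", 0.3)],
    "REM": [("QuietWake", 0.5), ("ActiveWake", 0.5)],
}
#: relative mean dwell per stage (× stage_dwell_s)
_DWELL_SCALE = {"ActiveWake": 0.7, "QuietWake": 0.8, "NREM": 1.5,
                "REM": 0.6}


def swd_train(dur_s: float, spike_hz: float, rate: float,
              amp_uV: float) -> tuple[np.ndarray, int]:
    """A spike-wave discharge: sharp negative spikes riding a slow wave.

    Returns (waveform, spike count); spikes sit on a regular grid at
    ``spike_hz`` so the count equals ``round(dur × rate)`` exactly.
    """
    if spike_hz <= 0:
        raise ValueError("swd_spike_hz must be positive")
    n = int(round(dur_s * rate))
    t = np.arange(n) / rate
    spike_t = np.arange(0.5 / spike_hz, dur_s - 1e-9, 1.0 / spike_hz)
    w = 0.35 * amp_uV * np.sin(2 * np.pi * spike_hz * t)   # the wave
    width = max(0.02, 2.0 / rate)
    for st in spike_t:
        w += -amp_uV * np.exp(-((t - st) / width) ** 2)    # the spikes
    return w, len(spike_t)


def generate_eeg_day(config: SynthConfig,
                     seed: int) -> tuple[EEGSession, GroundTruth]:
    """Simulate a staged EEG day with ground-truth hypnogram and SWDs."""
    cfg = config
    if cfg.swd_rate_per_hour > 0 and cfg.swd_spike_hz <= 0:
        raise ValueError("swd_spike_hz must be > 0 when SWDs are enabled")
    rate = cfg.eeg_sample_rate
    epoch = cfg.epoch_s
    n_epochs = int(cfg.eeg_duration_s / epoch)
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    n = int(round(n_epochs * epoch * rate))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEE6]))

    # hypnogram: exponential dwell in whole epochs
    labels = []
    stage = "QuietWake"
    while len(labels) < n_epochs:
        dwell = rng.exponential(cfg.stage_dwell_s * _DWELL_SCALE[stage])
        k = max(int(round(dwell / epoch)), 1)
        labels.extend([stage] * k)
        nxt, probs = zip(*_STAGE_NEXT[stage])
        stage = nxt[rng.choice(len(nxt), p=np.asarray(probs))]
    labels = labels[:n_epochs]

    eeg = np.zeros(n)
    movement = np.zeros(n_epochs)
    sd = cfg.eeg_noise_uV
    spe = int(round(epoch * rate))
    for e, lab in enumerate(labels):
        seg = slice(e * spe, (e + 1) * spe)
        x = 0.3 * sd * rng.standard_normal(spe)
        if lab == "NREM":
            x += 3.0 * sd * _bandlimited_noise(spe, rate, (1.0, 4.0), rng)
            x += 0.3 * sd * _bandlimited_noise(spe, rate, (10.0, 16.0), rng)
        elif lab == "REM":
            x += 2.0 * sd * _bandlimited_noise(spe, rate, (5.5, 8.0), rng)
            x += 0.2 * sd * _bandlimited_noise(spe, rate, (1.0, 4.0), rng)
        else:   # wake: low-amplitude mixed activity
            x += 0.8 * sd * _bandlimited_noise(spe, rate, (1.0, 20.0), rng)
        eeg[seg] = x
        if lab == "ActiveWake":
            movement[e] = rng.uniform(5.0, 20.0)
        else:
            movement[e] = abs(rng.normal(0.0, 0.05))

    gt = GroundTruth(hypnogram=list(labels), state_epoch_s=epoch)

    # SWDs only inside slow-wave (NREM) sleep
    n_swd = rng.poisson(cfg.swd_rate_per_hour * cfg.eeg_duration_s / 3600.0)
    nrem_epochs = [e for e, lab in enumerate(labels) if lab == "NREM"]
    need = int(math.ceil(cfg.swd_dur_s / epoch))
    # candidate starts: runs of NREM long enough to hold one event
    starts = [e for e in nrem_epochs
              if e + need <= n_epochs
              and all(labels[e + j] == "NREM" for j in range(need))]
    placed = []
    for _ in range(n_swd):
        avail = [s for s in starts
                 if all(abs(s - p) >= need + 1 for p in placed)]
        if not avail:
            break
        placed.append(int(rng.choice(avail)))
    for e in sorted(placed):
        t0 = e * epoch
        w, count = swd_train(cfg.swd_dur_s, cfg.swd_spike_hz, rate,
                             cfg.swd_amp_uV)
        i0 = int(round(t0 * rate))
        eeg[i0:i0 + len(w)] += w
        gt.swd_intervals.append((t0, t0 + cfg.swd_dur_s, count))

    session = EEGSession(eeg=eeg, movement=movement, sample_rate=rate,
                         epoch_s=epoch, animal_id=cfg.animal_id,
                         session_id=cfg.session_id)
    return session, gt
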