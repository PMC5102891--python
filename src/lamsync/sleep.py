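"""Rule-based sleep staging and spike-wave discharge (SWD) detection.

Staging follows the classical rodent feature set: per 2-s epoch the EEG
band powers (δ, θ, α, σ, β over 1–20 Hz) are z-scored across the
recording and combined with the integrated movement channel:

1. ActiveWake — movement above its 75th percentile;
2. REM        — elevated θ (z > +0.5) with low δ and σ (z < 0), no movement;
3. NREM       — elevated δ (z > +0.5);
4. QuietWake  — otherwise.

SWDs are rhythmic trains of high-amplitude spikes at 4–12 Hz
(characteristically 7–9 spikes/s) that occur predominantly in slow-wave
sleep.  A candidate spike is a deflection beyond 4× the rolling 30-s
background SD; an event needs ≥4 consecutive spikes with inter-spike
intervals in [1/12, 1/4] s and ≥0.5 s total duration; events closer than
1 s are merged.  Detection runs in every stage — the hypnogram only
annotates each event.  All thresholds are keyword-exposed; they are
operational stand-ins for what is classically scored by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .core import EEGSession
from .spectral import DEFAULT_BANDS
from .synth import SLEEP_STAGES


@dataclass
class Hypnogram:
    epoch_s: float
    labels: list                    # per epoch, one of SLEEP_STAGES
    band_z: np.ndarray              # epochs × 5 z-scored band powers
    movement_flag: np.ndarray       # per epoch

    def fraction(self, stage: str) -> float:
        return self.labels.count(stage) / len(self.labels)


@dataclass
class SWDEvent:
    start_s: float
    end_s: float
    spike_count: int
    during_stage: str = "unknown"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def spike_rate_hz(self) -> float:
        return self.spike_count / self.duration_s


@dataclass
class SeizureSummary:
    n_events: int
    total_duration_s: float
    mean_spikes_per_event: float | None
    per_stage: dict


def _epoch_band_powers(eeg: np.ndarray, rate: float,
                       epoch_s: float) -> np.ndarray:
    """Hann periodogram band powers per epoch (epochs × 5)."""
    spe = int(round(epoch_s * rate))
    n_ep = len(eeg) // spe
    win = np.hanning(spe)
    f = np.fft.rfftfreq(spe, d=1.0 / rate)
    band_masks = [(f >= lo) & (f < hi)
                  for lo, hi in DEFAULT_BANDS.values()]
    segs = eeg[:n_ep * spe].reshape(n_ep, spe)
    segs = (segs - segs.mean(axis=1, keepdims=True)) * win
    spec = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    return np.stack([spec[:, m].sum(axis=1) for m in band_masks], axis=1)


def stage_epochs(session: EEGSession, theta_z: float = 0.5,
                 delta_z: float = 0.5,
                 movement_pct: float = 75.0) -> Hypnogram:
    """Score the recording into 2-s sleep/wake epochs (deterministic)."""
    if session.duration_s < session.epoch_s:
        raise ValueError("recording shorter than one epoch")
    powers = _epoch_band_powers(session.eeg, session.sample_rate,
                                session.epoch_s)
    n_ep = powers.shape[0]
    # log powers: per-epoch spectral estimates are chi²-distributed, so
    # the log stabilises variance and separates the stage modes cleanly
    lp = np.log10(powers + 1e-12)
    mu = lp.mean(axis=0)
    sd = lp.std(axis=0)
    sd[sd == 0] = 1.0
    z = (lp - mu) / sd
    dz, tz, _, sz, _ = z.T

    move = session.movement_per_epoch()[:n_ep]
    # movement rule: 75th-percentile cutoff, guarded at both ends — a
    # mostly-moving animal (median above the absolute floor) uses the
    # floor so every moving epoch flags; a mostly-quiet one raises the
    # cutoff above the sensor-noise tail (20× median)
    med = float(np.median(move))
    movement_floor = 1.0           # integrated-activity units
    if med > movement_floor:
        move_thr = movement_floor
    else:
        move_thr = max(np.percentile(move, movement_pct),
                       20.0 * med, 1e-12)
    moving = move > move_thr

    labels = []
    for e in range(n_ep):
        if moving[e]:
            labels.append("ActiveWake")
        elif tz[e] > theta_z and dz[e] < 0 and sz[e] < 0:
            labels.append("REM")
        elif dz[e] > delta_z:
            labels.append("NREM")
        else:
            labels.append("QuietWake")
    return Hypnogram(epoch_s=session.epoch_s, labels=labels, band_z=z,
                     movement_flag=moving)


def detect_swd(session: EEGSession, hypnogram: Hypnogram | None = None,
               sd_mult: float = 4.0, background_s: float = 30.0,
               min_spikes: int = 4, isi_range=(1.0 / 12.0, 0.25),
               min_dur_s: float = 0.5,
               merge_gap_s: float = 1.0) -> list[SWDEvent]:
    """Detect spike-wave events on the EEG; stage is annotation only."""
    eeg = session.eeg
    rate = session.sample_rate
    w = max(int(round(background_s * rate)), 2)
    # clip at a global robust sigma before the rolling variance so the
    # discharges themselves do not inflate their own detection threshold
    sigma_g = float(np.median(np.abs(eeg - np.median(eeg))) / 0.6745)
    clipped = np.clip(eeg, -4.0 * sigma_g, 4.0 * sigma_g) \
        if sigma_g > 0 else eeg
    bg_var = ndimage.uniform_filter1d(clipped ** 2, size=w,
                                      mode="nearest")
    bg_sd = np.sqrt(np.maximum(bg_var, 1e-30))
    peaks, _ = sps.find_peaks(np.abs(eeg),
                              distance=max(int(rate * isi_range[0] / 2), 1))
    peaks = peaks[np.abs(eeg[peaks]) > sd_mult * bg_sd[peaks]]
    spike_t = peaks / rate

    # chain spikes whose consecutive intervals stay inside the SWD band
    events = []
    run = [0] if len(spike_t) else []
    for i in range(1, len(spike_t)):
        isi = spike_t[i] - spike_t[i - 1]
        if isi_range[0] <= isi <= isi_range[1]:
            run.append(i)
        else:
            events.append(run)
            run = [i]
    if run:
        events.append(run)

    # merge runs separated by < merge_gap_s first (a single missed
    # spike must not split one discharge into two), then filter
    candidates = [[spike_t[r[0]], spike_t[r[-1]] + 1e-9, len(r)]
                  for r in events if len(r) >= 2]
    merged = []
    for c in sorted(candidates):
        if merged and c[0] - merged[-1][1] < merge_gap_s:
            merged[-1][1] = c[1]
            merged[-1][2] += c[2]
        else:
            merged.append(c)

    out = []
    for s, e, count in merged:
        if count < min_spikes:
            continue
        # the train spans (count−1) ISIs; one more ISI closes the last cycle
        mean_isi = (e - s) / (count - 1) if count > 1 else isi_range[1]
        e_full = e + mean_isi
        if e_full - s < min_dur_s:
            continue
        stage = "unknown"
        if hypnogram is not None:
            idx = int(s / hypnogram.epoch_s)
            if idx < len(hypnogram.labels):
                stage = hypnogram.labels[idx]
        out.append(SWDEvent(start_s=float(s), end_s=float(e_full),
                            spike_count=int(count), during_stage=stage))
    return out


def seizure_summary(events: list[SWDEvent],
                    hypnogram: Hypnogram | None = None) -> SeizureSummary:
    """Event totals plus a per-stage cross-tabulation (by start epoch)."""
    per_stage = {s: 0 for s in SLEEP_STAGES}
    for ev in events:
        stage = ev.during_stage
        if stage == "unknown" and hypnogram is not None:
            idx = int(ev.start_s / hypnogram.epoch_s)
            if idx < len(hypnogram.labels):
                stage = hypnogram.labels[idx]
        per_stage[stage] = per_stage.get(stage, 0) + 1
    mean_spikes = (float(np.mean([ev.spike_count for ev in events]))
                   if events else None)
    return SeizureSummary(
        n_events=len(events),
        total_duration_s=float(sum(ev.duration_s for ev in events)),
        mean_spikes_per_event=mean_spikes,
        per_stage=per_stage)
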