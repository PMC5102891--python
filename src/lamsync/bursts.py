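"""Burst detection, anesthetic-state classification, and dose incidence.

Burst/suppression is a hyperexcitable anesthetic state in which a
near-flat (suppressed) field potential is interrupted by 1–3 s bursts of
4–12 Hz activity recurring 1–12 times per 60 s.  The original scoring of
such recordings is visual; here an explicit envelope detector with
hysteresis makes it reproducible:

* envelope = RMS of the LFP in 100 ms sliding windows;
* baseline = 10th percentile of the envelope (the suppressed floor);
* burst onset when the envelope exceeds ``k_on × baseline`` (k_on = 3),
  offset when it falls below ``k_off × baseline`` (k_off = 1.5);
* gaps < 0.2 s are merged, events < 0.3 s discarded.

All five constants are keyword-exposed.  Per-epoch (default 10 s) state
labels follow from the burst time fraction and the envelope level:
*suppression* when essentially burst-free at a near-baseline envelope,
*slow-wave* when high-amplitude activity is continuous, otherwise
*burst/suppression*.  A per-animal :class:`IncidenceRecord` marks the
first (highest) isoflurane level, scanning 3.0→2.0→1.0→0.5%, at which
burst/suppression appeared — the survival-analysis input for the
dose-incidence contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ISOFLURANE_LEVELS

MAX_BURST_S = 30.0


@dataclass
class BurstEvent:
    start_s: float
    end_s: float                 # half-open [start, end)
    peak_envelope_uV: float = np.nan
    channel_scope: str = "per-channel"   # or "global"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self):
        if not 0.0 < self.duration_s < MAX_BURST_S:
            raise ValueError(
                f"burst duration {self.duration_s:.3g} s outside "
                f"(0, {MAX_BURST_S}) s")


@dataclass
class StateSegmentation:
    epoch_s: float
    labels: list                 # per epoch, one of STATES
    burst_fraction: np.ndarray   # per epoch, in [0, 1]


@dataclass
class IncidenceRecord:
    animal_id: str
    group: str
    onset_level: float | None    # isoflurane % at first burst/suppression
    event: bool                  # False = censored (never observed)

    def __post_init__(self):
        if self.event and self.onset_level not in ISOFLURANE_LEVELS:
            raise ValueError(
                f"onset_level {self.onset_level} not a dose level")


def rms_envelope(x, rate: float, window_s: float = 0.1) -> np.ndarray:
    """Sliding-window RMS (centered, uniform window)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = np.asarray(x, dtype=float)
    w = max(int(round(window_s * rate)), 1)
    return np.sqrt(ndimage.uniform_filter1d(x ** 2, size=w,
                                            mode="nearest"))


def _merge_intervals(iv: list, max_gap_s: float) -> list:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s - out[-1][1] < max_gap_s:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(p) for p in out]


def detect_bursts(lfp, rate: float, k_on: float = 3.0, k_off: float = 1.5,
                  window_s: float = 0.1, baseline_pct: float = 10.0,
                  min_dur_s: float = 0.3,
                  merge_gap_s: float = 0.2) -> list[BurstEvent]:
    """Envelope-threshold burst detector with hysteresis.

    An all-zero (or all-subthreshold) signal yields an empty list.
    """
    env = rms_envelope(lfp, rate, window_s)
    baseline = float(np.percentile(env, baseline_pct))
    if baseline <= 0:
        baseline = float(np.mean(env)) or 1.0
    hi, lo = k_on * baseline, k_off * baseline

    above_on = env > hi
    above_off = env > lo
    events = []
    i, n = 0, len(env)
    while i < n:
        if above_on[i]:
            j = i
            while j < n and above_off[j]:
                j += 1
            events.append((i / rate, j / rate))
            i = j
        else:
            i += 1

    events = _merge_intervals(events, merge_gap_s)
    out = []
    for s, e in events:
        if e - s < min_dur_s:
            continue
        peak = float(np.max(env[int(s * rate):max(int(e * rate), 1)]))
        out.append(BurstEvent(s, min(e, s + MAX_BURST_S * 0.999),
                              peak_envelope_uV=peak))
    return out


def consensus_bursts(per_channel_events: list[list[BurstEvent]],
                     min_channels: int | None = None) -> list[BurstEvent]:
    """Global bursts supported by ≥ ``min_channels`` channels at once.

    Default quorum is 75% of channels.  Each global event spans the union
    of the per-channel events touching its quorum core.
    """
    n_ch = len(per_channel_events)
    if n_ch < 2:
        raise ValueError("need events from at least 2 channels")
    if min_channels is None:
        min_channels = int(np.ceil(0.75 * n_ch))
    if min_channels > n_ch:
        raise ValueError("min_channels exceeds channel count")

    edges = []   # (time, +1/-1)
    all_events = []
    for ch_events in per_channel_events:
        for ev in ch_events:
            edges.append((ev.start_s, +1))
            edges.append((ev.end_s, -1))
            all_events.append((ev.start_s, ev.end_s))
    if not edges:
        return []
    edges.sort()
    cores = []
    depth, core_start = 0, None
    for t, d in edges:
        depth += d
        if depth >= min_channels and core_start is None:
            core_start = t
        elif depth < min_channels and core_start is not None:
            cores.append((core_start, t))
            core_start = None
    # union extent: grow each core with every per-channel event overlapping it
    out = []
    for cs, ce in cores:
        s, e = cs, ce
        changed = True
        while changed:
            changed = False
            for (a, b) in all_events:
                if a < e and b > s and (a < s or b > e):
                    s, e = min(s, a), max(e, b)
                    changed = True
        out.append((s, e))
    return [BurstEvent(s, e, channel_scope="global")
            for s, e in _merge_intervals(out, 0.0)]


def classify_state(lfp, rate: float, events: list[BurstEvent],
                   epoch_s: float = 10.0, supp_frac: float = 0.05,
                   slow_frac: float = 0.7, supp_env_mult: float = 2.0,
                   high_env_mult: float = 1.5) -> StateSegmentation:
    """Per-epoch anesthetic-state labels from bursts + envelope stats.

    slow_wave: high-amplitude activity (envelope above ``high_env_mult ×
    baseline``) covers more than ``slow_frac`` of the epoch — continuous
    activity without suppression gaps; suppression: burst fraction below
    ``supp_frac`` with a median envelope below ``supp_env_mult ×
    baseline``; otherwise burst_suppression.
    """
    env = rms_envelope(lfp, rate)
    baseline = float(np.percentile(env, 10.0)) or 1.0
    n_epochs = int(len(lfp) / (epoch_s * rate))
    covered = np.zeros(len(lfp), dtype=bool)
    for ev in events:
        covered[int(ev.start_s * rate):int(ev.end_s * rate)] = True

    labels, fracs = [], np.zeros(n_epochs)
    spe = int(round(epoch_s * rate))
    for e in range(n_epochs):
        seg = slice(e * spe, (e + 1) * spe)
        frac = covered[seg].mean()
        fracs[e] = frac
        med_env = np.median(env[seg])
        high_frac = np.mean(env[seg] > high_env_mult * baseline)
        if high_frac > slow_frac:
            labels.append("slow_wave")
        elif frac < supp_frac and med_env < supp_env_mult * baseline:
            labels.append("suppression")
        else:
            labels.append("burst_suppression")
    return StateSegmentation(epoch_s=epoch_s, labels=labels,
                             burst_fraction=fracs)


def burst_metrics(events: list[BurstEvent],
                  analyzed_duration_s: float) -> dict:
    """Rate per minute and duration statistics of detected bursts."""
    if analyzed_duration_s <= 0:
        raise ValueError("analyzed duration must be positive")
    rate = len(events) / (analyzed_duration_s / 60.0)
    if events:
        durs = np.array([ev.duration_s for ev in events])
        return {"rate_per_min": rate,
                "mean_duration_s": float(np.mean(durs)),
                "sd_duration_s": float(np.std(durs, ddof=1))
                if len(durs) > 1 else 0.0,
                "n_events": len(events)}
    return {"rate_per_min": 0.0, "mean_duration_s": None,
            "sd_duration_s": None, "n_events": 0}


def build_incidence(per_animal_states: dict) -> list[IncidenceRecord]:
    """Incidence records from per-animal classification across doses.

    ``per_animal_states`` maps ``animal_id → {"group": str, "levels":
    {dose_pct: has_burst_suppression}}``.  The onset level is the first
    level, scanning 3.0→2.0→1.0→0.5%, with any burst/suppression epoch;
    an animal with none by 0.5% is censored.
    """
    out = []
    for animal_id, rec in per_animal_states.items():
        levels = rec["levels"]
        if not isinstance(levels, dict):
            pairs = list(levels)
            doses = [d for d, _ in pairs]
            if len(doses) != len(set(doses)):
                raise ValueError(f"duplicate dose entries for {animal_id}")
            levels = dict(pairs)
        onset, event = None, False
        for dose in ISOFLURANE_LEVELS:          # descending scan
            if levels.get(dose):
                onset, event = dose, True
                break
        out.append(IncidenceRecord(animal_id=animal_id,
                                   group=rec["group"],
                                   onset_level=onset, event=event))
    return out
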