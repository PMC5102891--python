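"""End-to-end synthetic study: simulate a cohort, run every analysis
stage, and emit figure-equivalent tables plus a statistics report.

The default :class:`StudyConfig` encodes the study regime being
emulated: 8 control and 9 freeze-lesion (FL) animals, each recorded at
isoflurane steps 3.0→2.0→1.0→0.5%.  Burst/suppression emerges at 2.0%
(or 1.0%) in FL animals but only at 0.5% in controls, a fraction of
controls never bursting (censored); FL animals carry a lesion at
200–2400 µm from the probe whose proximity drives the subcortical phase
inversion, and their bursts carry ~3.7-fold more subcortical power.
The run is fully deterministic under a master seed: per-animal and
per-session seeds come from ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bursts import build_incidence, burst_metrics, classify_state, \
    detect_bursts
from .core import ISOFLURANE_LEVELS
from .filters import bandpass, LFP_BAND
from .spectral import psd, total_power
from .stats import factorial_anova, kaplan_meier_logrank, pearson
from .synchrony import phase_reversal_channels, synchrony_profile
from .synth import SynthConfig, generate_recording

log = logging.getLogger("lamsync.pipeline")


@dataclass
class StudyConfig:
    n_control: int = 8
    n_fl: int = 9
    dose_levels: tuple = ISOFLURANE_LEVELS       # strictly decreasing
    session_duration_s: float = 60.0
    sample_rate: float = 1000.0
    # onset regime: probability of each first-burst/suppression dose
    control_onset_probs: tuple = ((0.5, 0.75), (None, 0.25))
    fl_onset_probs: tuple = ((2.0, 0.7), (1.0, 0.3))
    fl_distance_range_um: tuple = (200.0, 2400.0)
    fl_burst_gain: float = 19.24     # ≈ √3.7 × the control gain of 10
    burst_rate_per_min: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 1 or self.n_fl < 1:
            raise ValueError("group sizes must be ≥ 1")
        if list(self.dose_levels) != sorted(set(self.dose_levels),
                                            reverse=True):
            raise ValueError("dose levels must be strictly decreasing")


def _draw_onset(probs, rng) -> float | None:
    doses, ps = zip(*probs)
    return doses[rng.choice(len(doses), p=np.asarray(ps))]


def _session_config(study: StudyConfig, group: str, dose: float,
                    onset: float | None, distance: float | None,
                    animal_id: str) -> SynthConfig:
    bursting = onset is not None and dose <= onset
    state = "burst_suppression" if bursting else "suppression"
    gain = study.fl_burst_gain if group == "FL" else 10.0
    return SynthConfig(
        sample_rate=study.sample_rate,
        state_schedule=((state, study.session_duration_s),),
        burst_rate_per_min=study.burst_rate_per_min,
        burst_gain=gain,
        distance_to_lesion_um=distance,
        group=group, isoflurane_pct=dose, animal_id=animal_id,
        session_id=f"{animal_id}-iso{dose}")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""


def run_study(study: StudyConfig, out_dir) -> Path:
    """Simulate and analyse the full cohort; returns the output dir.

    Writes ``incidence.csv`` (dose-incidence per animal),
    ``band_power.csv`` (total 1–20 Hz power per electrode × state ×
    group), ``synchrony.csv`` (per-channel zero-lag profile + lesion
    distance), and ``stats.json`` with the study-level statistics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(study.seed)
    animal_seeds = master.spawn(study.n_control + study.n_fl)

    roster = [("control", f"C{i + 1:02d}") for i in range(study.n_control)] \
        + [("FL", f"F{i + 1:02d}") for i in range(study.n_fl)]

    incidence_inputs = {}
    power_rows, sync_rows, burst_rows = [], [], []
    stage = "simulate"
    try:
        for (group, animal_id), ss in zip(roster, animal_seeds):
            rng = np.random.default_rng(ss)
            onset = _draw_onset(study.control_onset_probs
                                if group == "control"
                                else study.fl_onset_probs, rng)
            distance = (float(rng.uniform(*study.fl_distance_range_um))
                        if group == "FL" else None)
            levels = {}
            for dose in study.dose_levels:
                stage = f"simulate:{animal_id}@{dose}"
                sess_dist = distance
                if distance is not None:
                    # electrode repositioned between sessions
                    sess_dist = float(np.clip(
                        distance + rng.uniform(-100, 100), 0, None))
                cfg = _session_config(study, group, dose, onset,
                                      sess_dist, animal_id)
                sess_seed = int(rng.integers(0, 2 ** 31 - 1))
                session, gt = generate_recording(cfg, sess_seed)

                stage = f"bursts:{animal_id}@{dose}"
                lfp_all = bandpass(session.signal, session.sample_rate,
                                   *LFP_BAND)
                lfp5 = lfp_all[4]
                events = detect_bursts(lfp5, session.sample_rate)
                seg = classify_state(lfp5, session.sample_rate, events)
                has_bs = "burst_suppression" in seg.labels
                levels[dose] = has_bs
                metrics = burst_metrics(events, session.duration_s)
                burst_rows.append({"animal_id": animal_id, "group": group,
                                   "isoflurane_pct": dose, **metrics})

                stage = f"psd:{animal_id}@{dose}"
                state_label = max(set(seg.labels), key=seg.labels.count)
                for ch in session.channel_ids:
                    # 0.1 Hz grid: ample for band integrals, much faster
                    tp = total_power(psd(lfp_all[ch - 1],
                                         session.sample_rate,
                                         freq_resolution_hz=0.1))
                    power_rows.append({
                        "animal_id": animal_id, "group": group,
                        "isoflurane_pct": dose, "state": state_label,
                        "channel": int(ch),
                        "total_power_uV2": tp})

                stage = f"synchrony:{animal_id}@{dose}"
                if has_bs and events:
                    prof = synchrony_profile(session, ref_channel=5,
                                             burst_intervals=events)
                    reversed_ch = phase_reversal_channels(prof)
                    for ch, z, pk, pl in zip(prof.channels, prof.zero_lag,
                                             prof.peak, prof.peak_lag_s):
                        sync_rows.append({
                            "animal_id": animal_id, "group": group,
                            "isoflurane_pct": dose,
                            "distance_um": sess_dist,
                            "channel": int(ch), "zero_lag": float(z),
                            "peak": float(pk), "peak_lag_s": float(pl),
                            "phase_reversed": int(ch) in reversed_ch})
            incidence_inputs[animal_id] = {"group": group,
                                           "levels": levels}

        stage = "incidence"
        records = build_incidence(incidence_inputs)
        inc_df = pd.DataFrame(
            [{"animal_id": r.animal_id, "group": r.group,
              "onset_level": r.onset_level, "event": r.event}
             for r in records])
        surv = kaplan_meier_logrank(records)

        stage = "stats"
        power_df = pd.DataFrame(power_rows)
        sync_df = pd.DataFrame(sync_rows)
        power_df["log_power"] = np.log10(power_df["total_power_uV2"])
        aov = factorial_anova(power_df, "log_power",
                              ["group", "state", "channel"])

        fl_sync = sync_df[(sync_df["group"] == "FL")
                          & (sync_df["channel"] == 13)]
        dist_corr = pearson(fl_sync["distance_um"], fl_sync["zero_lag"]) \
            if len(fl_sync) >= 3 else None

        grp_mean_13 = sync_df[sync_df["channel"] == 13] \
            .groupby("group")["zero_lag"].mean().to_dict()
        near = sync_df[(sync_df["group"] == "FL")
                       & (sync_df["channel"] == 13)
                       & (sync_df["distance_um"] < 1200)]

        stats_block = {
            "version": _version(),
            "seed": study.seed,
            "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(study).items()},
            "median_onset_level": surv.median_onset_level,
            "logrank_chi2": surv.logrank_chi2,
            "logrank_p": surv.logrank_p,
            "anova_p": {k: float(aov.table.loc[k, "p"])
                        for k in aov.table.index},
            "mean_zero_lag_ch13": grp_mean_13,
            "mean_zero_lag_ch13_fl_near_lesion":
                float(near["zero_lag"].mean()) if len(near) else None,
            "distance_synchrony": dist_corr,
        }

        stage = "write"
        inc_df.to_csv(out / "incidence.csv", index=False)
        pd.DataFrame(burst_rows).to_csv(out / "burst_metrics.csv",
                                        index=False)
        power_df.to_csv(out / "band_power.csv", index=False)
        sync_df.to_csv(out / "synchrony.csv", index=False)
        (out / "stats.json").write_text(json.dumps(stats_block, indent=1))
    except Exception as exc:                      # noqa: BLE001
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    log.info("study complete: %s", out)
    return out


_REQUIRED_TABLES = ("incidence.csv", "band_power.csv", "synchrony.csv",
                    "stats.json")


def report(results_dir) -> str:
    """Deterministic human-readable summary of a finished study run."""
    d = Path(results_dir)
    missing = [t for t in _REQUIRED_TABLES if not (d / t).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing study outputs in {d}: {', '.join(missing)}")
    stats = json.loads((d / "stats.json").read_text())
    inc = pd.read_csv(d / "incidence.csv")
    lines = [
        "# Synthetic cohort study report",
        f"package version: {stats['version']}; master seed: "
        f"{stats['seed']}",
        "",
        "## Burst/suppression incidence (dose-stepped Kaplan-Meier)",
    ]
    for g, m in stats["median_onset_level"].items():
        n = int((inc["group"] == g).sum())
        lines.append(f"- {g} (n={n}): median onset "
                     f"{m if m is not None else 'not reached'}% isoflurane")
    lines.append(f"- log-rank chi2 = {stats['logrank_chi2']:.3f}, "
                 f"p = {stats['logrank_p']:.2e}")
    lines += ["", "## Spectral power ANOVA (log10 total 1-20 Hz power)"]
    for effect, p in stats["anova_p"].items():
        lines.append(f"- {effect}: p = {p:.3g}")
    lines += ["", "## Cortico-subcortical synchrony (channel 13 vs 5)"]
    for g, v in stats["mean_zero_lag_ch13"].items():
        lines.append(f"- mean zero-lag correlation, {g}: {v:+.3f}")
    if stats.get("mean_zero_lag_ch13_fl_near_lesion") is not None:
        lines.append(f"- FL within 1200 um of lesion: "
                     f"{stats['mean_zero_lag_ch13_fl_near_lesion']:+.3f}")
    dc = stats.get("distance_synchrony")
    if dc:
        lines.append(f"- distance vs synchrony: Pearson r = "
                     f"{dc['r']:.3f}, p = {dc['p']:.3g} (n = {dc['n']})")
    lines += ["", "## Parameters", "```",
              json.dumps(stats["parameters"], indent=1), "```", ""]
    return "\n".join(lines)


def _version() -> str:
    from . import __version__
    return __version__
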