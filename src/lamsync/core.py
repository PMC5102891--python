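"""Core data types and container I/O.

A :class:`RecordingSession` is a laminar multielectrode recording:
channels × samples in µV, channel 1 the most superficial contact, contacts
spaced ``spacing_um`` apart so that ``depth(i) = (i − 1) × spacing``.
Channels at and below ``cortex_boundary_channel`` (default 13) are treated
as subcortical.  An :class:`EEGSession` is a single-channel cortical EEG
plus an integrated movement-activity trace scored in fixed epochs.

Sessions travel as EDF (signals) plus a JSON sidecar (metadata the EDF
header cannot hold: treatment group, isoflurane level, lesion distance).
Time is seconds from recording start; intervals are half-open [start, end).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf

GROUPS = ("control", "FL")
ISOFLURANE_LEVELS = (3.0, 2.0, 1.0, 0.5)

#: sidecar keys that must be present for a multielectrode session
REQUIRED_RECORDING_META = ("group", "isoflurane_pct")


class SidecarError(KeyError):
    """Metadata sidecar missing or incomplete; names the missing field."""


@dataclass
class RecordingSession:
    """Laminar multielectrode recording with acquisition/lesion metadata."""

    signal: np.ndarray            # channels × samples, µV
    sample_rate: float            # Hz
    group: str                    # "control" | "FL"
    isoflurane_pct: float         # one of ISOFLURANE_LEVELS
    spacing_um: float = 100.0
    #: first subcortical channel (1-based); None → 13 or the last channel
    cortex_boundary_channel: int | None = None
    distance_to_lesion_um: float | None = None
    animal_id: str = "animal"
    session_id: str = "session"

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.cortex_boundary_channel is None:
            self.cortex_boundary_channel = min(13, self.n_channels)
        if not 1 <= self.cortex_boundary_channel <= self.n_channels:
            raise ValueError("cortex_boundary_channel outside channel range")
        if self.distance_to_lesion_um is not None \
                and self.distance_to_lesion_um < 0:
            raise ValueError("distance_to_lesion_um must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def channel_ids(self) -> np.ndarray:
        """1-based channel indices, 1 = most superficial contact."""
        return np.arange(1, self.n_channels + 1)

    @property
    def channel_depths_um(self) -> np.ndarray:
        return (self.channel_ids - 1) * self.spacing_um

    def channel(self, channel_id: int) -> np.ndarray:
        """Signal of a 1-based channel id."""
        if not 1 <= channel_id <= self.n_channels:
            raise IndexError(f"channel {channel_id} out of range")
        return self.signal[channel_id - 1]

    @property
    def subcortical_channels(self) -> np.ndarray:
        return np.arange(self.cortex_boundary_channel, self.n_channels + 1)


def channel_depth_um(channel_id: int, spacing_um: float = 100.0) -> float:
    """Depth of a 1-based channel id: (i − 1) × spacing."""
    if channel_id < 1:
        raise ValueError("channel ids are 1-based")
    return (channel_id - 1) * spacing_um


@dataclass
class EEGSession:
    """Single-channel cortical EEG with a movement-activity trace."""

    eeg: np.ndarray               # µV
    movement: np.ndarray          # non-negative activity, per sample or epoch
    sample_rate: float
    epoch_s: float = 2.0
    animal_id: str = "animal"
    session_id: str = "session"

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=float).ravel()
        self.movement = np.asarray(self.movement, dtype=float).ravel()
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if np.any(self.movement < 0):
            raise ValueError("movement activity must be non-negative")
        n_ep = self.n_epochs
        if len(self.movement) not in (len(self.eeg), n_ep):
            raise ValueError(
                "movement must be per-sample or per-epoch over the same "
                f"duration as the EEG ({len(self.movement)} vs "
                f"{len(self.eeg)} samples / {n_ep} epochs)")

    @property
    def duration_s(self) -> float:
        return len(self.eeg) / self.sample_rate

    @property
    def n_epochs(self) -> int:
        return int(len(self.eeg) / (self.epoch_s * self.sample_rate))

    def movement_per_epoch(self) -> np.ndarray:
        """Integrated activity per epoch (sums samples if per-sample)."""
        n_ep = self.n_epochs
        if len(self.movement) == n_ep:
            return self.movement.copy()
        spe = int(round(self.epoch_s * self.sample_rate))
        return np.add.reduceat(
            self.movement[:n_ep * spe], np.arange(0, n_ep * spe, spe))


# ---------------------------------------------------------------------------
# results container

class ResultsTable:
    """Long-format results keyed by (animal_id, session_id, channel,
    measure); one value + unit per key.  Thin veneer over a DataFrame."""

    KEY = ["animal_id", "session_id", "channel", "measure"]

    def __init__(self, df: pd.DataFrame | None = None):
        cols = self.KEY + ["value", "unit"]
        self.df = pd.DataFrame(columns=cols) if df is None else df[cols].copy()
        if self.df.duplicated(self.KEY).any():
            raise ValueError("duplicate (animal, session, channel, measure) keys")

    def add(self, animal_id, session_id, channel, measure, value, unit=""):
        key = (animal_id, session_id, channel, measure)
        if len(self.df) and (self.df[self.KEY] == key).all(axis=1).any():
            raise ValueError(f"duplicate key {key}")
        self.df.loc[len(self.df)] = [*key, value, unit]

    def to_csv(self, path):
        self.df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        return cls(pd.read_csv(path))

    def __len__(self):
        return len(self.df)


# ---------------------------------------------------------------------------
# session I/O: EDF + JSON sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_session(session, path) -> Path:
    """Write a session as EDF + JSON sidecar; returns the EDF path.

    Signals are quantized onto each channel's 16-bit physical grid;
    a write→read round trip is exact for already-quantized data and
    within one quantization step otherwise.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(session, RecordingSession):
        if session.n_samples == 0:
            raise ValueError("cannot write zero-length session")
        meta = {
            "type": "recording",
            "group": session.group,
            "isoflurane_pct": session.isoflurane_pct,
            "spacing_um": session.spacing_um,
            "cortex_boundary_channel": session.cortex_boundary_channel,
            "animal_id": session.animal_id,
            "session_id": session.session_id,
            "n_samples": session.n_samples,
            "sample_rate": session.sample_rate,
        }
        if session.distance_to_lesion_um is not None:
            meta["distance_to_lesion_um"] = session.distance_to_lesion_um
        edf.write_edf(path, session.signal, session.sample_rate)
    elif isinstance(session, EEGSession):
        if len(session.eeg) == 0:
            raise ValueError("cannot write zero-length session")
        meta = {
            "type": "eeg",
            "epoch_s": session.epoch_s,
            "animal_id": session.animal_id,
            "session_id": session.session_id,
            "n_samples": len(session.eeg),
            "sample_rate": session.sample_rate,
            "movement_per_epoch": len(session.movement) == session.n_epochs,
        }
        if meta["movement_per_epoch"]:
            # per-epoch movement goes to the sidecar, not the EDF
            meta["movement"] = [float(v) for v in session.movement]
            edf.write_edf(path, session.eeg[None, :], session.sample_rate,
                          labels=["EEG"])
        else:
            edf.write_edf(
                path, np.vstack([session.eeg, session.movement]),
                session.sample_rate, labels=["EEG", "MOV"])
    else:
        raise TypeError(f"unsupported session type {type(session)!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_session(path):
    """Read an EDF + sidecar pair written by :func:`write_session`.

    Also accepts a foreign EDF with a hand-written sidecar, provided the
    sidecar carries the required metadata fields.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SidecarError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    signals, rate, labels = edf.read_edf(path)
    n_samples = int(meta.get("n_samples", signals.shape[1]))
    signals = signals[:, :n_samples]

    kind = meta.get("type", "recording")
    if kind == "recording":
        missing = [k for k in REQUIRED_RECORDING_META if k not in meta]
        if missing:
            raise SidecarError(
                f"sidecar {sidecar} missing required field(s): "
                + ", ".join(missing))
        return RecordingSession(
            signal=signals,
            sample_rate=rate,
            group=meta["group"],
            isoflurane_pct=float(meta["isoflurane_pct"]),
            spacing_um=float(meta.get("spacing_um", 100.0)),
            cortex_boundary_channel=int(
                meta.get("cortex_boundary_channel", 13)),
            distance_to_lesion_um=meta.get("distance_to_lesion_um"),
            animal_id=meta.get("animal_id", "animal"),
            session_id=meta.get("session_id", "session"),
        )
    if kind == "eeg":
        if meta.get("movement_per_epoch"):
            movement = np.asarray(meta["movement"], dtype=float)
            eeg_sig = signals[0]
        elif "MOV" in labels:
            eeg_sig = signals[labels.index("EEG")]
            movement = signals[labels.index("MOV")]
        else:
            raise SidecarError(f"sidecar {sidecar} missing field: movement")
        return EEGSession(
            eeg=eeg_sig, movement=np.maximum(movement, 0.0),
            sample_rate=rate, epoch_s=float(meta.get("epoch_s", 2.0)),
            animal_id=meta.get("animal_id", "animal"),
            session_id=meta.get("session_id", "session"),
        )
    raise SidecarError(f"unknown session type {kind!r} in {sidecar}")


def session_equal(a, b, atol=0.0) -> bool:
    """Equality of two sessions of the same kind (signals within atol)."""
    if type(a) is not type(b):
        return False
    da, db = dataclasses.asdict(a), dataclasses.asdict(b)
    for key in da:
        va, vb = da[key], db[key]
        if isinstance(va, np.ndarray):
            if va.shape != vb.shape or not np.allclose(va, vb, atol=atol,
                                                       rtol=0.0):
                return False
        elif va != vb:
            return False
    return True
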