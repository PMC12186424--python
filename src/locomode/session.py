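"""Session data model and directory I/O.

A *session* is one continuous multichannel recording of a walking trial:
surface EMG, inertial (accelerometer + gyroscope) axes and a uniaxial
ground-reaction-force (GRF) channel, all sampled on a common clock, plus the
conductor's raw mode-transition markers and the participant's body weight.

On disk a session is a directory::

    session_dir/
        meta.json      fs, body weight, initial mode, channel specs, markers
        signals.csv    samples x channels, header row = channel ids
     or signals.h5     HDF5 dataset "signals" with attribute "channel_ids"

Sample ``i`` occurs at ``t = i / fs_hz`` seconds (0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "LocomotionMode",
    "Modality",
    "ChannelSpec",
    "ModeMarker",
    "SessionRecording",
    "mode_at",
    "read_session",
    "write_session",
]


class LocomotionMode(str, Enum):
    """The five locomotion modes, serialized as two-letter codes."""

    W = "W"    # level walking
    RA = "RA"  # ramp ascent
    RD = "RD"  # ramp descent
    SA = "SA"  # stair ascent
    SD = "SD"  # stair descent

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Modality(str, Enum):
    EMG = "EMG"
    ACC = "ACC"
    GYR = "GYR"
    GRF = "GRF"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ChannelSpec:
    """Identity and physical meaning of one recorded channel."""

    channel_id: str
    modality: Modality
    axis: Optional[str] = None  # "x" | "y" | "z" for ACC/GYR, None otherwise
    placement: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.modality in (Modality.ACC, Modality.GYR):
            if self.axis not in ("x", "y", "z"):
                raise ValidationError(
                    f"channel {self.channel_id!r}: {self.modality} requires axis x/y/z"
                )
        elif self.axis is not None:
            raise ValidationError(
                f"channel {self.channel_id!r}: {self.modality} must not carry an axis"
            )

    @property
    def is_imu(self) -> bool:
        return self.modality in (Modality.ACC, Modality.GYR)

    def to_dict(self) -> dict:
        return {
            "channel_id": self.channel_id,
            "modality": self.modality.value,
            "axis": self.axis,
            "placement": self.placement,
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSpec":
        return cls(
            channel_id=d["channel_id"],
            modality=Modality(d["modality"]),
            axis=d.get("axis"),
            placement=d.get("placement", ""),
            units=d.get("units", ""),
        )


@dataclass(frozen=True)
class ModeMarker:
    """One raw conductor tag: 'the participant is about to enter target_mode'."""

    time_s: float
    target_mode: LocomotionMode

    def to_dict(self) -> dict:
        return {"time_s": self.time_s, "target_mode": self.target_mode.value}

    @classmethod
    def from_dict(cls, d: dict) -> "ModeMarker":
        return cls(time_s=float(d["time_s"]), target_mode=LocomotionMode(d["target_mode"]))


@dataclass
class SessionRecording:
    """One synchronized multichannel recording.

    ``signals`` is channel-by-sample (shape ``(n_channels, n_samples)``).
    """

    fs_hz: float
    signals: np.ndarray
    channels: list[ChannelSpec]
    markers: list[ModeMarker] = field(default_factory=list)
    body_weight_n: float = 700.0
    initial_mode: LocomotionMode = LocomotionMode.W
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        if self.body_weight_n <= 0:
            raise ValidationError("body_weight_n must be positive")
        if self.signals.ndim != 2:
            raise ValidationError("signals must be a 2-D channel-by-sample array")
        if self.signals.shape[0] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel specs but {self.signals.shape[0]} signal rows"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("channel_id values must be unique within a session")
        times = [m.time_s for m in self.markers]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("markers must be strictly increasing in time")
        for m1, m2 in zip(self.markers, self.markers[1:]):
            if m1.target_mode == m2.target_mode:
                raise ValidationError("consecutive markers must have different target modes")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"no channel {channel_id!r} in session") from None

    def indices_of(self, modality: Modality) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.modality == modality]

    @property
    def grf(self) -> np.ndarray:
        idx = self.indices_of(Modality.GRF)
        if len(idx) != 1:
            raise ValidationError(f"expected exactly one GRF channel, found {len(idx)}")
        return self.signals[idx[0]]

    def mode_at(self, time_s: float) -> LocomotionMode:
        return mode_at(self, time_s)


def mode_at(
    session: SessionRecording,
    time_s: float,
    markers: Optional[list[ModeMarker]] = None,
) -> LocomotionMode:
    """Ground-truth mode at ``time_s`` under the *raw* marker timeline.

    Piecewise-constant and right-continuous: a marker takes effect exactly at
    its own timestamp. Before the first marker the session's ``initial_mode``
    holds. Only meaningful before marker realignment; the labeling module's
    realigned timeline is the authoritative one for training and scoring.
    """
    if time_s < 0:
        raise ValidationError("time_s must be non-negative")
    if markers is None:
        markers = session.markers
    mode = session.initial_mode
    for m in markers:
        if m.time_s <= time_s:
            mode = m.target_mode
        else:
            break
    return mode


# -- directory I/O ---------------------------------------------------------

_META_NAME = "meta.json"
_CSV_NAME = "signals.csv"
_H5_NAME = "signals.h5"


def write_session(session: SessionRecording, path, fmt: str = "csv") -> None:
    """Write a session directory (``meta.json`` + ``signals.csv``/``signals.h5``).

    Numeric fidelity of the CSV dialect is at least 1e-6 relative (17
    significant digits are written, so round-trip is in fact exact for
    float64); integers round-trip bit-exactly in both dialects.
    """
    if fmt not in ("csv", "h5"):
        raise ValueError(f"fmt must be 'csv' or 'h5', got {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs_hz": session.fs_hz,
        "body_weight_n": session.body_weight_n,
        "initial_mode": session.initial_mode.value,
        "channels": [c.to_dict() for c in session.channels],
        "markers": [m.to_dict() for m in session.markers],
        "meta": session.meta,
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))
    if fmt == "csv":
        df = pd.DataFrame(session.signals.T, columns=session.channel_ids)
        df.to_csv(path / _CSV_NAME, index=False, float_format="%.17g")
    else:
        import h5py

        with h5py.File(path / _H5_NAME, "w") as f:
            ds = f.create_dataset("signals", data=session.signals.T)
            ds.attrs["channel_ids"] = session.channel_ids


def read_session(path) -> SessionRecording:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / _META_NAME
    if not meta_path.exists():
        raise FormatError(f"{path}: missing {_META_NAME}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{meta_path}: invalid JSON ({exc})") from exc

    try:
        channels = [ChannelSpec.from_dict(d) for d in meta["channels"]]
        markers = [ModeMarker.from_dict(d) for d in meta["markers"]]
        fs_hz = float(meta["fs_hz"])
        body_weight_n = float(meta["body_weight_n"])
        initial_mode = LocomotionMode(meta["initial_mode"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{meta_path}: {exc}") from exc

    expected_ids = [c.channel_id for c in channels]
    if (path / _CSV_NAME).exists():
        df = pd.read_csv(path / _CSV_NAME)
        found_ids = list(df.columns)
        signals = df.to_numpy(dtype=float).T
    elif (path / _H5_NAME).exists():
        import h5py

        with h5py.File(path / _H5_NAME, "r") as f:
            ds = f["signals"]
            found_ids = [str(s) for s in ds.attrs["channel_ids"]]
            signals = np.asarray(ds, dtype=float).T
    else:
        raise FormatError(f"{path}: neither {_CSV_NAME} nor {_H5_NAME} present")

    if found_ids != expected_ids:
        raise FormatError(
            f"{path}: metadata lists {len(expected_ids)} channels "
            f"{expected_ids} but signals table has {found_ids}"
        )
    return SessionRecording(
        fs_hz=fs_hz,
        signals=signals,
        channels=channels,
        markers=markers,
        body_weight_n=body_weight_n,
        initial_mode=initial_mode,
        meta=meta.get("meta", {}),
    )
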