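"""Time-domain features of the event-anchored windows.

Per EMG channel the four classical myoelectric features are computed: mean
absolute value (MAV), waveform length (WL), zero crossings (ZC) and
slope-sign changes (SSC); ZC and SSC accept an amplitude deadband (default
0). Per IMU axis and per GRF channel the four summary statistics mean, max,
min and standard deviation (sample, N-1) are computed.

With the study montage — 8 EMG channels, 3 six-axis IMUs (18 axes) and one
GRF channel — the full multimodal vector has 4 x (8 + 18 + 1) = 108
entries. Ordering is canonical: channels in session order (restricted to
the selected modalities), features in the fixed per-modality order above;
names are ``<channel_id>.<feature>``.

All feature functions operate along the last axis, so a stack of windows
``(n_windows, n_channels, n_samples)`` is reduced in one vectorized call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .labeling import AnalysisWindow
from .session import ChannelSpec, Modality

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "mav",
    "wl",
    "zc",
    "ssc",
    "stat4",
    "assemble_features",
    "feature_names",
    "feature_matrix",
    "EMG_FEATURES",
    "STAT_FEATURES",
]

EMG_FEATURES = ("mav", "wl", "zc", "ssc")
STAT_FEATURES = ("mean", "max", "min", "sd")

# Modality groups selectable in a FeatureConfig; "IMU" covers both the
# accelerometer and gyroscope axes of each unit.
_GROUPS = {
    "EMG": (Modality.EMG,),
    "IMU": (Modality.ACC, Modality.GYR),
    "GRF": (Modality.GRF,),
}


@dataclass(frozen=True)
class FeatureConfig:
    modalities: tuple[str, ...] = ("EMG", "IMU", "GRF")
    zc_deadband: float = 0.0
    ssc_deadband: float = 0.0

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ConfigurationError("modalities must be nonempty")
        object.__setattr__(self, "modalities", tuple(m.upper() for m in self.modalities))
        for m in self.modalities:
            if m not in _GROUPS:
                raise ConfigurationError(f"unknown modality {m!r} (choose from {list(_GROUPS)})")
        if self.zc_deadband < 0 or self.ssc_deadband < 0:
            raise ConfigurationError("deadbands must be >= 0")

    def selects(self, channel: ChannelSpec) -> bool:
        return any(channel.modality in _GROUPS[m] for m in self.modalities)

    def to_dict(self) -> dict:
        return {
            "modalities": list(self.modalities),
            "zc_deadband": self.zc_deadband,
            "ssc_deadband": self.ssc_deadband,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            modalities=tuple(d["modalities"]),
            zc_deadband=d.get("zc_deadband", 0.0),
            ssc_deadband=d.get("ssc_deadband", 0.0),
        )


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]
    event: object = None
    window_index: int | None = None


def _check(x: np.ndarray, min_len: int, op: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < min_len:
        raise ValidationError(f"{op} needs at least {min_len} samples, got {x.shape[-1]}")
    return x


def mav(x: np.ndarray) -> np.ndarray:
    """Mean absolute value, (1/N) sum |x_i|."""
    return np.mean(np.abs(_check(x, 1, "mav")), axis=-1)


def wl(x: np.ndarray) -> np.ndarray:
    """Waveform length, sum |x_i - x_{i-1}|."""
    return np.sum(np.abs(np.diff(_check(x, 2, "wl"), axis=-1)), axis=-1)


def zc(x: np.ndarray, deadband: float = 0.0) -> np.ndarray:
    """Zero crossings: sign changes whose amplitude step exceeds the deadband."""
    x = _check(x, 2, "zc")
    a, b = x[..., :-1], x[..., 1:]
    return np.sum((a * b < 0) & (np.abs(a - b) >= deadband), axis=-1)


def ssc(x: np.ndarray, deadband: float = 0.0) -> np.ndarray:
    """Slope-sign changes: local extrema with a neighbor step above the deadband."""
    x = _check(x, 3, "ssc")
    prev, cur, nxt = x[..., :-2], x[..., 1:-1], x[..., 2:]
    d1, d2 = cur - prev, cur - nxt
    return np.sum((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= deadband), axis=-1)


def stat4(x: np.ndarray) -> tuple:
    """(mean, max, min, sd) with sample (N-1) standard deviation."""
    x = _check(x, 2, "stat4")
    return (
        np.mean(x, axis=-1),
        np.max(x, axis=-1),
        np.min(x, axis=-1),
        np.std(x, axis=-1, ddof=1),
    )


def _selected_indices(channels: Sequence[ChannelSpec], config: FeatureConfig) -> list[int]:
    return [i for i, c in enumerate(channels) if config.selects(c)]


def feature_names(channels: Sequence[ChannelSpec], config: FeatureConfig) -> list[str]:
    """Canonical feature-name ordering: channel-major, feature-minor."""
    names = []
    for i in _selected_indices(channels, config):
        c = channels[i]
        feats = EMG_FEATURES if c.modality == Modality.EMG else STAT_FEATURES
        names.extend(f"{c.channel_id}.{f}" for f in feats)
    return names


def _stack_features(
    block: np.ndarray, channels: Sequence[ChannelSpec], config: FeatureConfig
) -> np.ndarray:
    """Features for a stack of windows, shape (..., n_channels, n_samples)."""
    cols = []
    for i in _selected_indices(channels, config):
        x = block[..., i, :]
        if channels[i].modality == Modality.EMG:
            cols.extend(
                [
                    mav(x),
                    wl(x),
                    zc(x, config.zc_deadband).astype(float),
                    ssc(x, config.ssc_deadband).astype(float),
                ]
            )
        else:
            cols.extend(np.asarray(s, dtype=float) for s in stat4(x))
    return np.stack(cols, axis=-1)


def assemble_features(window: AnalysisWindow, config: FeatureConfig | None = None) -> FeatureVector:
    """The multimodal feature vector of one analysis window."""
    config = config or FeatureConfig()
    if not _selected_indices(window.channels, config):
        raise ConfigurationError(
            f"window carries no channel of modalities {config.modalities}"
        )
    values = _stack_features(np.asarray(window.signals, dtype=float), window.channels, config)
    return FeatureVector(
        values=values,
        names=feature_names(window.channels, config),
        event=window.event,
        window_index=window.window_index,
    )


def feature_matrix(
    windows: Iterable[AnalysisWindow], config: FeatureConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Feature rows for many windows at once (vectorized over the stack).

    All windows must share the same montage and length.
    """
    config = config or FeatureConfig()
    windows = list(windows)
    if not windows:
        names = []
        return np.empty((0, 0)), names
    channels = windows[0].channels
    # Batched to bound peak memory on long sessions.
    parts = []
    for lo in range(0, len(windows), 2048):
        block = np.stack(
            [np.asarray(w.signals, dtype=float) for w in windows[lo : lo + 2048]]
        )
        parts.append(_stack_features(block, channels, config))
    X = np.concatenate(parts, axis=0)
    return X, feature_names(channels, config)
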