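"""Gait-event detection from the ground-reaction-force channel.

Heel contact (HC) is an upward crossing of ``threshold_fraction x body
weight`` on the raw GRF signal; toe-off (TO) is the downward crossing of the
same threshold. A crossing only counts if the new phase is *sustained* for at
least ``min_phase_s`` (debouncing against chatter near the threshold), so an
event is emitted at most ``min_phase_s`` after it physically occurred.

The detector is streaming-first: the batch API feeds the whole trace through
the same state machine in one chunk, so chunked and batch outputs are
identical by construction. Internally each chunk is reduced to run-length
segments of the boolean above/below-threshold signal, which keeps replay of
multi-minute 2 kHz recordings cheap.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = [
    "EventKind",
    "GaitEvent",
    "EventDetectorSpec",
    "StreamingEventDetector",
    "detect_events",
    "detect_events_streaming",
    "write_events_csv",
]


class EventKind(str, Enum):
    HC = "HC"  # heel contact: stance begins
    TO = "TO"  # toe-off: swing begins

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GaitEvent:
    sample_index: int
    time_s: float
    kind: EventKind


@dataclass(frozen=True)
class EventDetectorSpec:
    """Threshold as a fraction of body weight, plus the debounce duration."""

    threshold_fraction: float = 0.10
    min_phase_s: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction < 1):
            raise ValidationError("threshold_fraction must lie in (0, 1)")
        if self.min_phase_s < 0:
            raise ValidationError("min_phase_s must be >= 0")

    def to_dict(self) -> dict:
        return {"threshold_fraction": self.threshold_fraction, "min_phase_s": self.min_phase_s}

    @classmethod
    def from_dict(cls, d: dict) -> "EventDetectorSpec":
        return cls(**d)


def _runs(above: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean array as (value, start, length) triples."""
    if above.size == 0:
        return []
    change = np.flatnonzero(np.diff(above.view(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [above.size]))
    return [(bool(above[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


class StreamingEventDetector:
    """Chunk-wise GRF thresholding with persistent debounce state."""

    def __init__(self, spec: EventDetectorSpec, fs: float, body_weight_n: float):
        if body_weight_n <= 0:
            raise ValidationError("body_weight_n must be positive")
        self.spec = spec
        self.fs = fs
        self.threshold_n = spec.threshold_fraction * body_weight_n
        self.min_samples = int(round(spec.min_phase_s * fs))
        self.n_seen = 0
        self._confirmed: bool | None = None  # above-threshold state, None before data
        self._pend_start = -1
        self._pend_len = 0

    def process(self, chunk: np.ndarray) -> list[GaitEvent]:
        chunk = np.asarray(chunk, dtype=float)
        if chunk.size and not np.all(np.isfinite(chunk)):
            raise ValidationError("GRF chunk contains non-finite samples")
        events: list[GaitEvent] = []
        above = chunk >= self.threshold_n
        offset = self.n_seen
        for value, start, length in _runs(above):
            abs_start = offset + start
            if self._confirmed is None:
                # Recording opens mid-phase; adopt it silently (no event).
                self._confirmed = value
                continue
            if value == self._confirmed:
                self._pend_len = 0  # opposite-phase excursion broken
                continue
            if self._pend_len == 0:
                self._pend_start = abs_start
            self._pend_len += length
            if self._pend_len >= self.min_samples:
                kind = EventKind.HC if value else EventKind.TO
                events.append(
                    GaitEvent(self._pend_start, self._pend_start / self.fs, kind)
                )
                self._confirmed = value
                self._pend_len = 0
        self.n_seen += chunk.size
        return events


def detect_events(
    grf: np.ndarray,
    fs: float,
    body_weight_n: float,
    spec: EventDetectorSpec | None = None,
) -> list[GaitEvent]:
    """Detect all HC/TO events in a full GRF trace.

    Kinds strictly alternate; an all-zero trace (or a threshold above the
    trace maximum) yields an empty list.
    """
    spec = spec or EventDetectorSpec()
    det = StreamingEventDetector(spec, fs, body_weight_n)
    return det.process(np.asarray(grf, dtype=float))


def detect_events_streaming(state: StreamingEventDetector, chunk: np.ndarray):
    """Functional wrapper: ``(state, chunk) -> (new events, state)``."""
    return state.process(chunk), state


def write_events_csv(events: list[GaitEvent], path) -> None:
    with Path(path).open("w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["sample_index", "time_s", "kind"])
        for e in events:
            w.writerow([e.sample_index, f"{e.time_s:.6f}", e.kind.value])
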