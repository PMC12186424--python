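"""Marker realignment, event-anchored windows and ground-truth labeling.

The conductor tags each surface change a moment *before* it happens, so the
raw markers lag behind no biomechanical event in particular. Each marker is
therefore projected forward to the first gait event, at or after the tag, of
the kind appropriate for that transition:

* transitions into or out of stair ascent -> next toe-off,
* stair- or ramp-descent transitions -> next heel contact,
* ramp-ascent transitions -> next toe-off (chosen for symmetry with the
  other ascent mode; configurable per transition).

The realigned instant is the *critical timing*: the ideal moment by which
the new mode should be predicted. The realigned timeline (mode switches
inclusively at each critical event) is the authoritative ground truth for
both training labels and online scoring.

At every gait event a 300 ms segment (200 ms before to 100 ms after the
event) is sliced into four 200 ms windows stepped by 30 ms; those windows
are the classifier's inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import EdgeEventError, MarkerCollisionError, UnresolvableMarkerError
from .events import EventKind, GaitEvent
from .session import ChannelSpec, LocomotionMode, ModeMarker, SessionRecording

__all__ = [
    "REALIGN_KIND",
    "realign_kind_for",
    "CriticalTiming",
    "TransitionPeriod",
    "AnalysisWindow",
    "realign_markers",
    "extract_windows",
    "iter_event_windows",
    "label_windows",
    "build_transition_periods",
    "SEGMENT_PRE_S",
    "WINDOW_S",
    "WINDOW_STEP_S",
    "N_WINDOWS",
    "SEGMENT_POST_S",
]

# Segment/window geometry: 300 ms segment = 200 ms before + 100 ms after the
# event; four 200 ms windows stepped by 30 ms from the segment start.
SEGMENT_PRE_S = 0.200
SEGMENT_POST_S = 0.100
WINDOW_S = 0.200
WINDOW_STEP_S = 0.030
N_WINDOWS = 4

# Event kind each mode's transitions realign to (applies entering and
# leaving the mode; every study transition passes through walking, so the
# non-walking endpoint decides).
REALIGN_KIND: dict[LocomotionMode, EventKind] = {
    LocomotionMode.SA: EventKind.TO,
    LocomotionMode.RA: EventKind.TO,
    LocomotionMode.SD: EventKind.HC,
    LocomotionMode.RD: EventKind.HC,
}


def realign_kind_for(
    from_mode: LocomotionMode,
    to_mode: LocomotionMode,
    overrides: Optional[dict] = None,
) -> EventKind:
    """Event kind governing realignment of a (from, to) transition."""
    if overrides and (from_mode, to_mode) in overrides:
        return overrides[(from_mode, to_mode)]
    key = to_mode if to_mode != LocomotionMode.W else from_mode
    if key == LocomotionMode.W:
        # W -> W never occurs (markers change mode); default to toe-off.
        return EventKind.TO
    return REALIGN_KIND[key]


@dataclass(frozen=True)
class CriticalTiming:
    """A transition marker after projection onto its gait event."""

    transition: tuple[LocomotionMode, LocomotionMode]
    raw_marker_time_s: float
    event: GaitEvent
    time_s: float

    @property
    def from_mode(self) -> LocomotionMode:
        return self.transition[0]

    @property
    def to_mode(self) -> LocomotionMode:
        return self.transition[1]


@dataclass(frozen=True)
class TransitionPeriod:
    """Gait-event span within which detecting the transition counts as correct."""

    critical: CriticalTiming
    start_event: GaitEvent
    end_event: GaitEvent
    start_s: float
    end_s: float
    n_before: int = 2
    n_after: int = 3
    truncated: bool = False


@dataclass
class AnalysisWindow:
    """One 200 ms multimodal slice anchored to a gait event.

    ``signals`` is channel-by-sample for all session channels over the
    window's span. ``label`` is the ground-truth mode at the anchoring event
    (inclusive at critical timings); ``context_mode`` is the mode in effect
    just *before* the event — the state a causal decoder would be in when
    the event fires, hence the bank cell the window trains.
    """

    event: GaitEvent
    window_index: int
    start_s: float
    end_s: float
    signals: np.ndarray
    channels: list[ChannelSpec]
    label: Optional[LocomotionMode] = None
    context_mode: Optional[LocomotionMode] = None
    session_id: Optional[str] = None


def realign_markers(
    markers: list[ModeMarker],
    events: list[GaitEvent],
    initial_mode: LocomotionMode = LocomotionMode.W,
    rule_overrides: Optional[dict] = None,
) -> list[CriticalTiming]:
    """Project each raw marker forward to its critical-timing gait event.

    Raises :class:`UnresolvableMarkerError` if no eligible event exists at or
    after a marker, and :class:`MarkerCollisionError` if two markers land on
    the same event. Idempotent: realigning markers already placed at their
    critical events maps them to those same events.
    """
    out: list[CriticalTiming] = []
    used: set[int] = set()
    current = initial_mode
    for m in markers:
        kind = realign_kind_for(current, m.target_mode, rule_overrides)
        ev = next(
            (e for e in events if e.time_s >= m.time_s and e.kind == kind), None
        )
        if ev is None:
            raise UnresolvableMarkerError(
                f"marker at {m.time_s:.3f}s -> {m.target_mode}: no {kind} event at or after it"
            )
        if ev.sample_index in used:
            raise MarkerCollisionError(
                f"markers collide on {kind} event at {ev.time_s:.3f}s"
            )
        used.add(ev.sample_index)
        out.append(
            CriticalTiming(
                transition=(current, m.target_mode),
                raw_marker_time_s=m.time_s,
                event=ev,
                time_s=ev.time_s,
            )
        )
        current = m.target_mode
    return out


def _window_grid(fs: float) -> tuple[int, int, int]:
    return (
        int(round(SEGMENT_PRE_S * fs)),
        int(round(WINDOW_S * fs)),
        int(round(WINDOW_STEP_S * fs)),
    )


def extract_windows(session: SessionRecording, event: GaitEvent) -> list[AnalysisWindow]:
    """The four 200 ms windows of one gait event (unlabeled).

    Window ``k`` starts at ``event.time_s - 0.200 + 0.030*k``. Events closer
    than 200 ms to the start or 100 ms to the end of the recording raise
    :class:`EdgeEventError` (callers exclude them from analysis).
    """
    fs = session.fs_hz
    if event.time_s < SEGMENT_PRE_S or event.time_s > session.duration_s - SEGMENT_POST_S:
        raise EdgeEventError(
            f"event at {event.time_s:.3f}s too close to recording edge "
            f"(duration {session.duration_s:.3f}s)"
        )
    pre, wlen, step = _window_grid(fs)
    windows = []
    for k in range(N_WINDOWS):
        start = event.sample_index - pre + k * step
        windows.append(
            AnalysisWindow(
                event=event,
                window_index=k,
                start_s=start / fs,
                end_s=(start + wlen) / fs,
                signals=session.signals[:, start : start + wlen],
                channels=session.channels,
            )
        )
    return windows


def iter_event_windows(
    session: SessionRecording, events: list[GaitEvent], warn: bool = True
) -> list[tuple[GaitEvent, list[AnalysisWindow]]]:
    """Windows for every eligible event; edge events skipped (with a warning)."""
    out = []
    for ev in events:
        try:
            out.append((ev, extract_windows(session, ev)))
        except EdgeEventError as exc:
            if warn:
                warnings.warn(str(exc), stacklevel=2)
    return out


class ModeTimeline:
    """Piecewise-constant realigned mode timeline.

    ``at(t)`` switches inclusively at each critical timing (the critical
    event itself already belongs to the new mode); ``before(t)`` is the mode
    in effect strictly before ``t``.
    """

    def __init__(self, critical_timings: list[CriticalTiming], initial_mode: LocomotionMode):
        self.times = [c.time_s for c in critical_timings]
        self.modes = [c.to_mode for c in critical_timings]
        self.initial_mode = initial_mode
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("critical timings must be sorted and distinct")

    def at(self, t: float) -> LocomotionMode:
        mode = self.initial_mode
        for ct_time, ct_mode in zip(self.times, self.modes):
            if ct_time <= t:
                mode = ct_mode
            else:
                break
        return mode

    def before(self, t: float) -> LocomotionMode:
        mode = self.initial_mode
        for ct_time, ct_mode in zip(self.times, self.modes):
            if ct_time < t:
                mode = ct_mode
            else:
                break
        return mode


def label_windows(
    windows: list[AnalysisWindow],
    critical_timings: list[CriticalTiming],
    initial_mode: LocomotionMode = LocomotionMode.W,
) -> list[AnalysisWindow]:
    """Attach ground-truth ``label`` and ``context_mode`` to each window.

    All four windows of an event share the label of that event's time under
    the realigned timeline (mode switches exactly at, and including, each
    critical timing).
    """
    tl = ModeTimeline(critical_timings, initial_mode)
    for w in windows:
        w.label = tl.at(w.event.time_s)
        w.context_mode = tl.before(w.event.time_s)
    return windows


def build_transition_periods(
    critical_timings: list[CriticalTiming],
    events: list[GaitEvent],
    n_before: int = 2,
    n_after: int = 3,
) -> list[TransitionPeriod]:
    """Transition period of each critical timing: ``n_before`` events before
    it to ``n_after`` events after it. Periods that run off either end of the
    event list are clipped and flagged ``truncated``.
    """
    index_of = {e.sample_index: i for i, e in enumerate(events)}
    periods = []
    for ct in critical_timings:
        if ct.event.sample_index not in index_of:
            raise ValueError(f"critical event at {ct.time_s:.3f}s not in event list")
        i = index_of[ct.event.sample_index]
        lo, hi = i - n_before, i + n_after
        truncated = lo < 0 or hi > len(events) - 1
        lo = max(lo, 0)
        hi = min(hi, len(events) - 1)
        periods.append(
            TransitionPeriod(
                critical=ct,
                start_event=events[lo],
                end_event=events[hi],
                start_s=events[lo].time_s,
                end_s=events[hi].time_s,
                n_before=n_before,
                n_after=n_after,
                truncated=truncated,
            )
        )
    return periods
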