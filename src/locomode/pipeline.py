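"""End-to-end glue: raw session -> filtered signals -> events -> labeled windows.

This is the offline analysis path shared by training, cross-validation and
scoring. The causal replay path in :mod:`locomode.evaluation` runs the same
arithmetic chunk by chunk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .events import EventDetectorSpec, GaitEvent, detect_events
from .labeling import (
    AnalysisWindow,
    CriticalTiming,
    iter_event_windows,
    label_windows,
    realign_markers,
)
from .preprocess import FilterSpec, preprocess_session
from .session import SessionRecording

__all__ = ["SessionAnalysis", "analyze_session"]


@dataclass
class SessionAnalysis:
    """Everything the classifier needs from one session."""

    session: SessionRecording            # EMG-filtered copy
    events: list[GaitEvent]
    critical_timings: list[CriticalTiming]
    windows: list[AnalysisWindow] = field(default_factory=list)  # labeled, flat
    session_id: Optional[str] = None


def analyze_session(
    session: SessionRecording,
    filter_spec: Optional[FilterSpec] = None,
    detector_spec: Optional[EventDetectorSpec] = None,
    session_id: Optional[str] = None,
    warn: bool = False,
) -> SessionAnalysis:
    """Filter EMG, detect gait events, realign markers and label all windows."""
    filter_spec = filter_spec or FilterSpec()
    detector_spec = detector_spec or EventDetectorSpec()
    filtered = preprocess_session(session, filter_spec)
    events = detect_events(
        filtered.grf, filtered.fs_hz, filtered.body_weight_n, detector_spec
    )
    critical = realign_markers(session.markers, events, session.initial_mode)
    windows: list[AnalysisWindow] = []
    for _, ws in iter_event_windows(filtered, events, warn=warn):
        windows.extend(ws)
    label_windows(windows, critical, session.initial_mode)
    for w in windows:
        w.session_id = session_id
    return SessionAnalysis(
        session=filtered,
        events=events,
        critical_timings=critical,
        windows=windows,
        session_id=session_id,
    )
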