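"""Evaluation: offline cross-validation, causal replay and transition metrics.

Two views of classifier quality are computed, mirroring how real-time
myoelectric systems are reported:

* **Offline error** — stratified k-fold cross-validation over the labeled
  windows of each (mode, event-kind) cell; the percentage of misclassified
  windows, overall and attributed per transition type via the transition
  periods.
* **Online error** — a causal replay of an evaluation session through the
  trained bank (streaming filters, streaming event detection, per-event
  majority vote), scored inside each transition period: the percentage of
  wrongly-voted windows within the period, whether the mode switch happened
  inside the period at all, and the *prediction time* — time from the
  critical timing to the detecting event, negative when anticipatory. A
  switch outside the period does not count as a correct detection, and a
  transition never detected within the period plus a short grace horizon is
  scored as 100 % window error for that occurrence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    ClassifierBank,
    DecoderState,
    predict_event,
    train_lda,
)
from .errors import CompatibilityError, EdgeEventError
from .events import EventDetectorSpec, GaitEvent, StreamingEventDetector
from .features import FeatureConfig, feature_matrix, feature_names
from .labeling import (
    SEGMENT_PRE_S,
    WINDOW_S,
    WINDOW_STEP_S,
    N_WINDOWS,
    AnalysisWindow,
    CriticalTiming,
    ModeTimeline,
    TransitionPeriod,
    build_transition_periods,
    extract_windows,
)
from .preprocess import FilterSpec, StreamingEmgFilter, replace_signals
from .session import LocomotionMode, Modality, SessionRecording

__all__ = [
    "TransitionRecord",
    "ErrorReport",
    "DecisionTrace",
    "offline_cv_error",
    "replay_online",
    "score_online",
    "extended_window_analysis",
    "modality_ablation",
]


def _tkey(transition: tuple[LocomotionMode, LocomotionMode]) -> str:
    return f"{transition[0].value}>{transition[1].value}"


@dataclass
class TransitionRecord:
    """Outcome of one transition occurrence during replay."""

    transition: tuple[LocomotionMode, LocomotionMode]
    critical: CriticalTiming
    period: TransitionPeriod
    detected_time_s: Optional[float]
    prediction_time_ms: Optional[float]
    within_period: bool
    window_errors: int
    window_total: int
    truncated: bool = False

    @property
    def error_pct(self) -> float:
        if self.detected_time_s is None:
            return 100.0
        if self.window_total == 0:
            return 0.0
        return 100.0 * self.window_errors / self.window_total


@dataclass
class ErrorReport:
    """Aggregated error/timing metrics, recomputable from the raw records."""

    config: dict
    overall_error_pct: float
    per_transition: dict[str, dict]
    n_occurrences: int = 0
    detection_rate_pct: Optional[float] = None
    prediction_time_mean_ms: Optional[float] = None
    prediction_time_sd_ms: Optional[float] = None
    window_error_pct: Optional[float] = None  # pooled over windows

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "overall_error_pct": self.overall_error_pct,
            "per_transition": self.per_transition,
            "n_occurrences": self.n_occurrences,
            "detection_rate_pct": self.detection_rate_pct,
            "prediction_time_mean_ms": self.prediction_time_mean_ms,
            "prediction_time_sd_ms": self.prediction_time_sd_ms,
            "window_error_pct": self.window_error_pct,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"transition": k, **v} for k, v in self.per_transition.items()]
        return pd.DataFrame(rows)


# -- offline ---------------------------------------------------------------


def offline_cv_error(
    labeled_windows: list[AnalysisWindow],
    k: int = 10,
    feature_config: Optional[FeatureConfig] = None,
    shrinkage_lambda: float = 1e-3,
    seed: Optional[int] = None,
    periods: Optional[list[tuple[Optional[str], TransitionPeriod]]] = None,
) -> ErrorReport:
    """Stratified k-fold window error, per (mode, event-kind) cell.

    Folds are stratified by target label within each cell; a cell whose
    rarest class has fewer than ``k`` members uses that count as the fold
    number (with a warning). Single-class cells are trivially correct (the
    cell's constant model cannot err) and enter the totals as such.

    If ``periods`` is given — pairs of (session id, transition period) —
    the report also attributes each misclassified window to the transition
    period containing its event, yielding per-transition-type errors.
    """
    feature_config = feature_config or FeatureConfig()
    X_all, _ = feature_matrix(labeled_windows, feature_config)
    cells: dict[tuple, list[int]] = {}
    for i, w in enumerate(labeled_windows):
        cells.setdefault((w.context_mode, w.event.kind), []).append(i)

    correct = np.zeros(len(labeled_windows), dtype=bool)
    counted = np.zeros(len(labeled_windows), dtype=bool)
    for cell, idx in cells.items():
        idx = np.array(idx)
        y = np.array([labeled_windows[i].label.value for i in idx])
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) == 1:
            correct[idx] = True
            counted[idx] = True
            continue
        if counts.min() < 2:
            warnings.warn(
                f"cell {cell}: class with a single window excluded from CV", stacklevel=2
            )
            keep = np.isin(y, classes[counts >= 2])
            idx, y = idx[keep], y[keep]
            classes, counts = np.unique(y, return_counts=True)
            if len(classes) == 1:
                correct[idx] = True
                counted[idx] = True
                continue
        folds = min(k, int(counts.min()))
        if folds < k:
            warnings.warn(
                f"cell {cell}: reducing folds from {k} to {folds}", stacklevel=2
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        X = X_all[idx]
        for tr, te in skf.split(X, y):
            model = train_lda(
                X[tr],
                [labeled_windows[i].label for i in idx[tr]],
                shrinkage_lambda=shrinkage_lambda,
            )
            pred = model.predict(X[te])
            for j, p in zip(te, pred):
                correct[idx[j]] = p == labeled_windows[idx[j]].label
                counted[idx[j]] = True

    n_counted = int(counted.sum())
    overall = 100.0 * float((counted & ~correct).sum()) / max(n_counted, 1)

    per_transition: dict[str, dict] = {}
    if periods:
        groups: dict[str, list[int]] = {}
        for sid, period in periods:
            key = _tkey(period.critical.transition)
            for i, w in enumerate(labeled_windows):
                if not counted[i]:
                    continue
                if sid is not None and w.session_id != sid:
                    continue
                if period.start_s <= w.event.time_s <= period.end_s:
                    groups.setdefault(key, []).append(i)
        for key, members in sorted(groups.items()):
            members = np.array(members)
            per_transition[key] = {
                "error_pct": 100.0 * float((~correct[members]).sum()) / len(members),
                "n_windows": int(len(members)),
            }

    return ErrorReport(
        config={
            "kind": "offline_cv",
            "k": k,
            "feature_config": feature_config.to_dict(),
            "shrinkage_lambda": shrinkage_lambda,
            "n_windows": n_counted,
        },
        overall_error_pct=overall,
        per_transition=per_transition,
        n_occurrences=len(periods) if periods else 0,
        window_error_pct=overall,
    )


# -- online replay ---------------------------------------------------------


@dataclass
class DecisionTrace:
    """Causal replay output: one record per decided gait event."""

    records: list[dict]                  # event, votes, prev_mode, mode, decision_time_s
    events: list[GaitEvent]              # all detected events, including undecided edge ones
    initial_mode: LocomotionMode
    skipped_events: list[GaitEvent] = field(default_factory=list)
    session_id: Optional[str] = None

    def record_for(self, event: GaitEvent) -> Optional[dict]:
        for r in self.records:
            if r["event"].sample_index == event.sample_index:
                return r
        return None


def replay_online(
    session: SessionRecording,
    bank: ClassifierBank,
    detector_spec: Optional[EventDetectorSpec] = None,
    filter_spec: Optional[FilterSpec] = None,
    chunk_s: float = 0.5,
) -> DecisionTrace:
    """Causally replay a raw session through the trained bank.

    Signals are consumed chunk by chunk: EMG channels run through streaming
    causal filters, the raw GRF channel through the streaming event
    detector, and each confirmed event is decided as soon as the last
    window sample (90 ms after the event) and the debounce confirmation
    (``min_phase_s``) are both available — never using any sample later
    than 100 ms past the event. The result is bit-identical to the batch
    pipeline on the same session.
    """
    detector_spec = detector_spec or EventDetectorSpec()
    filter_spec = filter_spec or FilterSpec()
    fs = session.fs_hz

    expected = feature_names(session.channels, bank.feature_config)
    if expected != bank.feature_names:
        raise CompatibilityError("session montage does not match the bank's feature layout")

    emg_idx = session.indices_of(Modality.EMG)
    grf = session.grf
    filters = {i: StreamingEmgFilter(filter_spec, fs) for i in emg_idx}
    detector = StreamingEventDetector(detector_spec, fs, session.body_weight_n)

    n = session.n_samples
    filtered = session.signals.copy()
    # Samples needed past the event: last window ends +90 ms after it; the
    # decision additionally waits for the debounce confirmation.
    post_need = int(round((N_WINDOWS - 1) * WINDOW_STEP_S * fs + WINDOW_S * fs - SEGMENT_PRE_S * fs))
    horizon = max(post_need, detector.min_samples)

    filtered_session = replace_signals(session, filtered)
    state = DecoderState(current_mode=session.initial_mode)
    all_events: list[GaitEvent] = []
    skipped: list[GaitEvent] = []
    pending: list[GaitEvent] = []

    chunk = max(1, int(round(chunk_s * fs)))
    done = 0
    while done < n:
        hi = min(done + chunk, n)
        for i in emg_idx:
            filtered[i, done:hi] = filters[i].process(session.signals[i, done:hi])
        new_events = detector.process(grf[done:hi])
        all_events.extend(new_events)
        pending.extend(new_events)
        done = hi
        still = []
        for ev in pending:
            if ev.sample_index + horizon <= done:
                _decide(filtered_session, bank, state, ev, skipped, fs, horizon)
            else:
                still.append(ev)
        pending = still
    for ev in pending:  # recording ended; decide with what exists
        _decide(filtered_session, bank, state, ev, skipped, fs, horizon)

    return DecisionTrace(
        records=state.decision_log,
        events=all_events,
        initial_mode=session.initial_mode,
        skipped_events=skipped,
    )


def _decide(filtered_session, bank, state, ev, skipped, fs, horizon) -> None:
    try:
        windows = extract_windows(filtered_session, ev)
    except EdgeEventError:
        skipped.append(ev)
        return
    predict_event(
        bank, state, ev, windows, decision_time_s=(ev.sample_index + horizon) / fs
    )


# -- online scoring --------------------------------------------------------


def score_online(
    trace: DecisionTrace,
    critical_timings: list[CriticalTiming],
    events: list[GaitEvent],
    n_before: int = 2,
    n_after: int = 3,
    miss_horizon_events: int = 3,
    initial_mode: Optional[LocomotionMode] = None,
) -> tuple[ErrorReport, list[TransitionRecord]]:
    """Score a replay trace against the realigned ground-truth timeline.

    Per transition occurrence: window-level error inside the transition
    period; detection = the first event at/after the period start whose
    majority output equals the target mode, searched up to
    ``miss_horizon_events`` past the period end (never found -> missed,
    scored 100 %); the occurrence counts as *correct* only if detection
    falls inside the period. Prediction time is detection time minus
    critical timing (negative = anticipatory). Truncated periods are
    flagged and excluded from the aggregates.
    """
    initial_mode = initial_mode or trace.initial_mode
    timeline = ModeTimeline(critical_timings, initial_mode)
    periods = build_transition_periods(critical_timings, events, n_before, n_after)
    index_of = {e.sample_index: i for i, e in enumerate(events)}

    records: list[TransitionRecord] = []
    for ct, period in zip(critical_timings, periods):
        i_lo = index_of[period.start_event.sample_index]
        i_hi = index_of[period.end_event.sample_index]
        win_err = win_tot = 0
        for ev in events[i_lo : i_hi + 1]:
            rec = trace.record_for(ev)
            if rec is None:
                continue
            truth = timeline.at(ev.time_s)
            win_tot += len(rec["votes"])
            win_err += sum(1 for v in rec["votes"] if v != truth)
        detected = None
        i_stop = min(i_hi + miss_horizon_events, len(events) - 1)
        for ev in events[i_lo : i_stop + 1]:
            rec = trace.record_for(ev)
            if rec is not None and rec["mode"] == ct.to_mode:
                detected = ev.time_s
                break
        within = detected is not None and period.start_s <= detected <= period.end_s
        records.append(
            TransitionRecord(
                transition=ct.transition,
                critical=ct,
                period=period,
                detected_time_s=detected,
                prediction_time_ms=None
                if detected is None
                else 1000.0 * (detected - ct.time_s),
                within_period=within,
                window_errors=win_err,
                window_total=win_tot,
                truncated=period.truncated,
            )
        )

    scored = [r for r in records if not r.truncated]
    per_transition: dict[str, dict] = {}
    for key in sorted({_tkey(r.transition) for r in scored}):
        rs = [r for r in scored if _tkey(r.transition) == key]
        times = [r.prediction_time_ms for r in rs if r.prediction_time_ms is not None]
        per_transition[key] = {
            "error_pct": float(np.mean([r.error_pct for r in rs])),
            "n": len(rs),
            "detected_within_period": sum(r.within_period for r in rs),
            "prediction_time_mean_ms": float(np.mean(times)) if times else None,
            "prediction_time_sd_ms": float(np.std(times, ddof=1)) if len(times) > 1 else None,
        }

    all_times = [r.prediction_time_ms for r in scored if r.prediction_time_ms is not None]
    tot_win = sum(r.window_total for r in scored)
    report = ErrorReport(
        config={"kind": "online", "n_before": n_before, "n_after": n_after},
        overall_error_pct=float(np.mean([r.error_pct for r in scored])) if scored else 0.0,
        per_transition=per_transition,
        n_occurrences=len(scored),
        detection_rate_pct=100.0 * sum(r.within_period for r in scored) / max(len(scored), 1),
        prediction_time_mean_ms=float(np.mean(all_times)) if all_times else None,
        prediction_time_sd_ms=float(np.std(all_times, ddof=1)) if len(all_times) > 1 else None,
        window_error_pct=100.0 * sum(r.window_errors for r in scored) / max(tot_win, 1),
    )
    return report, records


def extended_window_analysis(
    trace: DecisionTrace,
    critical_timings: list[CriticalTiming],
    events: list[GaitEvent],
    miss_horizon_events: int = 3,
) -> ErrorReport:
    """Re-score with the widened (4 before, 5 after) transition period,
    which absorbs moderate marker-alignment uncertainty."""
    report, _ = score_online(
        trace,
        critical_timings,
        events,
        n_before=4,
        n_after=5,
        miss_horizon_events=miss_horizon_events,
    )
    return report


def modality_ablation(
    labeled_windows: list[AnalysisWindow],
    subsets: Sequence[Sequence[str]] = (("EMG",), ("IMU",), ("EMG", "IMU", "GRF")),
    k: int = 10,
    seed: Optional[int] = None,
    shrinkage_lambda: float = 1e-3,
    periods: Optional[list] = None,
) -> dict[str, ErrorReport]:
    """Offline CV error per sensor configuration (EMG-only / IMU-only / combined)."""
    out = {}
    for subset in subsets:
        cfg = FeatureConfig(modalities=tuple(subset))
        name = "+".join(cfg.modalities)
        out[name] = offline_cv_error(
            labeled_windows,
            k=k,
            feature_config=cfg,
            shrinkage_lambda=shrinkage_lambda,
            seed=seed,
            periods=periods,
        )
    return out
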