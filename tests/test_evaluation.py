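import numpy as np
import pytest

import locomode as lm
from locomode.classifier import DecoderState, predict_event
from locomode.evaluation import DecisionTrace
from locomode.events import EventKind, GaitEvent
from locomode.labeling import extract_windows

W, RA, RD, SA, SD = (
    lm.LocomotionMode.W,
    lm.LocomotionMode.RA,
    lm.LocomotionMode.RD,
    lm.LocomotionMode.SA,
    lm.LocomotionMode.SD,
)


# -- constructed traces for the scoring semantics --------------------------

def _event_grid(n=24, start=5.0, step=0.5):
    return [
        GaitEvent(int((start + i * step) * 2000), start + i * step,
                  EventKind.HC if i % 2 == 0 else EventKind.TO)
        for i in range(n)
    ]


def _trace(events, switch_at, to_mode, initial=W):
    """A decision trace that votes the old mode before `switch_at` (event
    index) and the new mode from it on."""
    records = []
    mode = initial
    for i, e in enumerate(events):
        new = to_mode if i >= switch_at else initial
        votes = [new] * 4
        records.append(
            {"event": e, "votes": votes, "prev_mode": mode, "mode": new,
             "decision_time_s": e.time_s + 0.1}
        )
        mode = new
    return DecisionTrace(records=records, events=events, initial_mode=initial)


def _critical(events, idx, transition):
    return lm.CriticalTiming(transition, events[idx].time_s - 0.2,
                             events[idx], events[idx].time_s)


def test_switch_at_critical_event_scores_zero_prediction_time():
    events = _event_grid()
    ct = _critical(events, 10, (W, RA))
    trace = _trace(events, switch_at=10, to_mode=RA)
    report, records = lm.score_online(trace, [ct], events)
    assert records[0].prediction_time_ms == 0.0
    assert records[0].within_period
    assert records[0].error_pct == 0.0
    assert report.detection_rate_pct == 100.0


def test_anticipatory_switch_has_negative_prediction_time():
    """A switch one event before critical timing is early, inside the period,
    and counts as correct."""
    events = _event_grid()
    ct = _critical(events, 10, (W, RA))
    trace = _trace(events, switch_at=9, to_mode=RA)
    report, records = lm.score_online(trace, [ct], events)
    r = records[0]
    assert r.prediction_time_ms is not None and r.prediction_time_ms < 0
    assert r.prediction_time_ms == pytest.approx(-500.0)
    assert r.within_period
    # the one mislabeled event (votes RA while truth still W) costs 4 windows
    assert r.window_errors == 4


def test_late_switch_counts_only_under_extended_period():
    events = _event_grid()
    ct = _critical(events, 10, (W, RA))
    trace = _trace(events, switch_at=14, to_mode=RA)  # 4 events after critical
    base, base_records = lm.score_online(trace, [ct], events)
    assert not base_records[0].within_period
    assert base.detection_rate_pct == 0.0
    wide, wide_records = lm.score_online(trace, [ct], events, n_before=4, n_after=5)
    assert wide_records[0].within_period
    assert wide.detection_rate_pct == 100.0
    assert wide.overall_error_pct <= base.overall_error_pct


def test_missed_transition_scores_100_percent():
    events = _event_grid()
    ct = _critical(events, 10, (W, RA))
    trace = _trace(events, switch_at=len(events) + 5, to_mode=RA)  # never
    report, records = lm.score_online(trace, [ct], events)
    assert records[0].detected_time_s is None
    assert records[0].error_pct == 100.0


def test_truncated_period_excluded_from_aggregates():
    events = _event_grid(n=6)
    ct = _critical(events, 1, (W, RA))
    trace = _trace(events, switch_at=1, to_mode=RA)
    report, records = lm.score_online(trace, [ct], events)
    assert records[0].truncated
    assert report.n_occurrences == 0


def test_empty_trace_gives_empty_report():
    events = _event_grid()
    trace = DecisionTrace(records=[], events=events, initial_mode=W)
    report, records = lm.score_online(trace, [], events)
    assert report.n_occurrences == 0 and report.per_transition == {}
    ext = lm.extended_window_analysis(trace, [], events)
    assert ext.n_occurrences == 0


def test_extended_never_worse_on_simulated_trace(small_sim, small_bank):
    cfg, _, _ = small_sim
    te_sess, _ = lm.generate_session(
        lm.SimConfig(seed=808, n_rounds=1, separability_delta=0.4, noise_sigma=0.4)
    )
    analysis = lm.analyze_session(te_sess)
    trace = lm.replay_online(te_sess, small_bank)
    base, _ = lm.score_online(trace, analysis.critical_timings, analysis.events)
    ext = lm.extended_window_analysis(trace, analysis.critical_timings, analysis.events)
    assert ext.overall_error_pct <= base.overall_error_pct + 1e-9


# -- replay ---------------------------------------------------------------

def test_replay_matches_batch_decisions(small_sim, small_bank, small_analysis):
    _, session, _ = small_sim
    trace = lm.replay_online(session, small_bank)
    state = DecoderState(current_mode=session.initial_mode)
    filtered = small_analysis.session
    for e in small_analysis.events:
        try:
            ws = extract_windows(filtered, e)
        except Exception:
            continue
        predict_event(small_bank, state, e, ws)
    assert [r["mode"] for r in state.decision_log] == [r["mode"] for r in trace.records]
    assert [r["votes"] for r in state.decision_log] == [r["votes"] for r in trace.records]


def test_replay_is_deterministic_and_chunking_invariant(small_sim, small_bank):
    _, session, _ = small_sim
    t1 = lm.replay_online(session, small_bank, chunk_s=0.5)
    t2 = lm.replay_online(session, small_bank, chunk_s=0.123)
    assert [r["mode"] for r in t1.records] == [r["mode"] for r in t2.records]
    assert [r["event"] for r in t1.records] == [r["event"] for r in t2.records]


def test_replay_latency_contract(small_sim, small_bank):
    """No decision may use signal later than 100 ms past its event."""
    _, session, _ = small_sim
    trace = lm.replay_online(session, small_bank)
    assert trace.records
    for r in trace.records:
        assert r["decision_time_s"] - r["event"].time_s <= 0.100 + 1e-9


def test_replay_montage_mismatch_rejected(small_sim, small_bank):
    _, session, _ = small_sim
    from locomode.errors import CompatibilityError

    sub = lm.SessionRecording(
        fs_hz=session.fs_hz,
        signals=session.signals[:9],
        channels=session.channels[:8] + [session.channels[-1]],
        markers=list(session.markers),
        body_weight_n=session.body_weight_n,
    )
    with pytest.raises(CompatibilityError):
        lm.replay_online(sub, small_bank)


# -- offline CV ------------------------------------------------------------

def test_offline_cv_zero_error_when_separable(small_analysis):
    report = lm.offline_cv_error(small_analysis.windows, k=5, seed=0)
    assert report.overall_error_pct <= 1.0


def test_offline_cv_shuffled_labels_near_chance(small_analysis, rng):
    import copy

    windows = [copy.copy(w) for w in small_analysis.windows]
    cells = {}
    for w in windows:
        cells.setdefault((w.context_mode, w.event.kind), []).append(w)
    expected_errors, weights = [], []
    for ws in cells.values():
        labels = [w.label for w in ws]
        perm = rng.permutation(len(labels))
        for w, j in zip(ws, perm):
            w.label = labels[j]
        counts = np.unique([l.value for l in labels], return_counts=True)[1]
        expected_errors.append(100.0 * (1 - counts.max() / counts.sum()))
        weights.append(len(ws))
    expected = float(np.average(expected_errors, weights=weights))
    report = lm.offline_cv_error(windows, k=5, seed=1)
    assert abs(report.overall_error_pct - expected) <= 7.0


def test_offline_cv_per_transition_attribution(small_analysis):
    periods = [
        ("small", p)
        for p in lm.build_transition_periods(
            small_analysis.critical_timings, small_analysis.events
        )
    ]
    report = lm.offline_cv_error(small_analysis.windows, k=5, seed=0, periods=periods)
    assert report.per_transition
    for key, stats in report.per_transition.items():
        assert 0.0 <= stats["error_pct"] <= 100.0
        assert stats["n_windows"] > 0
    assert {k.split(">")[1] for k in report.per_transition} >= {"RA", "SA", "RD", "SD"}


def test_modality_ablation_identical_subsets_identical_errors(small_analysis):
    out = lm.modality_ablation(
        small_analysis.windows,
        subsets=(("EMG",), ("EMG",)),
        k=4,
        seed=0,
    )
    assert len(out) == 1  # same config collapses to the same key and result


def test_emg_only_is_chance_when_only_imu_informative():
    cfg = lm.SimConfig(seed=77, n_rounds=2, emg_informative=False, imu_informative=True)
    session, _ = lm.generate_session(cfg)
    analysis = lm.analyze_session(session)
    out = lm.modality_ablation(
        analysis.windows, subsets=(("EMG",), ("IMU",)), k=4, seed=0
    )
    assert out["IMU"].overall_error_pct <= 2.0
    assert out["EMG"].overall_error_pct >= 5 * max(out["IMU"].overall_error_pct, 1.0)


def test_report_round_trips_to_json_and_dataframe(tmp_path, small_analysis):
    report = lm.offline_cv_error(small_analysis.windows, k=4, seed=0)
    report.to_json(tmp_path / "r.json")
    import json

    doc = json.loads((tmp_path / "r.json").read_text())
    assert doc["overall_error_pct"] == report.overall_error_pct
    df = report.to_dataframe()
    assert df.empty or "error_pct" in df.columns
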