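import numpy as np
import pytest

import locomode as lm
from locomode.classifier import (
    MODE_ORDER,
    allowed_targets,
    majority_vote,
    split_windows,
)
from locomode.errors import (
    CompatibilityError,
    ContractError,
    DataIntegrityError,
    NumericalError,
    TrainingError,
)
from locomode.events import EventKind, GaitEvent

W, RA, RD, SA, SD = MODE_ORDER


def blobs(rng, n_per_class=200, d=2, sep=6.0, modes=(W, RA)):
    X, y = [], []
    for k, m in enumerate(modes):
        X.append(rng.standard_normal((n_per_class, d)) + sep * k)
        y += [m] * n_per_class
    return np.vstack(X), y


def test_separated_gaussians_high_heldout_accuracy(rng):
    X, y = blobs(rng)
    Xt, yt = blobs(rng)
    model = lm.train_lda(X, y, shrinkage_lambda=0.0)
    pred = model.predict(Xt)
    assert np.mean([p == t for p, t in zip(pred, yt)]) >= 0.99


def test_identical_distributions_predict_majority_class(rng):
    X = rng.standard_normal((300, 3))
    y = [W] * 200 + [RA] * 100
    model = lm.train_lda(X, y)
    Xt = rng.standard_normal((2000, 3))
    pred = model.predict(Xt)
    acc_if_majority = np.mean([p == W for p in pred])
    assert acc_if_majority > 0.9  # priors dominate when classes coincide


def test_high_dimensional_training_with_shrinkage(rng):
    X, y = blobs(rng, n_per_class=40, d=108, sep=1.0)
    model = lm.train_lda(X, y, shrinkage_lambda=1e-3)
    assert np.all(np.isfinite(model.decision_function(X)))


def test_singular_covariance_without_shrinkage_raises(rng):
    X = np.zeros((40, 10))
    X[:, 0] = rng.standard_normal(40)  # rank-1 features
    y = [W] * 20 + [RA] * 20
    with pytest.raises(NumericalError):
        lm.train_lda(X, y, shrinkage_lambda=0.0)


def test_too_few_samples_or_classes(rng):
    with pytest.raises(TrainingError):
        lm.train_lda(rng.standard_normal((5, 2)), [W, W, W, W, RA])
    with pytest.raises(TrainingError):
        lm.train_lda(rng.standard_normal((5, 2)), [W] * 5)


def test_agrees_with_reference_lda(rng):
    """Cross-check against sklearn's LDA (lsqr, equal priors) on balanced blobs."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X, y = blobs(rng, n_per_class=150, d=4, sep=2.0, modes=(W, RA, SD))
    ours = lm.train_lda(X, y, shrinkage_lambda=0.0)
    ref = LinearDiscriminantAnalysis(solver="lsqr", priors=[1 / 3] * 3)
    ref.fit(X, [m.value for m in y])
    Xt = rng.standard_normal((500, 4)) * 3
    ours_pred = [m.value for m in ours.predict(Xt)]
    ref_pred = list(ref.predict(Xt))
    assert np.mean([a == b for a, b in zip(ours_pred, ref_pred)]) >= 0.995


def test_decision_invariant_under_common_rescaling(rng):
    X, y = blobs(rng, n_per_class=100, d=3, sep=2.0, modes=(W, RA, SA))
    Xt = rng.standard_normal((400, 3)) * 2
    base = lm.train_lda(X, y, shrinkage_lambda=0.0).predict(Xt)
    scaled = lm.train_lda(X * 37.5, y, shrinkage_lambda=0.0).predict(Xt * 37.5)
    assert base == scaled


def test_allowed_targets_walking_hub():
    assert allowed_targets(W) == {W, RA, RD, SA, SD}
    for m in (RA, RD, SA, SD):
        assert allowed_targets(m) == {m, W}


def test_bank_structure_from_simulated_session(small_bank):
    bank = small_bank
    assert len(bank.models) == 10
    assert set(bank.models) == {(m, k) for m in MODE_ORDER for k in (EventKind.HC, EventKind.TO)}
    assert set(bank.models[(W, EventKind.HC)].class_labels) == {W, RD, SD}
    assert set(bank.models[(W, EventKind.TO)].class_labels) == {W, RA, SA}
    assert set(bank.models[(SA, EventKind.TO)].class_labels) == {SA, W}
    assert set(bank.models[(RD, EventKind.HC)].class_labels) == {RD, W}
    for mode, kind in ((RA, EventKind.HC), (SA, EventKind.HC),
                       (RD, EventKind.TO), (SD, EventKind.TO)):
        assert bank.models[(mode, kind)].class_labels == [mode]


def test_strict_cells_raises_on_single_class(small_analysis):
    with pytest.raises(TrainingError, match="RA|SA|RD|SD"):
        lm.train_bank(small_analysis.windows, strict_cells=True)


def test_illegal_target_is_data_integrity_error(small_analysis):
    import copy

    windows = [copy.copy(w) for w in small_analysis.windows[:40]]
    windows[0].context_mode, windows[0].label = SA, RD  # SA can only go to SA or W
    with pytest.raises(DataIntegrityError):
        lm.train_bank(windows)
    windows[0].context_mode, windows[0].label = None, None
    with pytest.raises(TrainingError):
        lm.train_bank(windows)


def test_majority_vote_rules():
    assert majority_vote([RA, RA, RA, W], W) == RA
    assert majority_vote([RA, RA, W, W], W) == W          # 2-2 tie retains current
    assert majority_vote([RA, RA, SD, SD], W) == W        # tie between others too
    assert majority_vote([W, W, W, W], SA) == W
    assert majority_vote([SA, SA, SA, SA], SA) == SA


def test_state_machine_legality_over_random_vote_streams(rng):
    """No emitted transition may jump directly between two non-walking modes."""
    n_events = 0
    for _ in range(2000):
        mode = W
        for _ in range(50):
            legal = sorted(allowed_targets(mode), key=MODE_ORDER.index)
            votes = [legal[i] for i in rng.integers(0, len(legal), size=4)]
            new_mode = majority_vote(votes, mode)
            assert new_mode in allowed_targets(mode)
            if mode != W and new_mode != mode:
                assert new_mode == W
            mode = new_mode
            n_events += 1
    assert n_events == 100_000


def test_predict_event_contract_and_legality(small_bank, small_analysis):
    from locomode.labeling import extract_windows

    session = small_analysis.session
    event = small_analysis.events[10]
    windows = extract_windows(session, event)
    state = lm.DecoderState(current_mode=W)
    with pytest.raises(ContractError):
        lm.predict_event(small_bank, state, event, windows[:3])
    state = lm.predict_event(small_bank, state, event, windows)
    rec = state.decision_log[-1]
    assert len(rec["votes"]) == 4
    assert rec["mode"] in allowed_targets(rec["prev_mode"])


def test_save_load_round_trip(tmp_path, small_bank, small_analysis, rng):
    path = tmp_path / "bank.json"
    lm.save_bank(small_bank, path)
    loaded = lm.load_bank(path)
    assert loaded.feature_names == small_bank.feature_names
    X = rng.standard_normal((100, len(small_bank.feature_names)))
    for key in small_bank.models:
        assert small_bank.models[key].predict(X) == loaded.models[key].predict(X)


def test_load_with_mismatched_features_is_compatibility_error(tmp_path, small_bank):
    path = tmp_path / "bank.json"
    lm.save_bank(small_bank, path)
    with pytest.raises(CompatibilityError):
        lm.load_bank(path, expect_feature_names=["bogus.mav"])


def test_deterministic_predictions(small_bank, rng):
    X = rng.standard_normal((50, len(small_bank.feature_names)))
    model = small_bank.models[(W, EventKind.HC)]
    assert model.predict(X) == model.predict(X)


def test_split_windows_stratified(small_analysis):
    train, test = split_windows(small_analysis.windows, 0.8, seed=0)
    assert len(train) + len(test) == len(small_analysis.windows)
    assert 0.7 < len(train) / len(small_analysis.windows) < 0.9
    all_train, none = split_windows(small_analysis.windows, 1.0)
    assert none == [] and len(all_train) == len(small_analysis.windows)
    with pytest.raises(TrainingError):
        split_windows(small_analysis.windows, 0.0)
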