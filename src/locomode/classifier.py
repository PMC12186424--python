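"""Mode-specific, phase-dependent LDA bank with state-machine constraints.

One linear discriminant model is trained per (current locomotion mode, gait
event kind) cell — five modes times heel contact / toe-off gives exactly ten
models. Level walking is the hub of the transition graph: from walking every
mode is reachable, from any other mode only that mode itself or walking is
legal, so non-walking modes can never hand over to each other directly.

At run time the decoder holds the currently active mode; at each gait event
it consults the matching model, classifies the event's four windows, and
takes the majority label. A 2-2 tie retains the current mode (the
safety-conservative choice for a prosthesis).

LDA with shared shrinkage-regularized covariance: pooled within-class
covariance ``S`` is regularized to ``S + lambda * (trace(S)/d) * I`` and the
discriminant of class k is ``g_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 +
ln pi_k``; prediction is the argmax. Shrinkage matters because the
108-dimensional feature vector can rival per-cell sample counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CompatibilityError,
    ContractError,
    DataIntegrityError,
    NumericalError,
    TrainingError,
)
from .events import EventKind, GaitEvent
from .features import FeatureConfig, feature_matrix
from .labeling import AnalysisWindow
from .session import LocomotionMode

__all__ = [
    "MODE_ORDER",
    "allowed_targets",
    "LDAModel",
    "train_lda",
    "ClassifierBank",
    "train_bank",
    "DecoderState",
    "majority_vote",
    "predict_event",
    "save_bank",
    "load_bank",
    "split_windows",
]

MODE_ORDER = [
    LocomotionMode.W,
    LocomotionMode.RA,
    LocomotionMode.RD,
    LocomotionMode.SA,
    LocomotionMode.SD,
]


def allowed_targets(mode: LocomotionMode) -> set[LocomotionMode]:
    """Legal successor modes: walking reaches all five, every other mode
    only itself or walking."""
    if mode == LocomotionMode.W:
        return set(MODE_ORDER)
    return {mode, LocomotionMode.W}


@dataclass
class LDAModel:
    """Gaussian classes with a shared shrinkage-regularized covariance.

    A single-class model (``len(class_labels) == 1``) is the degenerate
    constant classifier; it arises in bank cells where the realignment rules
    make only one target observable (see :func:`train_bank`).
    """

    class_labels: list[LocomotionMode]
    class_means: np.ndarray          # (K, d)
    pooled_covariance: np.ndarray    # (d, d), after shrinkage
    priors: np.ndarray               # (K,)
    shrinkage_lambda: float
    _coefs: np.ndarray = field(default=None, repr=False)      # (K, d)
    _intercepts: np.ndarray = field(default=None, repr=False)  # (K,)

    def __post_init__(self) -> None:
        self.class_means = np.atleast_2d(np.asarray(self.class_means, dtype=float))
        self.pooled_covariance = np.asarray(self.pooled_covariance, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise TrainingError("priors must sum to 1")
        if self._coefs is None:
            self._solve()

    def _solve(self) -> None:
        try:
            sol = np.linalg.solve(self.pooled_covariance, self.class_means.T).T
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                "pooled covariance is singular; use shrinkage_lambda > 0"
            ) from exc
        self._coefs = sol
        self._intercepts = (
            -0.5 * np.einsum("kd,kd->k", self.class_means, sol) + np.log(self.priors)
        )

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self._coefs.T + self._intercepts

    def predict(self, X: np.ndarray) -> list[LocomotionMode]:
        if len(self.class_labels) == 1:
            n = np.atleast_2d(np.asarray(X)).shape[0]
            return [self.class_labels[0]] * n
        scores = self.decision_function(X)
        return [self.class_labels[int(i)] for i in np.argmax(scores, axis=1)]


def _mode_sorted(labels) -> list[LocomotionMode]:
    return sorted(set(labels), key=MODE_ORDER.index)


def train_lda(
    X: np.ndarray,
    y: Sequence[LocomotionMode],
    shrinkage_lambda: float = 1e-3,
    uniform_priors: bool = False,
) -> LDAModel:
    """Fit a shrinkage-LDA model.

    Requires at least two classes, each with at least two samples. The
    pooled within-class covariance uses the unbiased (N - K) denominator and
    is regularized by ``lambda * trace(S)/d`` on the diagonal.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise TrainingError("X must be (n_samples, d) matching len(y)")
    classes = _mode_sorted(y)
    if len(classes) < 2:
        raise TrainingError("need at least 2 classes to train an LDA model")
    n, d = X.shape
    means = np.empty((len(classes), d))
    counts = np.empty(len(classes))
    scatter = np.zeros((d, d))
    for k, c in enumerate(classes):
        rows = X[[yi == c for yi in y]]
        if rows.shape[0] < 2:
            raise TrainingError(f"class {c} has {rows.shape[0]} sample(s); need >= 2")
        counts[k] = rows.shape[0]
        means[k] = rows.mean(axis=0)
        centered = rows - means[k]
        scatter += centered.T @ centered
    cov = scatter / (n - len(classes))
    if shrinkage_lambda < 0:
        raise TrainingError("shrinkage_lambda must be >= 0")
    if shrinkage_lambda > 0:
        cov = cov + shrinkage_lambda * (np.trace(cov) / d) * np.eye(d)
    priors = np.full(len(classes), 1 / len(classes)) if uniform_priors else counts / n
    return LDAModel(
        class_labels=classes,
        class_means=means,
        pooled_covariance=cov,
        priors=priors,
        shrinkage_lambda=shrinkage_lambda,
    )


def _constant_model(mode: LocomotionMode, mean: np.ndarray, lam: float) -> LDAModel:
    d = mean.shape[0]
    return LDAModel(
        class_labels=[mode],
        class_means=mean.reshape(1, -1),
        pooled_covariance=np.eye(d),
        priors=np.array([1.0]),
        shrinkage_lambda=lam,
    )


@dataclass
class ClassifierBank:
    """Ten LDA models keyed by (current mode, event kind) plus the
    transition-legality map and the feature layout they were trained on."""

    models: dict[tuple[LocomotionMode, EventKind], LDAModel]
    feature_config: FeatureConfig
    feature_names: list[str]
    shrinkage_lambda: float = 1e-3

    def __post_init__(self) -> None:
        if len(self.models) != len(MODE_ORDER) * 2:
            raise TrainingError(
                f"bank must hold exactly {len(MODE_ORDER) * 2} models, got {len(self.models)}"
            )
        for (mode, kind), model in self.models.items():
            illegal = set(model.class_labels) - allowed_targets(mode)
            if illegal:
                raise DataIntegrityError(
                    f"model ({mode}, {kind}) carries illegal targets {illegal}"
                )

    @staticmethod
    def allowed(mode: LocomotionMode) -> set[LocomotionMode]:
        return allowed_targets(mode)


@dataclass
class DecoderState:
    """Running decoder: current mode plus the per-event decision log."""

    current_mode: LocomotionMode = LocomotionMode.W
    decision_log: list[dict] = field(default_factory=list)


def split_windows(
    windows: list[AnalysisWindow], fraction: float, seed: Optional[int] = None
) -> tuple[list[AnalysisWindow], list[AnalysisWindow]]:
    """Random split stratified by (context mode, event kind, label).

    ``fraction`` is the training share (the study used 0.8 for the model
    deployed in real time); ``fraction=1.0`` returns everything as training
    data for deployment.
    """
    if not (0 < fraction <= 1):
        raise TrainingError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(windows), []
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[AnalysisWindow]] = {}
    for w in windows:
        groups.setdefault((w.context_mode, w.event.kind, w.label), []).append(w)
    train, test = [], []
    for ws in groups.values():
        idx = rng.permutation(len(ws))
        n_train = max(1, int(round(fraction * len(ws))))
        for j, i in enumerate(idx):
            (train if j < n_train else test).append(ws[i])
    return train, test


def train_bank(
    labeled_windows: list[AnalysisWindow],
    feature_config: Optional[FeatureConfig] = None,
    shrinkage_lambda: float = 1e-3,
    uniform_priors: bool = False,
    strict_cells: bool = False,
) -> ClassifierBank:
    """Train the ten-model bank from labeled analysis windows.

    The training rows of model (M, P) are the windows anchored at events of
    kind P whose pre-event ground-truth mode (``context_mode``) is M; the
    target is the window's ``label`` (the mode at/after the event). Targets
    must lie in the legality map of M.

    The realignment rules make some cells single-class by construction: a
    mode entered and left at toe-off events (ramp/stair ascent) never shows
    a non-self target at heel contacts, and vice versa for the descent
    modes. Such a cell trains a degenerate constant model, which is also the
    only legal steady behavior there; ``strict_cells=True`` instead raises a
    :class:`TrainingError` naming the cell.
    """
    feature_config = feature_config or FeatureConfig()
    for w in labeled_windows:
        if w.label is None or w.context_mode is None:
            raise TrainingError("windows must be labeled (label + context_mode) first")
        if w.label not in allowed_targets(w.context_mode):
            raise DataIntegrityError(
                f"window at {w.event.time_s:.3f}s: target {w.label} is not a legal "
                f"successor of {w.context_mode}"
            )

    X_all, names = feature_matrix(labeled_windows, feature_config)
    cells: dict[tuple[LocomotionMode, EventKind], list[int]] = {}
    for i, w in enumerate(labeled_windows):
        cells.setdefault((w.context_mode, w.event.kind), []).append(i)

    models: dict[tuple[LocomotionMode, EventKind], LDAModel] = {}
    for mode in MODE_ORDER:
        for kind in (EventKind.HC, EventKind.TO):
            idx = cells.get((mode, kind), [])
            if not idx:
                raise TrainingError(f"no training windows for cell ({mode}, {kind})")
            X = X_all[idx]
            y = [labeled_windows[i].label for i in idx]
            classes = _mode_sorted(y)
            if len(classes) == 1:
                if strict_cells:
                    raise TrainingError(
                        f"cell ({mode}, {kind}) has a single observed class {classes[0]}"
                    )
                models[(mode, kind)] = _constant_model(
                    classes[0], X.mean(axis=0), shrinkage_lambda
                )
            else:
                models[(mode, kind)] = train_lda(
                    X, y, shrinkage_lambda=shrinkage_lambda, uniform_priors=uniform_priors
                )
    return ClassifierBank(
        models=models,
        feature_config=feature_config,
        feature_names=names,
        shrinkage_lambda=shrinkage_lambda,
    )


def majority_vote(
    votes: Sequence[LocomotionMode], current_mode: LocomotionMode
) -> LocomotionMode:
    """Most frequent vote; any tie for the maximum retains the current mode."""
    counts: dict[LocomotionMode, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = [m for m, c in counts.items() if c == best]
    if len(winners) != 1:
        return current_mode
    return winners[0]


def predict_event(
    bank: ClassifierBank,
    state: DecoderState,
    event: GaitEvent,
    windows: list[AnalysisWindow],
    decision_time_s: Optional[float] = None,
) -> DecoderState:
    """Classify one gait event's four windows and update the decoder state."""
    from .labeling import N_WINDOWS

    if len(windows) != N_WINDOWS:
        raise ContractError(f"expected {N_WINDOWS} windows, got {len(windows)}")
    model = bank.models[(state.current_mode, event.kind)]
    X, names = feature_matrix(windows, bank.feature_config)
    if names != bank.feature_names:
        raise CompatibilityError("window montage does not match the bank's feature layout")
    votes = model.predict(X)
    outcome = majority_vote(votes, state.current_mode)
    if outcome not in allowed_targets(state.current_mode):  # pragma: no cover - defensive
        outcome = state.current_mode
    state.decision_log.append(
        {
            "event": event,
            "votes": votes,
            "prev_mode": state.current_mode,
            "mode": outcome,
            "decision_time_s": decision_time_s,
        }
    )
    state.current_mode = outcome
    return state


# -- persistence -----------------------------------------------------------

_FORMAT = "locomode-bank-v1"


def save_bank(bank: ClassifierBank, path) -> None:
    """Serialize the bank to a single portable JSON file.

    Matrices are stored row-major as nested lists with full float precision
    (`repr` round-trips float64 exactly), keyed by feature names so that a
    montage mismatch is detectable on load.
    """
    doc = {
        "format": _FORMAT,
        "feature_names": bank.feature_names,
        "feature_config": bank.feature_config.to_dict(),
        "shrinkage_lambda": bank.shrinkage_lambda,
        "models": {
            f"{mode.value}|{kind.value}": {
                "class_labels": [c.value for c in m.class_labels],
                "class_means": m.class_means.tolist(),
                "pooled_covariance": m.pooled_covariance.tolist(),
                "priors": m.priors.tolist(),
                "shrinkage_lambda": m.shrinkage_lambda,
            }
            for (mode, kind), m in bank.models.items()
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_bank(path, expect_feature_names: Optional[list[str]] = None) -> ClassifierBank:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _FORMAT:
        raise CompatibilityError(f"{path}: not a {_FORMAT} file")
    names = list(doc["feature_names"])
    if expect_feature_names is not None and names != list(expect_feature_names):
        raise CompatibilityError(
            "model feature layout does not match the session montage"
        )
    models = {}
    for key, md in doc["models"].items():
        mode_s, kind_s = key.split("|")
        models[(LocomotionMode(mode_s), EventKind(kind_s))] = LDAModel(
            class_labels=[LocomotionMode(c) for c in md["class_labels"]],
            class_means=np.array(md["class_means"], dtype=float),
            pooled_covariance=np.array(md["pooled_covariance"], dtype=float),
            priors=np.array(md["priors"], dtype=float),
            shrinkage_lambda=md["shrinkage_lambda"],
        )
    return ClassifierBank(
        models=models,
        feature_config=FeatureConfig.from_dict(doc["feature_config"]),
        feature_names=names,
        shrinkage_lambda=doc["shrinkage_lambda"],
    )
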