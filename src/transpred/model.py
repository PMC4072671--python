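"""One-vs-rest RBF-SVM classification of transporter substrate classes.

Each of the eight classes (seven substrate classes plus the
non-transporter control) gets its own binary support vector machine
trained with that class as positive and the union of the other seven as
negative. Two hyperparameters are tuned over a grid: the RBF kernel
width ``gamma`` (default grid log-spaced over 1e-5 .. 10) and the
``cost_factor`` weighting errors on the positive class (default grid
1..4), mirroring SVM-Light's ``-g``/``-j`` options. The shared
regularisation constant C defaults to 1.

Multi-class fusion is the argmax of the eight decision scores with a
fixed class-order tie-break; this fusion rule is plumbing on top of the
per-class binary models, which are what the evaluation module scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from transpred.constants import CLASS_LABELS

MODEL_FORMAT_VERSION = 1

_DEFAULT_GAMMA_GRID = tuple(float(g) for g in np.logspace(-5, 1, 7))
_DEFAULT_COST_GRID = (1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class SvmConfig:
    """Hyperparameters for one binary SVM.

    ``cost_factor`` multiplies the penalty of errors on the positive
    class (SVM-Light's ``-j``); ``regularization`` is the shared C.
    """

    kernel: str = "rbf"
    gamma: float = 1e-2
    cost_factor: float = 1.0
    regularization: float = 1.0
    gamma_grid: tuple = _DEFAULT_GAMMA_GRID
    cost_factor_grid: tuple = _DEFAULT_COST_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.gamma <= 0 or self.cost_factor <= 0 or self.regularization <= 0:
            raise ValueError("gamma, cost_factor and regularization must be > 0")
        if not self.gamma_grid or not self.cost_factor_grid:
            raise ValueError("parameter grids must be non-empty")
        if min(self.gamma_grid) <= 0 or min(self.cost_factor_grid) <= 0:
            raise ValueError("grid values must be positive")


@dataclass
class BinaryClassModel:
    """A fitted binary SVM for one target class."""

    target_class: str
    encoder: str
    config: SvmConfig
    estimator: SVC
    feature_names: tuple = field(default_factory=tuple)
    n_positive: int = 0

    @property
    def n_features(self) -> int:
        return self.estimator.n_features_in_

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model for {self.target_class!r} expects "
                f"{self.n_features} features, got {X.shape[1]}"
            )
        return self.estimator.decision_function(X)


@dataclass
class OneVsRestEnsemble:
    """Eight binary models sharing one encoder and feature space."""

    models: dict  # class label -> BinaryClassModel
    encoder: str

    def __post_init__(self) -> None:
        missing = [c for c in CLASS_LABELS if c not in self.models]
        if missing:
            raise ValueError(f"ensemble missing classes: {', '.join(missing)}")
        dims = {m.n_features for m in self.models.values()}
        if len(dims) != 1:
            raise ValueError(f"members disagree on feature dimension: {dims}")

    @property
    def n_features(self) -> int:
        return next(iter(self.models.values())).n_features

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Decision scores, shape (n_samples, 8), columns in class order."""
        return np.column_stack(
            [self.models[c].decision_scores(X) for c in CLASS_LABELS]
        )


def _make_estimator(config: SvmConfig, n_features: int) -> SVC:
    kernel = {"rbf": "rbf", "linear": "linear", "polynomial": "poly"}[config.kernel]
    return SVC(
        kernel=kernel,
        C=config.regularization,
        gamma=config.gamma,
        class_weight={1: config.cost_factor},
        random_state=config.seed,
    )


def train_binary(
    X: np.ndarray, y: np.ndarray, config: SvmConfig, target_class: str = "positive",
    encoder: str = "custom", feature_names: Sequence[str] = (),
) -> BinaryClassModel:
    """Fit one binary SVM. ``y`` holds 0/1 (or boolean) labels.

    The feature matrix is consumed as-is: encoders already produce
    bounded components and no hidden re-scaling is applied here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each label needs at least 2 examples")
    est = _make_estimator(config, X.shape[1])
    est.fit(X, y)
    return BinaryClassModel(
        target_class, encoder, config, est, tuple(feature_names), int(y.sum())
    )


def grid_search(
    X: np.ndarray, y: np.ndarray, config: SvmConfig, folds: int = 5
) -> SvmConfig:
    """Pick (gamma, cost_factor) maximising mean CV accuracy on the grid.

    Ties are broken deterministically toward smaller gamma, then smaller
    cost_factor. A grid point whose CV split leaves a fold with a single
    class is scored as failed and excluded.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(X, y))
    best: tuple | None = None  # (-acc, gamma, cost_factor)
    for gamma in sorted(config.gamma_grid):
        for cost in sorted(config.cost_factor_grid):
            candidate = replace(config, gamma=float(gamma), cost_factor=float(cost))
            accs = []
            failed = False
            for train_idx, test_idx in splits:
                if len(np.unique(y[train_idx])) < 2:
                    failed = True
                    break
                model = train_binary(X[train_idx], y[train_idx], candidate)
                pred = (model.decision_scores(X[test_idx]) >= 0).astype(int)
                accs.append(float(np.mean(pred == y[test_idx])))
            if failed:
                continue
            key = (-np.mean(accs), gamma, cost)
            if best is None or key < best[0]:
                best = (key, candidate)
    if best is None:
        raise ValueError("every grid point failed cross-validation")
    return best[1]


def train_ovr(
    X: np.ndarray,
    labels: Sequence[str],
    config: SvmConfig | Mapping[str, SvmConfig],
    encoder: str = "custom",
    feature_names: Sequence[str] = (),
) -> OneVsRestEnsemble:
    """Train all eight one-vs-rest binary models on a labelled matrix.

    ``config`` may be a single :class:`SvmConfig` shared by all classes
    or a mapping class label -> config (per-class tuning).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        raise ValueError("one label per feature row required")
    present = set(labels)
    missing = [c for c in CLASS_LABELS if c not in present]
    if missing:
        raise ValueError(f"dataset missing class(es): {', '.join(missing)}")
    models = {}
    for cls in CLASS_LABELS:
        cfg = config[cls] if isinstance(config, Mapping) else config
        y = (labels == cls).astype(int)
        models[cls] = train_binary(X, y, cfg, cls, encoder, feature_names)
    return OneVsRestEnsemble(models, encoder)


def predict(
    ensemble: OneVsRestEnsemble, X: np.ndarray
) -> tuple[list, np.ndarray]:
    """Multi-class prediction: argmax of the 8 decision scores.

    Exact score ties resolve to the earlier class in the fixed class
    order. Returns (labels, score matrix of shape (n, 8)).
    """
    scores = ensemble.score_matrix(X)
    winners = np.argmax(scores, axis=1)  # argmax returns first max: tie-break
    return [CLASS_LABELS[i] for i in winners], scores


def predict_transporter(
    ensemble: OneVsRestEnsemble, X: np.ndarray, threshold: float = 0.0
) -> np.ndarray:
    """Transporter vs non-transporter call.

    A sequence is called a transporter iff the non_transporter model's
    decision score falls below ``threshold`` (the model's decision
    boundary by default).
    """
    scores = ensemble.models["non_transporter"].decision_scores(np.asarray(X))
    return scores < threshold


def save_model(ensemble: OneVsRestEnsemble, path: str | Path) -> None:
    """Persist an ensemble (config, encoder tag, component names, fit)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "encoder": ensemble.encoder,
        "models": {
            cls: {
                "target_class": m.target_class,
                "config": m.config,
                "estimator": m.estimator,
                "feature_names": m.feature_names,
                "n_positive": m.n_positive,
            }
            for cls, m in ensemble.models.items()
        },
    }
    joblib.dump(payload, Path(path))


def load_model(path: str | Path) -> OneVsRestEnsemble:
    try:
        payload = joblib.load(Path(path))
    except Exception as exc:
        raise ValueError(f"cannot load model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path}: not a transpred model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {payload['format_version']} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    models = {
        cls: BinaryClassModel(
            entry["target_class"],
            payload["encoder"],
            entry["config"],
            entry["estimator"],
            entry["feature_names"],
            entry.get("n_positive", 0),
        )
        for cls, entry in payload["models"].items()
    }
    return OneVsRestEnsemble(models, payload["encoder"])
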