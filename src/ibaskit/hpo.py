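"""Hyperparameter optimization: grid-search baseline and IBAS evolution.

The three search spaces follow the published hyperparameter table
verbatim: logistic regression (regularization strength [0.01, 100] step
10; L1 or L2 penalty), SVM (penalty C and gamma, both [0.01, 100] step
10), and XGBoost (learning rate [0.01, 1] step 0.1; max depth [1, 20]
step 0.5; boosting rounds [1, 100] step 10).  Grids include both range
endpoints; integer parameters round each grid value half-up and drop
duplicates.

Fitness of an assignment is the mean cross-validated metric (default
ROC-AUC) under stratified k-fold with per-fold z-score normalization
fitted on the training folds only.  ``evolve`` runs IBAS over the unit
cube with a decoder mapping positions to mixed-type assignments, and
stops early when fitness plateaus; an optional per-feature binary mask
can be appended to the search vector for joint feature selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import metrics as M
from . import optimizer as O

MODEL_KINDS = ("LR", "SVM", "XGB")
METRICS = ("roc_auc", "acc", "f1")


@dataclass(frozen=True)
class HyperparameterSpec:
    name: str
    kind: str  # continuous | integer | categorical
    low: Optional[float] = None
    high: Optional[float] = None
    step: Optional[float] = None
    levels: tuple = ()

    def __post_init__(self):
        if self.kind in ("continuous", "integer"):
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"{self.name}: need low < high")
            if self.step is not None and self.step <= 0:
                raise ValueError(f"{self.name}: grid step must be positive")
        elif self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"{self.name}: categorical needs levels")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind}")


@dataclass(frozen=True)
class HPOSpace:
    model_kind: str
    specs: tuple[HyperparameterSpec, ...]

    @property
    def dims(self) -> int:
        return len(self.specs)


@dataclass(frozen=True)
class HPOResult:
    best_assignment: dict
    best_fitness: float
    history: tuple[tuple[dict, float], ...]
    evaluations: int
    method: str  # grid | IBAS
    selected_features: Optional[tuple[str, ...]] = None


def build_space(model_kind: str) -> HPOSpace:
    """The published search space for one model family."""
    if model_kind == "LR":
        specs = (
            HyperparameterSpec("C", "continuous", 0.01, 100.0, 10.0),
            HyperparameterSpec("penalty", "categorical", levels=("l1", "l2")),
        )
    elif model_kind == "SVM":
        specs = (
            HyperparameterSpec("C", "continuous", 0.01, 100.0, 10.0),
            HyperparameterSpec("gamma", "continuous", 0.01, 100.0, 10.0),
        )
    elif model_kind == "XGB":
        specs = (
            HyperparameterSpec("learning_rate", "continuous", 0.01, 1.0, 0.1),
            HyperparameterSpec("max_depth", "integer", 1, 20, 0.5),
            HyperparameterSpec("n_estimators", "integer", 1, 100, 10.0),
        )
    else:
        raise ValueError(f"unknown model kind {model_kind!r}; "
                         f"expected one of {MODEL_KINDS}")
    return HPOSpace(model_kind=model_kind, specs=specs)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def grid_values(spec: HyperparameterSpec) -> list:
    """Grid for one spec: low, low+step, ... plus the clipped upper end."""
    if spec.kind == "categorical":
        return list(spec.levels)
    if spec.step is None:
        raise ValueError(f"{spec.name}: no grid step defined")
    vals = []
    v = spec.low
    while v <= spec.high + 1e-9:
        vals.append(min(v, spec.high))
        v += spec.step
    if vals[-1] < spec.high:
        vals.append(spec.high)
    if spec.kind == "integer":
        ints = []
        for v in vals:
            r = _round_half_up(v)
            if r not in ints:
                ints.append(r)
        return ints
    return vals


def decode(vector: Sequence[float], space: HPOSpace) -> dict:
    """Map a unit-cube vector to an in-range assignment."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != space.dims:
        raise ValueError(f"expected {space.dims} dimensions, got {vector.size}")
    out = {}
    for v, spec in zip(vector, space.specs):
        v = float(np.clip(v, 0.0, 1.0))
        if spec.kind == "continuous":
            out[spec.name] = spec.low + v * (spec.high - spec.low)
        elif spec.kind == "integer":
            raw = spec.low + v * (spec.high - spec.low)
            out[spec.name] = int(np.clip(_round_half_up(raw),
                                         spec.low, spec.high))
        else:
            idx = min(int(v * len(spec.levels)), len(spec.levels) - 1)
            out[spec.name] = spec.levels[idx]
    return out


def encode(assignment: dict, space: HPOSpace) -> np.ndarray:
    """Inverse of decode up to the rounding class of each parameter."""
    vec = np.empty(space.dims)
    for i, spec in enumerate(space.specs):
        val = assignment[spec.name]
        if spec.kind == "categorical":
            idx = spec.levels.index(val)
            vec[i] = (idx + 0.5) / len(spec.levels)
        else:
            vec[i] = (val - spec.low) / (spec.high - spec.low)
    return vec


# ------------------------------------------------------------- classifiers

def make_classifier(model_kind: str, assignment: dict, seed: int):
    """Uniform adapter over the three model families."""
    if model_kind == "LR":
        return LogisticRegression(C=assignment["C"],
                                  l1_ratio=1.0 if assignment["penalty"] == "l1" else 0.0,
                                  solver="liblinear", max_iter=2000,
                                  random_state=seed)
    if model_kind == "SVM":
        return SVC(C=assignment["C"], gamma=assignment["gamma"],
                   kernel="rbf", random_state=seed)
    if model_kind == "XGB":
        return XGBClassifier(learning_rate=assignment["learning_rate"],
                             max_depth=assignment["max_depth"],
                             n_estimators=assignment["n_estimators"],
                             random_state=seed, n_jobs=1,
                             tree_method="hist", eval_metric="logloss",
                             verbosity=0)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def _metric_value(metric: str, y_true, scores, preds) -> float:
    if metric == "roc_auc":
        return M.roc_auc(y_true, scores)
    panel = M.confusion_metrics(y_true, preds, threshold=0.5)
    value = panel.ACC if metric == "acc" else panel.F1
    if value is None:
        raise ValueError(f"metric {metric} undefined on this fold")
    return value


def cv_fitness(assignment: dict, X, y, model_kind: str, k: int = 5,
               metric: str = "roc_auc", seed: int = 0) -> float:
    """Mean stratified k-fold metric for one assignment.

    Normalization is fitted per training fold and applied to its
    validation fold, so no validation statistics leak into training.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    folds = M.stratified_kfold(y, k, seed)
    values = []
    for fold in range(k):
        val = folds == fold
        ytr, yva = y[~val], y[val]
        if len(np.unique(ytr)) < 2 or len(np.unique(yva)) < 2:
            raise ValueError(f"fold {fold} is missing an outcome class")
        scaler = StandardScaler().fit(X[~val])
        clf = make_classifier(model_kind, assignment, seed)
        try:
            clf.fit(scaler.transform(X[~val]), ytr)
        except Exception as exc:
            raise RuntimeError(
                f"classifier failed for assignment {assignment}: {exc}") from exc
        Xva = scaler.transform(X[val])
        scores = _scores(clf, Xva)
        preds = (clf.predict(Xva) == 1).astype(int)
        values.append(_metric_value(metric, yva, scores, preds))
    return float(np.mean(values))


# ------------------------------------------------------------------ search

def grid_search(space: HPOSpace, X, y, k: int = 5, metric: str = "roc_auc",
                seed: int = 0) -> HPOResult:
    """Exhaustive Cartesian grid over the published ranges and steps."""
    grids = [grid_values(s) for s in space.specs]
    if any(len(g) == 0 for g in grids):
        raise ValueError("empty grid")
    history = []
    best_fit, best_assignment = -np.inf, None
    for combo in itertools.product(*grids):
        assignment = {s.name: v for s, v in zip(space.specs, combo)}
        fit = cv_fitness(assignment, X, y, space.model_kind, k, metric, seed)
        history.append((assignment, fit))
        if fit > best_fit:  # strict: ties keep the earliest assignment
            best_fit, best_assignment = fit, assignment
    return HPOResult(best_assignment=best_assignment, best_fitness=best_fit,
                     history=tuple(history), evaluations=len(history),
                     method="grid")


def evolve(space: HPOSpace, X, y, cfg: O.OptimizerConfig, k: int = 5,
           metric: str = "roc_auc", plateau_tol: float = 1e-4,
           plateau_patience: int = 20,
           feature_names: Optional[Sequence[str]] = None) -> HPOResult:
    """IBAS hyperparameter evolution over the unit cube.

    The optimizer minimizes the negative cross-validated fitness of the
    decoded assignment; repeated assignments are served from a cache so
    the classifier is trained once per distinct configuration.  When
    ``feature_names`` is given, one extra dimension per feature encodes a
    binary inclusion mask (value >= 0.5 keeps the feature) — a labelled
    extension for joint feature selection.  Runs stop early once the best
    fitness improves by less than ``plateau_tol`` over
    ``plateau_patience`` consecutive iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n_mask = len(feature_names) if feature_names is not None else 0
    dims = space.dims + n_mask
    cfg = replace(
        cfg,
        walk_step_init=cfg.walk_step_init if cfg.walk_step_init is not None else 0.25,
        walk_step_threshold=(cfg.walk_step_threshold
                             if cfg.walk_step_threshold is not None else 0.02),
        walk_max_evals=min(cfg.walk_max_evals, 30),
        early_stop_tol=(cfg.early_stop_tol if cfg.early_stop_tol is not None
                        else plateau_tol),
        early_stop_patience=(cfg.early_stop_patience
                             if cfg.early_stop_patience is not None
                             else plateau_patience),
    )
    unit = O.SearchSpace(np.zeros(dims), np.ones(dims))
    cache: dict = {}
    history: list[tuple[dict, float]] = []

    def objective(v: np.ndarray) -> float:
        assignment = decode(v[:space.dims], space)
        if n_mask:
            mask = tuple(v[space.dims:] >= 0.5)
            if not any(mask):  # empty feature set cannot be fitted
                return 1.0
            cols = np.flatnonzero(mask)
        else:
            mask, cols = (), slice(None)
        key = (tuple(sorted(assignment.items())), mask)
        if key not in cache:
            fit = cv_fitness(assignment, X[:, cols], y, space.model_kind,
                             k, metric, cfg.seed)
            cache[key] = fit
            record = dict(assignment)
            if n_mask:
                record["features"] = tuple(
                    f for f, m in zip(feature_names, mask) if m)
            history.append((record, fit))
        return -cache[key]

    result = O.optimize(objective, unit, cfg, variant="IBAS")
    if not history:
        raise RuntimeError("no successful fitness evaluations")
    best_record, best_fit = max(enumerate(history),
                                key=lambda t: (t[1][1], -t[0]))[1]
    best_record = dict(best_record)
    selected = best_record.pop("features", None) if n_mask else None
    return HPOResult(best_assignment=best_record, best_fitness=best_fit,
                     history=tuple(history), evaluations=len(history),
                     method="IBAS",
                     selected_features=selected)


def history_frame(result: HPOResult) -> pd.DataFrame:
    rows = []
    for assignment, fit in result.history:
        row = dict(assignment)
        row["fitness"] = fit
        rows.append(row)
    return pd.DataFrame(rows)
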