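"""Headless one-step analysis: cleaning, hyperparameter evolution, report.

Mirrors a point-and-click "one-step" clinical modelling workflow without
the GUI: a stratified train/test split, data cleaning whose statistics
are fitted on training rows only (missing-value imputation, winsorized
outliers, z-score normalization, optional minority oversampling), IBAS
hyperparameter evolution with optional joint feature selection, a final
refit, and metric panels for the training and held-out test sets plus
per-subject risk probabilities.

Nothing derived from test rows ever enters a training-side artifact;
the test suite enforces this by poisoning test rows and checking the
training artifacts are bit-identical.  By default normalization is
fitted on training rows only; a ``global`` scope exists for parity with
workflows that normalize the full dataset before splitting (which leaks
test statistics and is off by default).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from . import hpo
from . import metrics as M
from . import optimizer as O
from .cohort import CONTINUOUS, OUTCOME, CohortTable
from .stats import LogisticFit, predict_risk


@dataclass(frozen=True)
class PipelineConfig:
    model_kind: str = "XGB"
    metric: str = "roc_auc"
    population_size: int = 30
    iteration_count: int = 200
    test_set_proportion: float = 0.2
    cv_folds: int = 5
    seed: int = 0
    imputation: str = "median_mode"
    outlier_rule: str = "winsorize"  # winsorize | none
    normalization: bool = True
    normalization_scope: str = "train"  # train | global
    balancing: bool = True
    feature_selection: bool = False
    risk_threshold: float = 0.5
    plateau_tol: float = 1e-4
    plateau_patience: int = 20


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return one named diagnostic per violated invariant (empty = ok)."""
    diags = []
    if not 0.0 < cfg.test_set_proportion < 1.0:
        diags.append("test_set_proportion must be in (0, 1)")
    if cfg.cv_folds < 2:
        diags.append("cv_folds must be >= 2")
    if cfg.population_size < 1:
        diags.append("population_size must be >= 1")
    if cfg.iteration_count < 1:
        diags.append("iteration_count must be >= 1")
    if cfg.model_kind not in hpo.MODEL_KINDS:
        diags.append(f"model_kind must be one of {hpo.MODEL_KINDS}")
    if cfg.metric not in hpo.METRICS:
        diags.append(f"metric must be one of {hpo.METRICS}")
    if cfg.imputation not in ("median_mode",):
        diags.append("imputation must be 'median_mode'")
    if cfg.outlier_rule not in ("winsorize", "none"):
        diags.append("outlier_rule must be 'winsorize' or 'none'")
    if cfg.normalization_scope not in ("train", "global"):
        diags.append("normalization_scope must be 'train' or 'global'")
    if not 0.0 < cfg.risk_threshold < 1.0:
        diags.append("risk_threshold must be in (0, 1)")
    return diags


# ----------------------------------------------------------------- cleaning

@dataclass
class CleanResult:
    table: CohortTable
    log: dict
    artifacts: dict  # training-fitted statistics, keyed by step


def clean(table: CohortTable, cfg: PipelineConfig,
          train_mask: Optional[np.ndarray] = None) -> CleanResult:
    """Impute, winsorize and normalize; statistics fitted on training rows.

    ``train_mask`` marks the rows whose statistics parameterize every
    step (default: all rows).  Winsorization clips continuous values at
    median +/- 3*IQR/1.349 (a robust 3-sigma rule); normalization
    z-scores continuous columns.  Every action is counted in the log.
    """
    frame = table.frame.copy()
    if train_mask is None:
        train_mask = np.ones(len(frame), dtype=bool)
    predictors = [c for c in frame.columns if c != OUTCOME]
    log = {"imputed": {}, "winsorized": {}, "normalized": []}
    artifacts = {"impute": {}, "winsorize": {}, "normalize": {}}

    for col in predictors:
        if frame[col].isna().all():
            raise ValueError(f"column '{col}' is entirely missing")
        kind = table.types.get(col, CONTINUOUS)
        train_vals = frame.loc[train_mask, col].dropna()
        if kind == CONTINUOUS:
            fill = float(train_vals.median())
        else:
            fill = float(train_vals.mode().iloc[0])
        n_missing = int(frame[col].isna().sum())
        if n_missing:
            frame[col] = frame[col].fillna(fill)
            log["imputed"][col] = n_missing
        artifacts["impute"][col] = fill

    if cfg.outlier_rule == "winsorize":
        for col in predictors:
            if table.types.get(col, CONTINUOUS) != CONTINUOUS:
                continue
            tv = frame.loc[train_mask, col]
            med = float(tv.median())
            iqr = float(tv.quantile(0.75) - tv.quantile(0.25))
            half_width = 3.0 * iqr / 1.349
            lo, hi = med - half_width, med + half_width
            n_out = int(((frame[col] < lo) | (frame[col] > hi)).sum())
            if n_out:
                frame[col] = frame[col].clip(lo, hi)
                log["winsorized"][col] = n_out
            artifacts["winsorize"][col] = (lo, hi)

    if cfg.normalization:
        fit_mask = train_mask if cfg.normalization_scope == "train" \
            else np.ones(len(frame), dtype=bool)
        for col in predictors:
            if table.types.get(col, CONTINUOUS) != CONTINUOUS:
                continue
            mu = float(frame.loc[fit_mask, col].mean())
            sd = float(frame.loc[fit_mask, col].std(ddof=0))
            if sd == 0.0:
                sd = 1.0
            frame[col] = (frame[col] - mu) / sd
            log["normalized"].append(col)
            artifacts["normalize"][col] = (mu, sd)

    return CleanResult(table=CohortTable(frame=frame, types=dict(table.types)),
                       log=log, artifacts=artifacts)


def oversample_minority(y: np.ndarray, idx: np.ndarray,
                        seed: int) -> np.ndarray:
    """Indices of ``idx`` plus resampled minority rows to balance classes."""
    y_idx = y[idx]
    counts = {c: int(np.sum(y_idx == c)) for c in np.unique(y_idx)}
    if len(counts) < 2:
        return idx
    minority = min(counts, key=counts.get)
    deficit = max(counts.values()) - counts[minority]
    if deficit == 0:
        return idx
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 17)))
    extra = rng.choice(idx[y_idx == minority], size=deficit, replace=True)
    return np.concatenate([idx, extra])


# ------------------------------------------------------------------ one_step

@dataclass
class FittedModel:
    """Final classifier plus everything needed to score new subjects."""

    model_kind: str
    classifier: object
    feature_names: tuple[str, ...]
    impute: dict
    winsorize: dict
    normalize: dict
    types: dict

    def prepare(self, subjects: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in subjects.columns]
        if missing:
            raise ValueError(f"subjects are missing columns: {missing}")
        frame = subjects[list(self.feature_names)].copy().astype(float)
        for col in self.feature_names:
            if col in self.impute:
                frame[col] = frame[col].fillna(self.impute[col])
            if col in self.winsorize:
                lo, hi = self.winsorize[col]
                frame[col] = frame[col].clip(lo, hi)
            if col in self.normalize:
                mu, sd = self.normalize[col]
                frame[col] = (frame[col] - mu) / sd
        return frame.to_numpy(dtype=float)

    def predict_proba(self, subjects: pd.DataFrame) -> np.ndarray:
        X = self.prepare(subjects)
        clf = self.classifier
        if hasattr(clf, "predict_proba"):
            return clf.predict_proba(X)[:, 1]
        # decision scores squashed through the logistic link
        return 1.0 / (1.0 + np.exp(-clf.decision_function(X)))


@dataclass
class RunReport:
    config: PipelineConfig
    best_assignment: dict
    best_cv_fitness: float
    selected_features: tuple[str, ...]
    convergence: tuple[float, ...]
    cleaning_log: dict
    train_panel: M.MetricsPanel
    test_panel: M.MetricsPanel
    risks: pd.DataFrame
    model: FittedModel = field(repr=False, default=None)
    train_artifacts: dict = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "best_assignment": self.best_assignment,
            "best_cv_fitness": self.best_cv_fitness,
            "selected_features": list(self.selected_features),
            "convergence": list(self.convergence),
            "cleaning_log": self.cleaning_log,
            "train_metrics": self.train_panel.as_row(),
            "test_metrics": self.test_panel.as_row(),
        }
        return json.dumps(_pyify(payload), sort_keys=True, indent=2)


def _pyify(obj):
    if isinstance(obj, dict):
        return {str(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def one_step(data: Union[CohortTable, str, Path], cfg: PipelineConfig,
             out_dir: Optional[Union[str, Path]] = None) -> RunReport:
    """Full pipeline: split, clean, evolve, refit, evaluate, report.

    Deterministic given config + seed; with ``out_dir`` all artifacts
    (JSON report, metric/convergence/risk CSVs) are written there, and
    partial outputs are removed if any stage fails.
    """
    diags = validate_config(cfg)
    if diags:
        raise ValueError("invalid config: " + "; ".join(diags))
    table = data if isinstance(data, CohortTable) else CohortTable.read_csv(data)
    try:
        report = _run(table, cfg)
    except Exception as exc:
        raise RuntimeError(f"one-step pipeline failed: {exc}") from exc
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / "report.json").write_text(report.to_json())
            M.panel_frame({"train": report.train_panel,
                           "test": report.test_panel}
                          ).to_csv(out_dir / "metrics.csv")
            pd.DataFrame({"iteration": np.arange(1, len(report.convergence) + 1),
                          "best_fitness": report.convergence}
                         ).to_csv(out_dir / "convergence.csv", index=False)
            report.risks.to_csv(out_dir / "risk.csv", index=False)
        except Exception:
            shutil.rmtree(out_dir, ignore_errors=True)
            raise
    return report


def _run(table: CohortTable, cfg: PipelineConfig) -> RunReport:
    frame = table.frame
    y = frame[OUTCOME].to_numpy().astype(int)
    idx = np.arange(len(frame))
    train_idx, test_idx = train_test_split(
        idx, test_size=cfg.test_set_proportion, stratify=y,
        random_state=cfg.seed, shuffle=True)
    train_mask = np.zeros(len(frame), dtype=bool)
    train_mask[train_idx] = True

    cleaned = clean(table, cfg, train_mask)
    cframe = cleaned.table.frame
    predictors = [c for c in cframe.columns if c != OUTCOME]

    fit_idx = np.sort(train_idx)
    if cfg.balancing:
        fit_idx = oversample_minority(y, fit_idx, cfg.seed)
    Xtr = cframe.iloc[fit_idx][predictors].to_numpy(dtype=float)
    ytr = y[fit_idx]

    space = hpo.build_space(cfg.model_kind)
    ocfg = O.OptimizerConfig(population_size=cfg.population_size,
                             iterations=cfg.iteration_count, seed=cfg.seed)
    result = hpo.evolve(space, Xtr, ytr, ocfg, k=cfg.cv_folds,
                        metric=cfg.metric, plateau_tol=cfg.plateau_tol,
                        plateau_patience=cfg.plateau_patience,
                        feature_names=predictors if cfg.feature_selection else None)
    selected = (result.selected_features if result.selected_features
                else tuple(predictors))
    cols = [predictors.index(c) for c in selected]

    clf = hpo.make_classifier(cfg.model_kind, result.best_assignment, cfg.seed)
    scaler = StandardScaler().fit(Xtr[:, cols])
    clf.fit(scaler.transform(Xtr[:, cols]), ytr)

    # running best-so-far fitness over the evolution history
    best_curve = np.maximum.accumulate([f for _, f in result.history])

    model = FittedModel(
        model_kind=cfg.model_kind, classifier=_Scaled(clf, scaler),
        feature_names=tuple(selected),
        impute={k: v for k, v in cleaned.artifacts["impute"].items() if k in selected},
        winsorize={k: v for k, v in cleaned.artifacts["winsorize"].items() if k in selected},
        normalize={k: v for k, v in cleaned.artifacts["normalize"].items() if k in selected},
        types=dict(table.types))

    def panel(rows: np.ndarray) -> M.MetricsPanel:
        sub = cframe.iloc[rows]
        scores = _proba(clf, scaler, sub[list(selected)].to_numpy(dtype=float))
        return M.full_panel(y[rows], scores, threshold=cfg.risk_threshold)

    train_panel = panel(np.sort(train_idx))
    test_panel = panel(np.sort(test_idx))

    scores_all = _proba(clf, scaler, cframe[list(selected)].to_numpy(dtype=float))
    risks = pd.DataFrame({
        "subject": idx,
        "split": np.where(train_mask, "train", "test"),
        "probability": scores_all,
        "band": np.where(scores_all >= cfg.risk_threshold, "high", "low"),
    })

    return RunReport(
        config=cfg,
        best_assignment=result.best_assignment,
        best_cv_fitness=result.best_fitness,
        selected_features=tuple(selected),
        convergence=tuple(float(v) for v in best_curve),
        cleaning_log=cleaned.log,
        train_panel=train_panel,
        test_panel=test_panel,
        risks=risks,
        model=model,
        train_artifacts={"clean": cleaned.artifacts,
                         "best_assignment": result.best_assignment,
                         "cv_fitness": result.best_fitness},
    )


class _Scaled:
    """Classifier pre-composed with its final-training scaler."""

    def __init__(self, clf, scaler):
        self._clf = clf
        self._scaler = scaler

    def predict_proba(self, X):
        return self._clf.predict_proba(self._scaler.transform(X))

    def decision_function(self, X):
        return self._clf.decision_function(self._scaler.transform(X))


def _proba(clf, scaler, X: np.ndarray) -> np.ndarray:
    Xs = scaler.transform(X)
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(Xs)[:, 1]
    return 1.0 / (1.0 + np.exp(-clf.decision_function(Xs)))


# -------------------------------------------------------------- risk report

def risk_report(model: Union[FittedModel, LogisticFit], subjects: pd.DataFrame,
                threshold: float = 0.5,
                out_prefix: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Per-subject probabilities with a high/low band (p >= threshold => high)."""
    if isinstance(model, LogisticFit):
        probs = predict_risk(model, subjects)
    else:
        probs = model.predict_proba(subjects)
    out = pd.DataFrame({
        "probability": probs,
        "band": np.where(probs >= threshold, "high", "low"),
    })
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out.to_csv(out_prefix.with_suffix(".csv"), index=False)
        lines = [f"subject {i}: p={p:.3f} -> {b} risk"
                 for i, (p, b) in enumerate(zip(out.probability, out.band))]
        out_prefix.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return out
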