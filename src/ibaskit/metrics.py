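"""Binary-classifier evaluation: PRE/SEN/SPE/ACC/F1, ROC-AUC, PR-AUC.

Threshold-dependent metrics come from the confusion matrix at "score >=
threshold => positive".  ROC-AUC is the Mann-Whitney probability that a
random positive outscores a random negative (ties count half); PR-AUC is
average precision (trapezoidal interpolation over PR space is biased and
deliberately not used).  Ratios with a zero denominator are reported as
``None`` — undefined, never coerced to 0.

The ranking metrics and stratified folds delegate to scikit-learn; the
test suite cross-checks them against exhaustive pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

PANEL_COLUMNS = ["PRE", "SEN", "SPE", "ACC", "F1", "ROC-AUC", "PR-AUC"]


@dataclass(frozen=True)
class MetricsPanel:
    TP: int
    FP: int
    TN: int
    FN: int
    PRE: Optional[float]
    SEN: Optional[float]
    SPE: Optional[float]
    ACC: Optional[float]
    F1: Optional[float]
    ROC_AUC: Optional[float] = None
    PR_AUC: Optional[float] = None

    def as_row(self) -> dict:
        return {"PRE": self.PRE, "SEN": self.SEN, "SPE": self.SPE,
                "ACC": self.ACC, "F1": self.F1,
                "ROC-AUC": self.ROC_AUC, "PR-AUC": self.PR_AUC}


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_metrics(y, scores, threshold: float = 0.5) -> MetricsPanel:
    """Confusion-matrix metrics at a fixed score threshold."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    pre = _ratio(tp, tp + fp)
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    if pre is None or sen is None or (pre + sen) == 0:
        f1 = None
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return MetricsPanel(TP=tp, FP=fp, TN=tn, FN=fn, PRE=pre, SEN=sen,
                        SPE=spe, ACC=acc, F1=f1)


def roc_auc(y, scores) -> float:
    """Mann-Whitney ROC-AUC; errors on single-class labels."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def pr_auc(y, scores) -> float:
    """Average-precision PR-AUC; errors when no positives exist."""
    y = np.asarray(y).astype(int)
    if np.sum(y == 1) == 0:
        raise ValueError("PR-AUC needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def full_panel(y, scores, threshold: float = 0.5) -> MetricsPanel:
    """Confusion metrics plus both ranking AUCs."""
    base = confusion_metrics(y, scores, threshold)
    return MetricsPanel(**{**base.__dict__,
                           "ROC_AUC": roc_auc(y, scores),
                           "PR_AUC": pr_auc(y, scores)})


def panel_frame(panels: dict[str, MetricsPanel]) -> pd.DataFrame:
    """Rows of model -> metric panel in the standard column layout."""
    return pd.DataFrame({name: p.as_row() for name, p in panels.items()}).T[
        PANEL_COLUMNS]


def stratified_kfold(y, k: int, seed: int) -> np.ndarray:
    """Per-sample fold indices, class-balanced within one sample per fold."""
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y)
    if np.min(counts[counts > 0]) < k:
        raise ValueError(f"every class needs at least k={k} members")
    folds = np.empty(len(y), dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for i, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test_idx] = i
    return folds
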