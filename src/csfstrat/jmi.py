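"""Joint-mutual-information selection of a compact sub-grouping panel.

JMI is a greedy forward filter: the first feature maximizes the plug-in
mutual information I(X; Y) with the class; every later step adds the
candidate maximizing sum_{s in selected} I(X_cand, X_s; Y), the summed
joint information with the class over pairs formed with the already
selected features. Unlike a wrapper (e.g. RFE) it is classifier-free.

Continuous abundances are discretized by equal-frequency binning (default
5 bins) with bin edges computed on training subjects only; the pairwise
joint I(X_a, X_b; Y) is estimated from the 3-way contingency of
(bin_a, bin_b, y) with the plug-in estimator (no bias correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .selection import _standardizer, split_train_test

logger = logging.getLogger(__name__)


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X; Y) in nats from two discrete vectors.

    I = sum_{x,y} p(x,y) * log(p(x,y) / (p(x) p(y))), with 0*log0 = 0.
    """
    xv = np.asarray(x).ravel()
    yv = np.asarray(y).ravel()
    if xv.size == 0 or yv.size == 0:
        raise ValueError("empty input")
    if xv.size != yv.size:
        raise ValueError("length mismatch")
    _, xi = np.unique(xv, return_inverse=True)
    _, yi = np.unique(yv, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def equal_frequency_bins(train_values, bins: int = 5) -> np.ndarray:
    """Interior bin edges at training-set quantiles (duplicates collapsed)."""
    edges = np.quantile(np.asarray(train_values, dtype=float),
                        np.linspace(0, 1, bins + 1)[1:-1])
    return np.unique(edges)


def discretize(values, edges: np.ndarray) -> np.ndarray:
    return np.digitize(np.asarray(values, dtype=float), edges)


@dataclass
class JMISelection:
    selected: list
    step_scores: list[float]  # JMI objective value at each selection step
    bins: int
    bin_edges: dict  # feature -> edges (train-only)
    train_idx: np.ndarray | None = None
    excluded: tuple = ()


def jmi_select(
    features: pd.DataFrame,
    labels,
    target_size: int = 5,
    bins: int = 5,
) -> JMISelection:
    """Greedy JMI forward selection of ``target_size`` features.

    ``features`` should be the training subjects only (bin edges are
    computed here, so passing held-out rows would leak). Constant features
    are excluded and logged; ties break toward the earlier column.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if target_size >= features.shape[1]:
        raise ValueError("target_size must be smaller than the number of features")

    edges: dict = {}
    binned: dict = {}
    excluded = []
    for col in features.columns:
        vals = features[col].to_numpy()
        levels = np.unique(vals)
        if levels.size < 2:
            excluded.append(col)
            logger.warning("jmi_select: %s is constant, excluded", col)
            continue
        if levels.size <= bins:
            # already discrete: use the observed levels as categories
            # (quantile edges can land on data values and merge levels)
            edges[col] = levels
            binned[col] = np.searchsorted(levels, vals)
        else:
            e = equal_frequency_bins(vals, bins)
            edges[col] = e
            binned[col] = discretize(vals, e)
    candidates = [c for c in features.columns if c in binned]
    if target_size > len(candidates):
        raise ValueError("too few non-constant features for target_size")

    selected: list = []
    scores: list[float] = []
    nb = bins
    while len(selected) < target_size:
        best_col, best_score = None, -np.inf
        for col in candidates:
            if col in selected:
                continue
            if not selected:
                score = mutual_information(binned[col], y)
            else:
                score = 0.0
                for s in selected:
                    pair = binned[col].astype(np.int64) * (binned[s].max() + 1) + binned[s]
                    score += mutual_information(pair, y)
            if score > best_score + 1e-12:
                best_col, best_score = col, score
        selected.append(best_col)
        scores.append(float(best_score))
    return JMISelection(selected=selected, step_scores=scores, bins=nb,
                        bin_edges=edges, excluded=tuple(excluded))


def evaluate_subgroup_panel(
    features: pd.DataFrame,
    labels,
    panel,
    holdout_fraction: float = 0.2,
    seed: int = 0,
):
    """Held-out accuracy of a logistic classifier on the panel.

    80/20 stratified split; standardization and training use the 80% only.
    Returns (accuracy, confusion_matrix, train_idx, test_idx).
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    y = np.asarray(labels)
    train_idx, test_idx = split_train_test(y, fraction=1 - holdout_fraction, seed=seed)
    classes = np.unique(y)
    yb = (y == classes[-1]).astype(int)
    Xtr = features.iloc[train_idx][list(panel)].to_numpy(dtype=float)
    Xte = features.iloc[test_idx][list(panel)].to_numpy(dtype=float)
    mean, sd = _standardizer(Xtr)
    clf = LogisticRegression(C=1.0, max_iter=2000).fit((Xtr - mean) / sd, yb[train_idx])
    pred = clf.predict((Xte - mean) / sd)
    acc = float(accuracy_score(yb[test_idx], pred))
    cm = confusion_matrix(yb[test_idx], pred)
    return acc, cm, train_idx, test_idx


@dataclass
class CVResult:
    fold_assignments: np.ndarray  # fold id per subject
    fold_aucs: list[float]
    roc_curves: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per fold
    mean_auc: float
    se_auc: float


def cross_validated_roc(
    features: pd.DataFrame,
    labels,
    panel,
    k: int = 6,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold ROC of a linear logistic model on the panel.

    Per fold: standardize on the training folds, fit, sweep the decision
    score for the ROC; report mean AUC and its standard error across folds.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"each class needs at least {k} members for {k}-fold CV")
    yb = (y == classes[-1]).astype(int)
    X = features[list(panel)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    aucs, curves = [], []
    for f, (tr, te) in enumerate(skf.split(X, yb)):
        folds[te] = f
        mean, sd = _standardizer(X[tr])
        clf = LogisticRegression(C=1.0, max_iter=2000).fit((X[tr] - mean) / sd, yb[tr])
        score = clf.decision_function((X[te] - mean) / sd)
        fpr, tpr, _ = roc_curve(yb[te], score)
        curves.append((fpr, tpr))
        aucs.append(float(roc_auc_score(yb[te], score)))
    aucs_arr = np.asarray(aucs)
    return CVResult(fold_assignments=folds, fold_aucs=aucs,
                    roc_curves=curves, mean_auc=float(aucs_arr.mean()),
                    se_auc=float(aucs_arr.std(ddof=1) / np.sqrt(k)))
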