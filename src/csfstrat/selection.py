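"""Discriminative peptide-panel selection (control vs AD).

The panel is chosen by running recursive feature elimination (RFE) twice on
the training split — once under a linear max-margin classifier (SVM, C=1)
and once under L2 logistic regression — stopping each at a fixed panel size
(default 14), and keeping the intersection of the two selections. The
held-out split plays no role in selection or training and is scored once.
Panel significance is calibrated against random same-size panels evaluated
identically (permutation null with the (1+x)/(B+1) empirical p).

RFE here drops exactly one feature per step: refit the classifier on the
surviving features (standardized with train-only statistics), remove the
feature with the smallest absolute coefficient, repeat. The elimination
trace is recorded so selection behavior is fully auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, confusion_matrix, precision_score,
                             recall_score, roc_auc_score)
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "precision", "recall", "roc_auc")


def _make_classifier(kind: str, C: float = 1.0):
    if kind in ("svm", "max-margin"):
        return SVC(kernel="linear", C=C)
    if kind in ("logistic", "logreg"):
        return LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    raise ValueError(f"unknown classifier kind {kind!r}")


def split_train_test(labels, fraction: float = 0.8, seed: int = 0):
    """Stratified train/test index partition.

    Per class, ``ceil((1 - fraction) * n_class)`` subjects are held out
    (so e.g. 134 per class at fraction 0.8 yields 27 held-out per class);
    assignment within a class is a seeded shuffle. Returns
    (train_idx, test_idx) as sorted integer arrays partitioning
    ``range(len(labels))``.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size < 2:
            raise ValueError(f"class {c!r} too small to stratify")
        perm = rng.permutation(idx)
        n_test = int(np.ceil((1 - fraction) * idx.size))
        n_train = idx.size - n_test
        if n_train < 1:
            raise ValueError(f"class {c!r} too small to stratify")
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _standardizer(X_train: np.ndarray):
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def rfe(
    features: pd.DataFrame | np.ndarray,
    labels,
    base_classifier: str = "svm",
    stop_size: int = 14,
    step: int = 1,
) -> tuple[list, list]:
    """Recursive feature elimination down to ``stop_size`` features.

    ``features`` must already be standardized on the training set (the
    selection helpers do this). Returns (elimination_order, selected) in
    terms of column names (DataFrame input) or column indices. Ties on the
    smallest absolute coefficient break toward the lower column index.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else list(range(X.shape[1]))
    y = np.asarray(labels)
    if not (0 < stop_size <= X.shape[1]):
        raise ValueError("stop_size must be in (0, n_features]")
    if step != 1:
        raise ValueError("this implementation drops exactly one feature per step")

    remaining = list(range(X.shape[1]))
    eliminated: list = []
    while len(remaining) > stop_size:
        coefs = _fit_coefs(base_classifier, X[:, remaining], y)
        drop_pos = int(np.argmin(np.abs(coefs)))  # argmin is tie-stable (lowest index)
        eliminated.append(names[remaining[drop_pos]])
        del remaining[drop_pos]
    return eliminated, [names[j] for j in remaining]


def _fit_coefs(kind: str, X, y) -> np.ndarray:
    clf = _make_classifier(kind)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            logger.warning("rfe: %s did not converge; retrying with stronger regularization", kind)
            clf = _make_classifier(kind, C=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
    return np.ravel(clf.coef_)


def intersect_panels(set_a, set_b, feature_order=None) -> list:
    """Intersection of two selected panels, in input feature order."""
    a, b = list(set_a), list(set_b)
    if not a or not b:
        raise ValueError("both panels must be nonempty")
    order = list(feature_order) if feature_order is not None else a
    common = set(a) & set(b)
    panel = [f for f in order if f in common]
    if not panel:
        logger.warning("intersect_panels: empty intersection")
    return panel


@dataclass
class PanelMetrics:
    accuracy: float
    precision: float
    recall: float
    roc_auc: float
    confusion: np.ndarray

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "roc_auc": self.roc_auc,
                "confusion": self.confusion.tolist()}


def evaluate_panel(
    panel,
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    classifier: str = "logistic",
) -> PanelMetrics:
    """Train on the panel's training columns, report held-out metrics.

    Standardization parameters come from the training split only. The
    positive class is the lexicographically larger label.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    ytr, yte = np.asarray(y_train), np.asarray(y_test)
    if len(np.unique(yte)) < 2:
        raise ValueError("test split contains a single class")
    Xtr = X_train[list(panel)].to_numpy(dtype=float)
    Xte = X_test[list(panel)].to_numpy(dtype=float)
    mean, sd = _standardizer(Xtr)
    clf = _make_classifier(classifier)
    classes = np.unique(ytr)
    ytr_b, yte_b = (ytr == classes[-1]).astype(int), (yte == classes[-1]).astype(int)
    clf.fit((Xtr - mean) / sd, ytr_b)
    Z = (Xte - mean) / sd
    pred = clf.predict(Z)
    score = clf.decision_function(Z) if hasattr(clf, "decision_function") else clf.predict_proba(Z)[:, 1]
    return PanelMetrics(
        accuracy=float(accuracy_score(yte_b, pred)),
        precision=float(precision_score(yte_b, pred, zero_division=0)),
        recall=float(recall_score(yte_b, pred, zero_division=0)),
        roc_auc=float(roc_auc_score(yte_b, score)),
        confusion=confusion_matrix(yte_b, pred),
    )


@dataclass
class PanelSelection:
    train_idx: np.ndarray
    test_idx: np.ndarray
    elimination: dict  # classifier -> elimination order
    selected: dict  # classifier -> selected set (size stop_size)
    panel: list
    metrics: PanelMetrics


def select_panel(
    features: pd.DataFrame,
    labels,
    stop_size: int = 14,
    fraction: float = 0.8,
    seed: int = 0,
    classifiers: tuple[str, str] = ("svm", "logistic"),
) -> PanelSelection:
    """Full dual-classifier selection: split, standardize, RFE x2, intersect,
    evaluate the intersection on the held-out split."""
    y = np.asarray(labels)
    train_idx, test_idx = split_train_test(y, fraction=fraction, seed=seed)
    Xtr = features.iloc[train_idx]
    mean, sd = _standardizer(Xtr.to_numpy(dtype=float))
    Ztr = pd.DataFrame((Xtr.to_numpy(dtype=float) - mean) / sd,
                       columns=features.columns, index=Xtr.index)
    elimination, selected = {}, {}
    for kind in classifiers:
        elim, sel = rfe(Ztr, y[train_idx], base_classifier=kind, stop_size=stop_size)
        elimination[kind], selected[kind] = elim, sel
    panel = intersect_panels(selected[classifiers[0]], selected[classifiers[1]],
                             feature_order=features.columns)
    metrics = evaluate_panel(panel, features.iloc[train_idx], y[train_idx],
                             features.iloc[test_idx], y[test_idx])
    return PanelSelection(train_idx=train_idx, test_idx=test_idx,
                          elimination=elimination, selected=selected,
                          panel=panel, metrics=metrics)


@dataclass
class PermutationNull:
    observed: dict
    null: dict  # metric -> np.ndarray of B null values
    pvalues: dict
    B: int


def permutation_null(
    panel,
    features: pd.DataFrame,
    labels,
    train_idx,
    test_idx,
    B: int = 100_000,
    seed: int = 0,
    classifier: str = "logistic",
    metrics: tuple[str, ...] = METRICS,
) -> PermutationNull:
    """Random same-size-panel null for the observed panel's held-out metrics.

    Each of the ``B`` draws picks ``len(panel)`` features without
    replacement (draws may repeat across iterations), trains and scores the
    same classifier on the same split, and the empirical p per metric is
    (1 + #{null >= observed}) / (B + 1), which can never be zero.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    k = len(panel)
    n_feat = features.shape[1]
    if k > n_feat:
        raise ValueError("panel larger than the feature set")
    if k == n_feat:
        raise ValueError("panel equals the full feature set; null undefined")
    y = np.asarray(labels)
    ytr, yte = y[train_idx], y[test_idx]
    classes = np.unique(ytr)
    ytr_b, yte_b = (ytr == classes[-1]).astype(int), (yte == classes[-1]).astype(int)

    X = features.to_numpy(dtype=float)
    mean, sd = _standardizer(X[train_idx])
    Z = (X - mean) / sd  # train-referenced z-scores for all subjects
    Ztr, Zte = Z[train_idx], Z[test_idx]
    col_of = {name: i for i, name in enumerate(features.columns)}

    fns = {
        "accuracy": lambda yt, pred, sc: accuracy_score(yt, pred),
        "precision": lambda yt, pred, sc: precision_score(yt, pred, zero_division=0),
        "recall": lambda yt, pred, sc: recall_score(yt, pred, zero_division=0),
        "roc_auc": lambda yt, pred, sc: roc_auc_score(yt, sc),
    }
    bad = set(metrics) - set(fns)
    if bad:
        raise ValueError(f"unknown metrics: {sorted(bad)}")

    def score_cols(cols) -> dict:
        clf = _make_classifier(classifier)
        clf.fit(Ztr[:, cols], ytr_b)
        pred = clf.predict(Zte[:, cols])
        sc = (clf.decision_function(Zte[:, cols]) if hasattr(clf, "decision_function")
              else clf.predict_proba(Zte[:, cols])[:, 1])
        return {m: fns[m](yte_b, pred, sc) for m in metrics}

    observed = score_cols([col_of[p] for p in panel])
    rng = np.random.default_rng(seed)
    null = {m: np.empty(B) for m in metrics}
    for b in range(B):
        cols = rng.choice(n_feat, size=k, replace=False)
        sc = score_cols(cols)
        for m in metrics:
            null[m][b] = sc[m]
    pvalues = {m: float((1 + np.sum(null[m] >= observed[m] - 1e-12)) / (B + 1))
               for m in metrics}
    return PermutationNull(observed=observed, null=null, pvalues=pvalues, B=B)
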