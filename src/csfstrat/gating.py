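"""CSF analyte standardization, mixture-model ratio cutoffs, and gating.

The biomarker gate follows the common practice of fitting a two-component
Gaussian mixture to the cohort's tTau:Abeta42 ratio and declaring subjects
biomarker-positive when the ratio exceeds the decision boundary (strictly,
ratio > cutoff). The boundary is the equal-posterior crossing of the fitted
mixture — the Bayes decision boundary between the two components — found on
a grid between the component means and refined by root bracketing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from ._utils import as_float_array

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# standardization

def standardize(values, reference: tuple[float, float] | None = None):
    """Z-score ``values``; returns (z, (mean, sd)).

    When ``reference`` is given (e.g. train-only statistics) it is used
    instead of the input's own moments, so held-out data can be scored
    without leakage.
    """
    x = as_float_array(values)
    if reference is None:
        mean, sd = float(x.mean()), float(x.std(ddof=1))
    else:
        mean, sd = map(float, reference)
    if sd <= 0:
        raise ValueError("standard deviation of the reference set must be > 0")
    return (x - mean) / sd, (mean, sd)


@dataclass
class AnalytePanel:
    """Per-subject CSF analytes with derived ratios and z-scores."""

    data: pd.DataFrame  # columns abeta42, ttau, ptau (pg/ml)

    def __post_init__(self) -> None:
        missing = [c for c in ("abeta42", "ttau", "ptau") if c not in self.data.columns]
        if missing:
            raise ValueError(f"analyte columns missing: {missing}")

    def ratio(self, num: str = "ttau", den: str = "abeta42") -> pd.Series:
        r = self.data[num] / self.data[den]
        r.name = f"{num}_{den}_ratio"
        return r

    def standardized(self, column: str, reference=None) -> pd.Series:
        z, _ = standardize(self.data[column].to_numpy(), reference)
        return pd.Series(z, index=self.data.index, name=f"{column}_z")


# ---------------------------------------------------------------------------
# two-component mixture cutoff

@dataclass
class CutoffModel:
    """Two-component univariate Gaussian mixture and its decision cutoff.

    ``means``/``variances``/``weights`` are sorted by component mean (on the
    fitting scale; log scale if ``on_log_scale``). ``cutoff`` is on the
    original ratio scale, or None for a degenerate fit.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    variances: tuple[float, float]
    cutoff: float | None
    log_likelihood: float
    converged: bool
    degenerate: bool = False
    on_log_scale: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights), "means": list(self.means),
            "variances": list(self.variances), "cutoff": self.cutoff,
            "log_likelihood": self.log_likelihood, "converged": self.converged,
            "degenerate": self.degenerate, "on_log_scale": self.on_log_scale,
            "note": self.note,
        }


def equal_posterior_point(weights, means, variances) -> float:
    """Point between the component means where posterior membership is equal.

    Solved by locating a sign change of w1*N1(x) - w2*N2(x) on a dense grid
    between the means, then refining by Brent's method.
    """
    (w1, w2), (m1, m2), (v1, v2) = weights, means, variances
    s1, s2 = np.sqrt(v1), np.sqrt(v2)

    def f(x):
        return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

    grid = np.linspace(m1, m2, 2048)
    vals = f(grid)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        raise ValueError("no equal-posterior crossing between the component means")
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    return float(brentq(f, lo, hi))


def fit_ratio_mixture(
    ratios,
    on_log_scale: bool = False,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    min_separation: float = 1.0,
    min_weight: float = 0.02,
) -> CutoffModel:
    """EM fit of a two-component Gaussian mixture to a positive ratio vector.

    Best of ``n_starts`` restarts by log-likelihood; variance floored at
    1e-6 * var(data). A fit whose components are closer than
    ``min_separation`` of the wider component SD, or whose lighter component
    weighs less than ``min_weight``, is flagged degenerate and yields no
    cutoff (single-component data must not produce a silent threshold).
    """
    x = as_float_array(ratios, "ratios")
    if x.size < 20:
        raise ValueError("need at least 20 observations to fit a mixture")
    if np.any(x <= 0):
        raise ValueError("ratios must be positive")
    y = np.log(x) if on_log_scale else x
    floor = 1e-6 * float(np.var(y))
    if floor <= 0:
        raise ValueError("degenerate data: zero variance")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=n_starts, tol=tol,
        max_iter=max_iter, reg_covar=floor, random_state=seed,
    ).fit(y[:, None])
    order = np.argsort(gm.means_.ravel())
    w = tuple(float(v) for v in gm.weights_.ravel()[order])
    m = tuple(float(v) for v in gm.means_.ravel()[order])
    v = tuple(float(c) for c in gm.covariances_.reshape(-1)[order])
    ll = float(gm.score(y[:, None]) * y.size)
    converged = bool(gm.converged_)
    if not converged:
        logger.warning("mixture EM did not converge in %d iterations", max_iter)

    sep = abs(m[1] - m[0]) / np.sqrt(max(v))
    degenerate = sep < min_separation or min(w) < min_weight
    cutoff = None
    note = ""
    if degenerate:
        note = (f"degenerate fit: separation {sep:.3f} SD, min weight {min(w):.3f}; "
                "no cutoff derived")
        logger.warning("fit_ratio_mixture: %s", note)
    else:
        c = equal_posterior_point(w, m, v)
        cutoff = float(np.exp(c)) if on_log_scale else float(c)
    return CutoffModel(weights=w, means=m, variances=v, cutoff=cutoff,
                       log_likelihood=ll, converged=converged,
                       degenerate=degenerate, on_log_scale=on_log_scale, note=note)


# ---------------------------------------------------------------------------
# gating

def gate_subjects(
    analytes: AnalytePanel | pd.DataFrame,
    cutoff: float,
    cognitive_status,
) -> pd.Series:
    """Assign diagnosis-group labels from the tTau:Abeta42 ratio gate.

    Biomarker-positive iff ratio > cutoff (strict). Cognitively normal and
    positive -> "AsymAD"; normal and negative -> "CN/BM-"; impaired and
    positive -> "AD"; impaired but negative -> "Impaired/BM-" (outside the
    study groups). Subjects with missing analytes are labeled "excluded"
    and logged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    panel = analytes if isinstance(analytes, AnalytePanel) else AnalytePanel(analytes)
    df = panel.data
    normal = pd.Series(np.asarray(cognitive_status, dtype=bool), index=df.index)
    ratio = df["ttau"] / df["abeta42"]
    missing = df[["ttau", "abeta42"]].isna().any(axis=1)
    positive = ratio > cutoff

    labels = pd.Series(index=df.index, dtype="object", name="group")
    labels[normal & positive] = "AsymAD"
    labels[normal & ~positive] = "CN/BM-"
    labels[~normal & positive] = "AD"
    labels[~normal & ~positive] = "Impaired/BM-"
    if missing.any():
        labels[missing] = "excluded"
        for sid in df.index[missing]:
            logger.warning("gate_subjects: %s excluded (missing analytes)", sid)
    return labels


# ---------------------------------------------------------------------------
# Youden-index ROC cutoff

@dataclass
class RocCutoff:
    threshold: float
    direction: str  # "greater" (score > threshold is positive) or "lesser"
    sensitivity: float
    specificity: float
    youden_j: float
    uninformative: bool = False


def youden_cutoff(scores, labels, direction: str = "greater") -> RocCutoff:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct scores; ties in J
    break toward higher specificity. With a single distinct score the lone
    candidate is that value and the result is flagged uninformative.
    """
    if direction not in ("greater", "lesser"):
        raise ValueError("direction must be 'greater' or 'lesser'")
    s = as_float_array(scores, "scores")
    y = np.asarray(labels).astype(int).ravel()
    if s.size != y.size:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    distinct = np.unique(s)
    if distinct.size == 1:
        cands = distinct
    else:
        cands = (distinct[:-1] + distinct[1:]) / 2.0
    npos, nneg = int(y.sum()), int((1 - y).sum())
    best = None
    for t in cands:
        pred = s > t if direction == "greater" else s < t
        sens = float((pred & (y == 1)).sum()) / npos
        spec = float((~pred & (y == 0)).sum()) / nneg
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, t, sens, spec, j)
    _, t, sens, spec, j = best
    return RocCutoff(threshold=float(t), direction=direction, sensitivity=sens,
                     specificity=spec, youden_j=j,
                     uninformative=bool(distinct.size == 1 or j <= 0))
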