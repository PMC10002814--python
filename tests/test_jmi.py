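import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfstrat.jmi import (cross_validated_roc, discretize, equal_frequency_bins,
                          evaluate_subgroup_panel, jmi_select, mutual_information)


# ---------------------------------------------------------------------------
# mutual information

def test_identical_balanced_binary_is_log2():
    x = np.array([0, 1] * 50)
    assert mutual_information(x, x) == pytest.approx(np.log(2))


def test_independent_counts_give_zero():
    # exact product joint supplied as counts: 2x2 with p(x,y)=p(x)p(y)
    x = np.repeat([0, 0, 1, 1], [6, 2, 3, 1])
    y = np.repeat([0, 1, 0, 1], [6, 2, 3, 1])
    assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)


def test_three_by_two_table_term_by_term():
    counts = np.array([[4, 1], [2, 3], [1, 5]])
    x = np.repeat([0, 0, 1, 1, 2, 2], counts.ravel())
    y = np.repeat([0, 1, 0, 1, 0, 1], counts.ravel())
    n = counts.sum()
    expected = 0.0
    for i in range(3):
        for j in range(2):
            pij = counts[i, j] / n
            if pij:
                expected += pij * np.log(pij / (counts[i].sum() / n * counts[:, j].sum() / n))
    assert mutual_information(x, y) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=10, max_size=60), st.integers(0, 2**30))
def test_mi_nonnegative_and_symmetric(xs, seed):
    rng = np.random.default_rng(seed)
    x = np.asarray(xs)
    y = rng.integers(0, 2, x.size)
    mi_xy = mutual_information(x, y)
    assert mi_xy >= -1e-12
    assert mi_xy == pytest.approx(mutual_information(y, x), abs=1e-12)


def test_mi_matches_sklearn(rng):
    from sklearn.metrics import mutual_info_score

    x = rng.integers(0, 5, 200)
    y = rng.integers(0, 2, 200)
    assert mutual_information(x, y) == pytest.approx(mutual_info_score(x, y), rel=1e-10)


# ---------------------------------------------------------------------------
# discretization

def test_equal_frequency_bins_on_train_only(rng):
    train = rng.normal(size=500)
    edges = equal_frequency_bins(train, bins=5)
    binned = discretize(train, edges)
    counts = np.bincount(binned, minlength=5)
    assert counts.min() > 80  # roughly equal occupancy
    assert edges.size == 4


# ---------------------------------------------------------------------------
# JMI selection

def test_feature_identical_to_label_selected_first(rng):
    n = 200
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({
        "noise1": rng.normal(size=n),
        "signal": y + rng.normal(0, 1e-6, n),
        "noise2": rng.normal(size=n),
    })
    sel = jmi_select(X, y, target_size=2, bins=4)
    assert sel.selected[0] == "signal"


def _jmi_oracle(binned, y, target_size):
    """Exhaustive evaluation of the greedy JMI objective at every step."""
    cols = list(binned)
    selected, scores = [], []
    while len(selected) < target_size:
        best, best_s = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            if not selected:
                s = mutual_information(binned[c], y)
            else:
                s = sum(
                    mutual_information(
                        [f"{a}_{b}" for a, b in zip(binned[c], binned[sv])], y)
                    for sv in selected)
            if s > best_s + 1e-12:
                best, best_s = c, s
        selected.append(best)
        scores.append(best_s)
    return selected, scores


def test_selection_matches_exhaustive_objective(rng):
    n = 150
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({f"f{j}": rng.normal(size=n) + 0.7 * y * (j % 2) for j in range(4)})
    sel = jmi_select(X, y, target_size=2, bins=3)
    binned = {c: discretize(X[c], equal_frequency_bins(X[c], 3)) for c in X.columns}
    oracle_sel, oracle_scores = _jmi_oracle(binned, y, 2)
    assert sel.selected == oracle_sel
    np.testing.assert_allclose(sel.step_scores, oracle_scores, rtol=1e-10)


def test_xor_partner_outranks_noise():
    # constructed joint: y = xor(f1, f2) with a 5% marginal bias planted on
    # f1 (20 of 400 rows flipped toward y) and noise features built exactly
    # balanced within every (f1, y) cell, so their sample MI with y is 0 and
    # their joint score with f1 adds nothing
    rows = []
    for a, b in itertools.product([0, 1], repeat=2):
        rows += [(a, b, a ^ b)] * 100
    f1, f2, y = (np.array(v) for v in zip(*rows))
    flip = np.flatnonzero(f1 != y)[:20]
    f1[flip] = y[flip]
    noise = np.arange(400) % 2  # alternating within each 100-row block
    X = pd.DataFrame({
        "f1": f1.astype(float),
        "n1": noise.astype(float), "n2": noise[::-1].astype(float),
        "f2": f2.astype(float),
    })
    sel = jmi_select(X, y, target_size=2, bins=2)
    assert sel.selected[0] == "f1"
    assert sel.selected[1] == "f2"


def test_target_size_one_equals_univariate_mi_ranking(rng):
    n = 300
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({f"f{j}": rng.normal(size=n) + 0.3 * j * y for j in range(5)})
    sel = jmi_select(X, y, target_size=1, bins=4)
    mis = {c: mutual_information(discretize(X[c], equal_frequency_bins(X[c], 4)), y)
           for c in X.columns}
    assert sel.selected[0] == max(mis, key=mis.get)


def test_constant_feature_excluded(rng):
    n = 100
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({"const": np.ones(n), "a": rng.normal(size=n) + y,
                      "b": rng.normal(size=n)})
    sel = jmi_select(X, y, target_size=1, bins=3)
    assert "const" in sel.excluded
    assert sel.selected[0] == "a"


def test_validation_errors(rng):
    X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
    with pytest.raises(ValueError):
        jmi_select(X, np.zeros(50), target_size=1)
    with pytest.raises(ValueError):
        jmi_select(X, np.repeat([0, 1], 25), target_size=2)


# ---------------------------------------------------------------------------
# panel evaluation

def test_separable_subgroups_score_one(rng):
    n = 100
    y = np.repeat(["Control-like", "AD-like"], n // 2)
    X = pd.DataFrame({"a": rng.normal(size=n) + 8 * (y == "AD-like"),
                      "b": rng.normal(size=n)})
    acc, cm, tr, te = evaluate_subgroup_panel(X, y, ["a"], seed=0)
    assert acc == 1.0
    assert cm.sum() == len(te)


def test_shuffled_labels_near_majority_rate(rng):
    n = 400
    y = rng.permutation(np.repeat(["Control-like", "AD-like"], n // 2))
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    acc, *_ = evaluate_subgroup_panel(X, y, ["a", "b"], seed=1)
    assert abs(acc - 0.5) < 0.2


# ---------------------------------------------------------------------------
# cross-validated ROC

def test_perfect_panel_has_unit_auc_zero_se(rng):
    n = 120
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({"a": y + rng.normal(0, 1e-3, n)})
    cv = cross_validated_roc(X, y, ["a"], k=6, seed=0)
    assert cv.mean_auc == pytest.approx(1.0)
    assert cv.se_auc == pytest.approx(0.0)
    assert len(cv.fold_aucs) == 6


def test_fold_auc_equals_mannwhitney_pair_counting(rng):
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    n = 60
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({"a": rng.normal(size=n) + 0.8 * y, "b": rng.normal(size=n)})
    cv = cross_validated_roc(X, y, ["a", "b"], k=6, seed=5)
    # reproduce each fold's score and count pairs by brute force
    skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=5)
    Xv = X.to_numpy()
    for f, (tr, te) in enumerate(skf.split(Xv, y)):
        mean, sd = Xv[tr].mean(0), Xv[tr].std(0)
        clf = LogisticRegression(C=1.0, max_iter=2000).fit((Xv[tr] - mean) / sd, y[tr])
        s = clf.decision_function((Xv[te] - mean) / sd)
        pos, neg = s[y[te] == 1], s[y[te] == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert cv.fold_aucs[f] == pytest.approx(wins / (len(pos) * len(neg)))


def test_random_features_near_chance(rng):
    n = 300
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    cv = cross_validated_roc(X, y, ["a", "b"], k=6, seed=2)
    assert abs(cv.mean_auc - 0.5) <= 3 * max(cv.se_auc, 0.05)


def test_class_smaller_than_k_rejected(rng):
    y = np.array([0] * 4 + [1] * 30)
    X = pd.DataFrame({"a": rng.normal(size=34)})
    with pytest.raises(ValueError):
        cross_validated_roc(X, y, ["a"], k=6)
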