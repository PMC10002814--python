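import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from scipy.stats import hypergeom

from csfstrat.stats import (bh_fdr, dichotomized_logistic, fisher_exact_rx2,
                            kendall_ranking, matched_test, mcnemar_bowker,
                            median_regression, paired_t, wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# median regression

def test_noiseless_linear_fit_is_exact(rng):
    x = rng.normal(size=60)
    y = 2.0 + 3.0 * x
    res = median_regression(y, x, ci_method="asymptotic")
    assert res.beta == pytest.approx(3.0, abs=1e-6)


def test_planted_slope_recovered_under_skewed_noise(rng):
    n = 2000
    x = rng.normal(size=n)
    noise = rng.gamma(2.0, 1.5, n)
    noise -= np.median(rng.gamma(2.0, 1.5, 200000))  # median-zero skew noise
    y = 1.0 - 0.9 * x + noise
    res = median_regression(y, x, ci_method="asymptotic")
    assert res.beta == pytest.approx(-0.9, abs=0.1)


def test_small_n_matches_linear_programming_oracle(rng):
    # oracle: exhaustive search over all lines through 2 points (an optimal
    # median-regression fit passes through at least p data points)
    x = rng.normal(size=12)
    y = 0.5 + 1.3 * x + rng.gamma(1.5, 1.0, 12)
    best = None
    for i, j in itertools.combinations(range(12), 2):
        if x[i] == x[j]:
            continue
        b = (y[j] - y[i]) / (x[j] - x[i])
        a = y[i] - b * x[i]
        loss = np.abs(y - a - b * x).sum()
        if best is None or loss < best[0]:
            best = (loss, b)
    res = median_regression(y, x, ci_method="asymptotic")
    assert res.beta == pytest.approx(best[1], abs=1e-4)


def test_scaling_outcome_scales_beta(rng):
    x = rng.normal(size=80)
    y = 1.0 + 2.0 * x + rng.gamma(2, 1, 80)
    b1 = median_regression(y, x, ci_method="asymptotic").beta
    b2 = median_regression(10 * y, x, ci_method="asymptotic").beta
    assert b2 == pytest.approx(10 * b1, rel=1e-4)


def test_bootstrap_ci_contains_estimate(rng):
    x = rng.normal(size=120)
    y = 0.3 * x + rng.gamma(2, 1, 120)
    res = median_regression(y, x, n_boot=100, seed=4)
    assert res.ci_low <= res.beta <= res.ci_high


def test_rank_deficiency_rejected(rng):
    x = rng.normal(size=50)
    cov = {"dup": x}  # duplicate of the analyte column
    with pytest.raises(ValueError):
        median_regression(rng.normal(size=50), x, covariates=cov)


# ---------------------------------------------------------------------------
# dichotomized logistic

def test_no_signal_gives_near_zero_logodds(rng):
    x = rng.normal(size=400)
    y = rng.normal(size=400)  # outcome independent of analyte
    res = dichotomized_logistic(y, x)
    assert abs(res.beta) < 0.3


def test_planted_logodds_slope_recovered(rng):
    n = 2000
    x = rng.normal(size=n)
    # latent outcome whose median split has log-odds slope ~1 in x
    p = 1 / (1 + np.exp(-x))
    y = (rng.random(n) < p).astype(float) + rng.normal(0, 1e-6, n)
    res = dichotomized_logistic(y, x)
    assert res.beta == pytest.approx(1.0, abs=0.15)


def test_constant_outcome_rejected(rng):
    with pytest.raises(ValueError):
        dichotomized_logistic(np.ones(50), rng.normal(size=50))


def test_perfect_separation_flagged(rng):
    x = np.concatenate([rng.normal(-3, 0.1, 30), rng.normal(3, 0.1, 30)])
    y = np.concatenate([np.zeros(30), np.ones(30)]) + rng.normal(0, 1e-9, 60)
    res = dichotomized_logistic(y, x)
    assert res.flagged


# ---------------------------------------------------------------------------
# BH FDR

def _stepup_oracle(p, q):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            kmax = rank
    reject[order[:kmax]] = True
    return reject


def test_bh_extremes():
    assert bh_fdr([0.0, 0.0, 0.0]).all()
    assert not bh_fdr([1.0, 1.0, 1.0]).any()


def test_bh_matches_stepup_definition():
    p = [0.01, 0.02, 0.30, 0.90]
    np.testing.assert_array_equal(bh_fdr(p, q=0.20), _stepup_oracle(p, 0.20))


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
       st.floats(0.01, 0.5))
def test_bh_properties(p, q):
    reject = bh_fdr(p, q=q)
    np.testing.assert_array_equal(reject, _stepup_oracle(p, q))
    # monotone in p
    p_arr = np.asarray(p)
    if reject.any():
        assert reject[p_arr <= p_arr[reject].max()].all()
    # superset of Bonferroni
    bonf = p_arr <= q / len(p_arr)
    assert reject[bonf].all()


# ---------------------------------------------------------------------------
# Kendall ranking

def _tau_b_bruteforce(x, y):
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - ties_x) * (n0 - ties_y))


def test_kendall_extremes(small_cohort):
    import pandas as pd

    score = np.arange(20, dtype=float)
    peptides = pd.DataFrame({"same": score, "anti": -score})
    rank = kendall_ranking(peptides, score)
    tab = rank.table.set_index("peptide")["tau"]
    assert tab["same"] == pytest.approx(1.0)
    assert tab["anti"] == pytest.approx(-1.0)


def test_kendall_matches_pair_counting_with_ties(rng):
    import pandas as pd

    x = rng.integers(0, 5, 30).astype(float)
    y = rng.integers(0, 4, 30).astype(float)
    rank = kendall_ranking(pd.DataFrame({"p": x}), y)
    assert rank.table.loc[0, "tau"] == pytest.approx(_tau_b_bruteforce(x, y))


def test_kendall_sorted_descending_and_constant_excluded(rng):
    import pandas as pd

    df = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30),
                       "const": np.ones(30)})
    score = rng.normal(size=30)
    rank = kendall_ranking(df, score, highlight=["a"])
    assert rank.excluded == ("const",)
    taus = rank.table["tau"].to_numpy()
    assert (np.diff(taus) <= 0).all()
    assert rank.table.set_index("peptide")["highlighted"]["a"]


# ---------------------------------------------------------------------------
# matched / contingency tests

def test_wilcoxon_undefined_for_identical_pairs():
    res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
    assert res.flagged and np.isnan(res.pvalue)


def test_paired_t_on_shifted_pairs(rng):
    a = rng.normal(size=40)
    res = paired_t(a + 1.0, a)
    assert res.pvalue < 1e-10


def test_symmetric_table_gives_zero_bowker_statistic():
    table = [[5, 3, 2], [3, 7, 4], [2, 4, 6]]
    res = mcnemar_bowker(table)
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)


def test_fisher_2x2_equals_hypergeometric_enumeration():
    table = np.array([[8, 2], [1, 9]])
    res = matched_test("fisher_exact", table)
    # oracle: enumerate k successes in the first row margin
    M, n, N = table.sum(), table[0].sum(), table[:, 0].sum()
    probs = {k: hypergeom.pmf(k, M, n, N) for k in range(0, min(n, N) + 1)}
    p_obs = probs[table[0, 0]]
    p_two = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
    assert res.pvalue == pytest.approx(p_two, rel=1e-9)


def test_fisher_rx2_disjoint_diagonal():
    res = fisher_exact_rx2([[10, 0], [0, 10]])
    assert res.pvalue == pytest.approx(2 * hypergeom.pmf(10, 20, 10, 10), rel=1e-9)


def _rx2_bruteforce(table):
    t = np.asarray(table, int)
    rows = t.sum(axis=1)
    c1 = t[:, 0].sum()
    N = t.sum()

    def prob(x):
        num = np.prod([comb(r, k, exact=True) for r, k in zip(rows, x)])
        return num / comb(N, c1, exact=True)

    p_obs = prob(t[:, 0])
    total = 0.0
    for x in itertools.product(*[range(r + 1) for r in rows]):
        if sum(x) != c1:
            continue
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_rx2_equals_bruteforce_enumeration():
    table = [[6, 2], [3, 7], [1, 5]]
    res = fisher_exact_rx2(table)
    assert res.pvalue == pytest.approx(_rx2_bruteforce(table), rel=1e-9)


def test_fisher_identical_distributions_p_one():
    res = fisher_exact_rx2([[5, 5], [3, 3], [2, 2]])
    assert res.pvalue == pytest.approx(1.0, abs=1e-9)


def test_fisher_monte_carlo_fallback_close_to_exact():
    table = [[6, 2], [3, 7], [1, 5]]
    exact = fisher_exact_rx2(table).pvalue
    mc = fisher_exact_rx2(table, max_tables=1, n_mc=20000, seed=0).pvalue
    assert mc == pytest.approx(exact, abs=0.02)
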