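"""Fisher exact, Mann-Whitney, Spearman and one-tailed chi-square tests.

The Fisher implementation is checked three ways: against the published
rearrangement-frequency p-values, against an exact-rational brute-force
enumeration, and against scipy's independent implementation.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from minisatkit.stability_stats import (
    chi2_one_tailed,
    fisher_exact_two_tailed,
    mann_whitney_two_tailed,
    spearman_correlation,
)


# ---------------------------------------------------------------- Fisher

def _fisher_oracle(a, b, c, d):
    """Exact-rational enumeration of all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)

    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    total = sum(
        pmf(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(k) <= p_obs
    )
    return float(total)


@pytest.mark.parametrize(
    "table, published",
    [
        ([[3, 189], [39, 153]], 8.8e-10),  # untreated vs G4-ligand treated
        ([[3, 189], [16, 176]], 3.55e-3),  # wild type vs pif1 deletion
    ],
)
def test_rearrangement_frequency_p_values(table, published):
    res = fisher_exact_two_tailed(table)
    assert res.p_value == pytest.approx(published, rel=0.02)
    (a, b), (c, d) = table
    assert res.p_value == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)


@pytest.mark.parametrize(
    "table",
    [
        [[5, 5], [5, 5]],
        [[1, 9], [8, 2]],
        [[0, 12], [7, 5]],
        [[3, 189], [16, 176]],
        [[20, 172], [45, 147]],
    ],
)
def test_fisher_matches_oracle_and_scipy(table):
    res = fisher_exact_two_tailed(table)
    (a, b), (c, d) = table
    assert res.p_value == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)
    assert res.p_value == pytest.approx(
        sps.fisher_exact(table, alternative="two-sided")[1], rel=1e-9
    )


def test_fisher_symmetry_under_row_and_column_swap():
    t = [[3, 189], [16, 176]]
    p = fisher_exact_two_tailed(t).p_value
    assert fisher_exact_two_tailed([t[1], t[0]]).p_value == pytest.approx(p)
    assert fisher_exact_two_tailed([[3, 16], [189, 176]]).p_value == pytest.approx(p)


def test_fisher_degenerate_tables():
    assert fisher_exact_two_tailed([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="empty margin"):
        assert fisher_exact_two_tailed([[0, 0], [3, 4]]).p_value == 1.0
    with pytest.raises(ValueError):
        fisher_exact_two_tailed([[1, -1], [2, 3]])


# ---------------------------------------------------------------- Mann-Whitney

def test_mw_identical_samples():
    x = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    res = mann_whitney_two_tailed(x, x)
    assert res.p_value > 0.95


def test_mw_complete_separation():
    x = list(range(10))
    y = list(range(100, 110))
    res = mann_whitney_two_tailed(x, y)
    assert res.statistic == 0.0
    assert res.p_value < 1e-3


def test_mw_exact_path_small_samples():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = mann_whitney_two_tailed(x, y)
    assert "exact" in res.method
    assert res.p_value == pytest.approx(2 / math.comb(6, 3))  # 0.1


def test_mw_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    x = rng.normal(size=15)
    y = rng.normal(0.8, 1, size=12)
    p1 = mann_whitney_two_tailed(x, y).p_value
    p2 = mann_whitney_two_tailed(np.exp(x), np.exp(y)).p_value
    assert p1 == pytest.approx(p2)


def test_mw_detects_shifted_addition_position_distributions():
    """Samples emulating remaining-motif counts with medians near 25 vs 11."""
    rng = np.random.default_rng(42)
    untreated = np.clip(rng.normal(25, 9, size=15), 1, 43).round()
    treated = np.clip(rng.normal(11, 7, size=12), 1, 43).round()
    res = mann_whitney_two_tailed(untreated, treated)
    assert res.p_value < 0.05


def test_mw_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney_two_tailed([], [1, 2])


# ---------------------------------------------------------------- Spearman

def test_spearman_monotone_extremes():
    x = [1, 2, 3, 4, 5, 6]
    assert spearman_correlation(x, [v * 3 + 1 for v in x]).statistic == pytest.approx(1.0)
    assert spearman_correlation(x, x[::-1]).statistic == pytest.approx(-1.0)


def test_spearman_constant_input_flagged():
    res = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
    assert math.isnan(res.statistic) and "undefined" in res.method


def test_spearman_exact_matches_scipy_permutation_test():
    rng = np.random.default_rng(9)
    x = rng.normal(size=7)
    y = rng.normal(size=7)
    res = spearman_correlation(x, y)
    assert "exact" in res.method

    def statistic(yy):
        return sps.spearmanr(x, yy).statistic

    ref = sps.permutation_test(
        (y,), statistic, permutation_type="pairings", n_resamples=math.inf
    )
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


def test_spearman_large_n_uses_t_approximation():
    rng = np.random.default_rng(10)
    x = rng.normal(size=30)
    y = x + rng.normal(scale=2, size=30)
    res = spearman_correlation(x, y)
    assert "t approximation" in res.method
    assert res.p_value == pytest.approx(sps.spearmanr(x, y).pvalue)


# ---------------------------------------------------------------- calibration

def test_exact_spearman_attainable_level_near_alpha():
    """Type-I error of the exact n=8 permutation rule sits in 0.05 +/- 0.01.

    Computed analytically: enumerate the null distribution of |sum rx*ry|
    over all pairings and evaluate P(p-value <= 0.05).
    """
    from itertools import permutations

    n = 8
    rx = np.arange(1, n + 1, dtype=float)
    rxc = rx - rx.mean()
    perm = np.array(list(permutations(rxc)))
    dots = np.abs(perm @ rxc)
    pvals = np.array([(dots >= d - 1e-9).mean() for d in np.unique(dots)])
    probs = np.array([(np.isclose(dots, d)).mean() for d in np.unique(dots)])
    type1 = float(probs[pvals <= 0.05].sum())
    assert abs(type1 - 0.05) <= 0.01


def test_mw_and_spearman_type1_calibration():
    """Monte-Carlo type-I error at alpha=0.05 within 0.05 +/- 0.01."""
    rng = np.random.default_rng(123)
    reps = 4000
    rej_mw = rej_sp = 0
    for _ in range(reps):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        if mann_whitney_two_tailed(x, y).p_value <= 0.05:
            rej_mw += 1
        x10 = rng.normal(size=10)
        y10 = rng.normal(size=10)
        if sps.spearmanr(x10, y10).pvalue <= 0.05:  # the n>9 path's approximation
            rej_sp += 1
    assert abs(rej_mw / reps - 0.05) <= 0.01
    assert abs(rej_sp / reps - 0.05) <= 0.01


# ---------------------------------------------------------------- chi-square

def test_chi2_one_tailed_rules():
    # observed exactly at expectation: chi2 = 0, one-tailed p = 0.5
    res = chi2_one_tailed(observed=100, total=1000, expected_fraction=0.10)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(0.5)
    # enrichment: one-tailed p is half the two-tailed p
    res_hi = chi2_one_tailed(150, 1000, 0.10)
    assert res_hi.p_value == pytest.approx(
        float(sps.chi2.sf(res_hi.statistic, 1)) / 2
    )
    # depletion maps to the complementary tail
    res_lo = chi2_one_tailed(50, 1000, 0.10)
    assert res_lo.p_value == pytest.approx(
        1 - float(sps.chi2.sf(res_lo.statistic, 1)) / 2
    )
    assert res_lo.p_value > 0.99


def test_chi2_input_validation():
    with pytest.raises(ValueError):
        chi2_one_tailed(1, 0, 0.1)
    with pytest.raises(ValueError):
        chi2_one_tailed(1, 10, 0.0)
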