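"""Hypothesis tests used in the minisatellite fragility analyses.

* Two-tailed Fisher's exact test for 2x2 rearrangement-frequency tables
  (hand-written, log-gamma arithmetic, point-probability two-sided rule —
  the convention of R's ``fisher.test`` — so that p-values down to 1e-12
  stay accurate to 3 significant figures).
* Two-tailed Mann-Whitney-Wilcoxon for telomere-addition position
  distributions: exact null for small tie-free samples, tie-corrected
  normal approximation otherwise.
* Spearman rank correlation for array-size versus rate: exact permutation
  p for n <= 9, t approximation otherwise.
* One-tailed chi-square (1 df) for terminal enrichment of catalog records.

All tests are deterministic given their inputs; the significance cutoff
used throughout is alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "fisher_exact_two_tailed",
    "mann_whitney_two_tailed",
    "spearman_correlation",
    "chi2_one_tailed",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one" or "two"
    method: str


def _log_hypergeom_pmf(k: int, r1: int, r2: int, c1: int) -> float:
    # P(K=k) for the hypergeometric with margins (r1, r2) x (c1, c2).
    return (
        math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1) - math.lgamma(r2 - (c1 - k) + 1)
        - (math.lgamma(r1 + r2 + 1) - math.lgamma(c1 + 1)
           - math.lgamma(r1 + r2 - c1 + 1))
    )


def fisher_exact_two_tailed(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums the probabilities (fixed margins) of every table
    whose point probability is <= that of the observed table, with a
    1 + 1e-7 relative guard against floating-point ties (no mid-p).  The
    statistic is the sample odds ratio.  An empty margin makes the test
    undefined; p = 1 is returned with a warning.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    odds = math.inf if b * c == 0 and a * d > 0 else (
        math.nan if b * c == 0 else (a * d) / (b * c)
    )
    if min(r1, r2, c1, b + d) == 0:
        warnings.warn("empty margin: Fisher test undefined, p = 1", stacklevel=2)
        return TestResult(odds, 1.0, "two", "fisher_exact")
    log_p_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    cutoff = log_p_obs + math.log1p(1e-7)
    terms = [
        math.exp(lp)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (lp := _log_hypergeom_pmf(k, r1, r2, c1)) <= cutoff
    ]
    p = min(1.0, math.fsum(terms))
    return TestResult(odds, p, "two", "fisher_exact")


def mann_whitney_two_tailed(x, y) -> TestResult:
    """Two-tailed Mann-Whitney-Wilcoxon U test.

    Exact null distribution when both samples have n <= 8 and there are no
    ties; otherwise the tie-corrected normal approximation (with continuity
    correction), matching standard statistical software.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(x.size, y.size) <= 8 and not has_ties
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), "two",
        f"mann_whitney ({'exact' if exact else 'normal approximation'})",
    )


def _rank(v: np.ndarray) -> np.ndarray:
    return _sps.rankdata(v)  # average ranks for ties


def spearman_correlation(x, y) -> TestResult:
    """Spearman's rho with an exact permutation p for n <= 9.

    rho is the Pearson correlation of the (average-tie) ranks.  For n <= 9
    the p-value enumerates all n! permutations of one rank vector; beyond
    that the usual t approximation is used.  Constant input makes rho
    undefined: NaN is returned, flagged in the method string.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(math.nan, math.nan, "two", "spearman (undefined: constant input)")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        obs = abs(rxc @ ryc)
        perm_matrix = np.array(list(permutations(ryc)))
        dots = np.abs(perm_matrix @ rxc)
        p = float(np.mean(dots >= obs - 1e-9))
        return TestResult(rho, p, "two", "spearman (exact permutation)")
    res = _sps.spearmanr(x, y)
    return TestResult(rho, float(res.pvalue), "two", "spearman (t approximation)")


def chi2_one_tailed(observed: int, total: int, expected_fraction: float) -> TestResult:
    """One-tailed chi-square (1 df) for enrichment above an expected fraction.

    The catalog itself is the trial population: chi2 compares the observed
    split (observed, total - observed) with (f*total, (1-f)*total), no
    continuity correction.  The one-tailed p is half the two-tailed p when
    observed > expected, and 1 minus half otherwise (0.5 at equality).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 < expected_fraction < 1:
        raise ValueError("expected_fraction must be in (0, 1)")
    exp_in = expected_fraction * total
    exp_out = total - exp_in
    chi2 = (observed - exp_in) ** 2 / exp_in + ((total - observed) - exp_out) ** 2 / exp_out
    p_two = float(_sps.chi2.sf(chi2, df=1))
    p = p_two / 2 if observed > exp_in else 1 - p_two / 2
    return TestResult(float(chi2), p, "one", "chi2 enrichment (1 df)")
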