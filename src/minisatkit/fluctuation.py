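"""Luria-Delbruck fluctuation analysis of gross chromosomal rearrangement rates.

In a fluctuation assay, C parallel cultures are grown from small inocula to
a final population Nt and plated under selection; the per-culture counts of
resistant colonies r follow the heavy-tailed Luria-Delbruck distribution.
The rate of events per generation is estimated by the Lea-Coulson method of
the median: the expected number of events per culture m solves

    r0 / m - ln(m) = 1.24

where r0 is the median of r, and the rate is M = m / Nt.  The 95% CI follows
the Rosche-Foster convention used by the FALCOR calculator:

    sigma_ln_m = 1.225 * m**(-0.315) / sqrt(C)
    CI = exp(ln m +/- 1.96 * sigma_ln_m) / Nt

A seeded simulator of the assay (events Poisson-distributed in number, each
founding a clone whose final size is distributed as floor(1/u), u~U(0,1),
capped at Nt) is provided for estimator-recovery testing; it generates the
classic heavy-tailed "jackpot" cultures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import median

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FluctuationExperiment",
    "RateEstimate",
    "LDSimParams",
    "lea_coulson_m",
    "lea_coulson_m_from_median",
    "estimate_rate",
    "fold_change",
    "round_sig",
    "simulate_ld",
    "LEA_COULSON_CONSTANT",
]

#: Constant of the Lea-Coulson median equation r0/m - ln(m) = 1.24.
LEA_COULSON_CONSTANT = 1.24


@dataclass
class FluctuationExperiment:
    """Per-culture resistant counts plus the viable-cell count.

    ``Nt`` may be a single per-experiment value (the assay convention) or a
    per-culture list, which is averaged with a warning.  ``plating_fraction``
    scales Nt when only part of each culture was plated.
    """

    r: list[int]
    Nt: float
    label: str = ""
    plating_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.r) < 1:
            raise ValueError("need at least one culture")
        if len(self.r) < 10:
            warnings.warn(
                f"{self.label or 'experiment'}: only {len(self.r)} cultures; "
                "at least 10 independent cultures are the assay minimum",
                stacklevel=2,
            )
        for v in self.r:
            if v < 0 or int(v) != v:
                raise ValueError("resistant counts must be non-negative integers")
        if np.ndim(self.Nt) > 0:
            warnings.warn("per-culture Nt supplied; using the mean", stacklevel=2)
            self.Nt = float(np.mean(self.Nt))
        if self.Nt <= 0:
            raise ValueError("Nt must be positive")
        if not 0 < self.plating_fraction <= 1:
            raise ValueError("plating_fraction must be in (0, 1]")

    @property
    def C(self) -> int:
        return len(self.r)

    @property
    def effective_Nt(self) -> float:
        return self.Nt * self.plating_fraction


@dataclass(frozen=True)
class RateEstimate:
    """Events per culture (m) and per generation (rate), with 95% CI."""

    m: float
    rate: float
    ci95_low: float
    ci95_high: float
    C: int
    label: str = ""
    no_mutants: bool = False


@dataclass(frozen=True)
class LDSimParams:
    mu: float  # events per cell per generation
    Nt: float  # final cells per culture
    C: int  # number of cultures
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")
        if self.Nt < 1 or self.C < 1:
            raise ValueError("Nt and C must be >= 1")


def lea_coulson_m_from_median(r0: float) -> float:
    """Solve r0/m - ln(m) = 1.24 for m, given the median count r0.

    The median of an even-length list is the midpoint of the two central
    order statistics, so r0 may be fractional.  The left-hand side is
    strictly decreasing in m, so the root is unique; it is bracketed on
    (1e-6, 1e6) and solved to 1e-9 relative tolerance.  r0 = 0 gives m = 0
    ("no mutants observed").
    """
    if r0 < 0:
        raise ValueError("median count must be non-negative")
    if r0 == 0:
        return 0.0

    def f(m: float) -> float:
        return r0 / m - math.log(m) - LEA_COULSON_CONSTANT

    lo, hi = 1e-6, 1e6
    while f(hi) > 0:  # absurdly large medians: extend the bracket
        hi *= 10
    return float(brentq(f, lo, hi, rtol=1e-9))


def lea_coulson_m(r: list[int]) -> float:
    """Lea-Coulson median estimate of m from per-culture resistant counts."""
    for v in r:
        if v < 0 or int(v) != v:
            raise ValueError("resistant counts must be non-negative integers")
    return lea_coulson_m_from_median(float(median(r)))


def _sigma_ln_m(m: float, C: int) -> float:
    return 1.225 * m ** (-0.315) / math.sqrt(C)


def estimate_rate(exp: FluctuationExperiment) -> RateEstimate:
    """Lea-Coulson rate with FALCOR-style 95% confidence interval.

    With zero mutants in every culture the point estimate is 0 and only an
    upper bound is reported, taken from the Poisson zero class across the C
    cultures: m_up = -ln(0.025)/C.
    """
    m = lea_coulson_m(exp.r)
    nt = exp.effective_Nt
    if m == 0:
        m_up = -math.log(0.025) / exp.C
        return RateEstimate(
            m=0.0, rate=0.0, ci95_low=0.0, ci95_high=m_up / nt,
            C=exp.C, label=exp.label, no_mutants=True,
        )
    sigma = _sigma_ln_m(m, exp.C)
    return RateEstimate(
        m=m,
        rate=m / nt,
        ci95_low=math.exp(math.log(m) - 1.96 * sigma) / nt,
        ci95_high=math.exp(math.log(m) + 1.96 * sigma) / nt,
        C=exp.C,
        label=exp.label,
    )


def fold_change(rate_a: float, rate_b: float) -> float:
    """rate_a / rate_b (the induction of condition a over baseline b)."""
    if rate_b <= 0:
        raise ValueError("undefined fold: baseline rate must be positive")
    return rate_a / rate_b


def round_sig(x: float, digits: int = 3) -> float:
    """Round to *digits* significant figures, the convention for reported folds."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def simulate_ld(
    params: LDSimParams, rng: np.random.Generator | None = None
) -> FluctuationExperiment:
    """Simulate one fluctuation experiment.

    Per culture the number of events is Poisson(m = mu*Nt); each event's
    surviving clone size is floor(1/u), u ~ U(0,1) (the Luria-Delbruck
    clone-size law under deterministic exponential growth), capped at Nt.
    Deterministic under a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    m = params.mu * params.Nt
    k = rng.poisson(m, size=params.C)
    total = int(k.sum())
    sizes = np.zeros(0, dtype=np.int64)
    if total:
        u = rng.uniform(size=total)
        sizes = np.minimum(np.floor(1.0 / u), params.Nt).astype(np.int64)
    r = np.zeros(params.C, dtype=np.int64)
    idx = np.repeat(np.arange(params.C), k)
    np.add.at(r, idx, sizes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny C is deliberate in simulations
        return FluctuationExperiment(r=[int(v) for v in r], Nt=params.Nt)
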