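"""Chromosome-arm distribution of minisatellite catalogs.

Minisatellite catalogs (Tandem Repeat Finder-style tables: chromosome,
position, motif size, copy number, GC bias, array length, GC content,
per-window G4 counts) are placed on a normalized chromosome-arm axis with
the centromere at 0 and the telomere at 1, and tested for enrichment in
the terminal 10% / 5% of arms with a one-tailed chi-square (1 df) against
a uniform-along-arm null.  GC-rich means GC content strictly > 50%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stability_stats import TestResult, chi2_one_tailed

__all__ = [
    "ChromosomeArmModel",
    "MinisatelliteRecord",
    "EnrichmentResult",
    "normalized_arm_position",
    "normalized_positions",
    "terminal_enrichment",
    "stratify_by_g4",
    "dedup_catalog",
    "GC_RICH_THRESHOLD",
]

logger = logging.getLogger(__name__)

GC_RICH_THRESHOLD = 0.50  # GC-rich: strictly greater


@dataclass(frozen=True)
class ChromosomeArmModel:
    """One chromosome arm: 1-based inclusive coordinates plus centromere side."""

    chrom: str
    arm: str  # "p" or "q"
    arm_start: int
    arm_end: int
    centromere_side: str  # "start" or "end"

    def __post_init__(self) -> None:
        if self.arm_end <= self.arm_start:
            raise ValueError("arm_end must exceed arm_start")
        if self.centromere_side not in ("start", "end"):
            raise ValueError("centromere_side must be 'start' or 'end'")

    @property
    def length(self) -> int:
        return self.arm_end - self.arm_start + 1

    def contains(self, pos: float) -> bool:
        return self.arm_start <= pos <= self.arm_end

    def normalize(self, pos: float) -> float:
        """0 at the centromeric end, 1 at the telomeric end."""
        cen = self.arm_start if self.centromere_side == "start" else self.arm_end
        return abs(pos - cen) / (self.length - 1)


@dataclass
class MinisatelliteRecord:
    """One catalog row; ``sequence`` and truth fields are optional extras."""

    chrom: str
    start: int
    end: int
    motif_size: int
    copy_number: float
    array_length: int
    gc_content: float
    gc_bias: float = math.nan
    g4_counts: dict = field(default_factory=dict)
    g4_strand: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def gc_rich(self) -> bool:
        return self.gc_content > GC_RICH_THRESHOLD


@dataclass(frozen=True)
class EnrichmentResult:
    fraction: float
    observed: int
    total: int
    expected: float
    chi2: float
    p_one_tailed: float
    log10_p: float  # log-scale p, meaningful when p underflows


def _find_arm(record: MinisatelliteRecord, arms) -> ChromosomeArmModel | None:
    for arm in arms:
        if arm.chrom == record.chrom and arm.contains(record.midpoint):
            return arm
    return None


def normalized_arm_position(record: MinisatelliteRecord, arms) -> float | None:
    """Midpoint position on the 0(CEN)-1(TEL) axis; None if outside all arms."""
    arm = _find_arm(record, arms)
    if arm is None:
        return None
    return arm.normalize(record.midpoint)


def normalized_positions(records, arms) -> tuple[np.ndarray, int]:
    """Vector of normalized positions plus the count of excluded records."""
    vals, excluded = [], 0
    for rec in records:
        x = normalized_arm_position(rec, arms)
        if x is None:
            excluded += 1
        else:
            vals.append(x)
    if excluded:
        logger.info("%d records outside all annotated arms were excluded", excluded)
    return np.asarray(vals), excluded


def terminal_enrichment(records, arms, f: float = 0.10) -> EnrichmentResult:
    """One-tailed chi-square for enrichment in the terminal fraction *f*.

    A record lies in the terminal fraction when its normalized midpoint
    position exceeds 1 - f.  Under the uniform-along-arm null, f*total
    records are expected there.
    """
    xs, _ = normalized_positions(records, arms)
    total = xs.size
    if total == 0:
        raise ValueError("no records fall within the annotated arms")
    observed = int(np.sum(xs > 1 - f))
    res: TestResult = chi2_one_tailed(observed, total, f)
    # log10 of the one-tailed p, robust when sf underflows
    log_sf = _sps.chi2.logsf(res.statistic, df=1)
    expected = f * total
    if observed > expected:
        log10_p = (log_sf - math.log(2)) / math.log(10)
    else:
        log10_p = math.log10(res.p_value) if res.p_value > 0 else -math.inf
    return EnrichmentResult(
        fraction=f,
        observed=observed,
        total=total,
        expected=expected,
        chi2=res.statistic,
        p_one_tailed=res.p_value,
        log10_p=log10_p,
    )


def stratify_by_g4(
    records, arms, min_g4_values=(0, 1, 5, 10, 30), f: float = 0.10, window: int = 30
) -> pd.DataFrame:
    """Terminal-fraction proportion as a function of a minimum G4 count.

    For each threshold t the stratum is the records with at least t
    non-overlapping G4 hits (at the given scan window); the table reports
    the stratum size, its terminal-f proportion, and its mean GC content
    (to check that G4 count does not merely proxy for GC content).  Empty
    strata yield NaN proportions.
    """
    rows = []
    for t in min_g4_values:
        stratum = [r for r in records if r.g4_counts.get(window, 0) >= t]
        xs, _ = normalized_positions(stratum, arms)
        n = xs.size
        prop = float(np.mean(xs > 1 - f)) if n else math.nan
        mean_gc = float(np.mean([r.gc_content for r in stratum])) if stratum else math.nan
        rows.append({"min_g4": t, "n": n, "terminal_proportion": prop, "mean_gc": mean_gc})
    return pd.DataFrame(rows)


def dedup_catalog(records) -> tuple[list, int]:
    """Collapse overlapping duplicate calls of the same repeat.

    Among records on one chromosome whose intervals overlap and that share
    the same motif size, only the one with the longest array is kept
    (leftmost on ties).  Overlapping records with different motif sizes are
    different repeats and are all kept.  Idempotent.  Returns (kept,
    n_removed).
    """
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    kept: list = []
    removed = 0
    clusters: dict[tuple, list] = {}
    # group into overlap chains per (chrom, motif_size)
    for rec in ordered:
        key = (rec.chrom, rec.motif_size)
        chain = clusters.get(key)
        if chain and rec.start <= chain[-1][1]:
            chain[-1] = (chain[-1][0], max(chain[-1][1], rec.end), chain[-1][2] + [rec])
        else:
            clusters.setdefault(key, []).append((rec.start, rec.end, [rec]))
    for chains in clusters.values():
        for _s, _e, members in chains:
            best = max(members, key=lambda r: (r.array_length, -r.start))
            kept.append(best)
            removed += len(members) - 1
    kept.sort(key=lambda r: (r.chrom, r.start, r.end))
    return kept, removed
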