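"""G-quadruplex-forming-sequence scanner for tandem repeats.

A potential G-quadruplex-forming sequence (G4) is defined by four runs
("tracts") of at least three consecutive guanines falling within a 30-nt
window, with every loop between consecutive tracts between 1 and 16 nt.
The 16-nt maximum is the arithmetic consequence of the window: with four
3-G tracts and the three other loops at their 1-nt minimum, the longest
single loop that still fits a 30-nt window is 30 - 4*3 - 2*1 = 16.

Counting is greedy and non-overlapping, left to right: the leftmost set
of ``n_tracts`` consecutive maximal G-runs that satisfies the loop and
window constraints is emitted as a hit, and scanning resumes strictly
after that hit's last tract.  On tandem-repeat inputs this greedy count
equals the maximum-cardinality disjoint selection (interval scheduling
with earliest finishing time), which the test suite verifies against a
brute-force oracle.

Two non-obvious rules, both of which the oracle shares:

* Tracts are *maximal* G-runs: ``GGGGGG`` is one tract of six, never two
  tracts of three (splitting would imply a forbidden 0-nt loop).
* The window test uses the tightest qualifying sub-span — the
  ``tract_min_g``-long suffix of the first tract through the
  ``tract_min_g``-long prefix of the last — so a long flanking G-run
  cannot disqualify an otherwise identical motif.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .motifs import clean_sequence, reverse_complement

__all__ = [
    "G4ScanParams",
    "G4Hit",
    "find_g_runs",
    "scan_g4",
    "count_g4",
    "annotate_catalog",
    "CATALOG_WINDOWS",
]

logger = logging.getLogger(__name__)

#: Window sizes used when annotating minisatellite catalogs.
CATALOG_WINDOWS = (30, 40, 50, 100)

_G_RUN = re.compile(r"G+")


@dataclass(frozen=True)
class G4ScanParams:
    """Scanner rule set.

    Defaults encode the standard search: 4 tracts of >=3 G within a 30-nt
    window, loops 1..16 nt.  ``window_max`` is the only knob normally
    varied (30/40/50/100 for catalog annotation); ``loop_max`` is derived,
    never set directly.
    """

    n_tracts: int = 4
    tract_min_g: int = 3
    window_max: int = 30
    loop_min: int = 1

    def __post_init__(self) -> None:
        if self.n_tracts < 2:
            raise ValueError("n_tracts must be >= 2")
        if self.tract_min_g < 1:
            raise ValueError("tract_min_g must be >= 1")
        floor = self.n_tracts * self.tract_min_g + (self.n_tracts - 1) * self.loop_min
        if self.window_max < floor:
            raise ValueError(
                f"window_max {self.window_max} cannot fit {self.n_tracts} tracts "
                f"of {self.tract_min_g} G with loops >= {self.loop_min}"
            )

    @property
    def loop_max(self) -> int:
        return (
            self.window_max
            - self.n_tracts * self.tract_min_g
            - (self.n_tracts - 1) * self.loop_min
            + self.loop_min
        )


@dataclass(frozen=True)
class G4Hit:
    """One non-overlapping G4 match, 0-based half-open on the scanned strand."""

    start: int
    end: int
    tract_starts: tuple[int, ...]
    tract_lengths: tuple[int, ...]
    strand: str = "given"  # "given" or "reverse_complement"

    @property
    def span(self) -> int:
        return self.end - self.start


def find_g_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """All maximal runs of consecutive G of length >= *min_len*, as (start, length)."""
    s = clean_sequence(seq)
    return [
        (m.start(), m.end() - m.start())
        for m in _G_RUN.finditer(s)
        if m.end() - m.start() >= min_len
    ]


def _window_qualifies(
    runs: list[tuple[int, int]], i: int, params: G4ScanParams
) -> bool:
    """Do the n_tracts consecutive maximal runs starting at index *i* qualify?"""
    n, t = params.n_tracts, params.tract_min_g
    chosen = runs[i : i + n]
    for (s0, l0), (s1, _l1) in zip(chosen, chosen[1:]):
        gap = s1 - (s0 + l0)
        if not params.loop_min <= gap <= params.loop_max:
            return False
    # Tightest qualifying sub-span: suffix of first tract to prefix of last.
    first_s, first_l = chosen[0]
    last_s, _last_l = chosen[-1]
    span = (last_s + t) - (first_s + first_l - t)
    return span <= params.window_max


def scan_g4(seq: str, params: G4ScanParams | None = None) -> list[G4Hit]:
    """Greedy non-overlapping G4 hits on the given strand."""
    params = params or G4ScanParams()
    runs = find_g_runs(seq, params.tract_min_g)
    n = params.n_tracts
    hits: list[G4Hit] = []
    i = 0
    while i + n <= len(runs):
        if _window_qualifies(runs, i, params):
            chosen = runs[i : i + n]
            hits.append(
                G4Hit(
                    start=chosen[0][0],
                    end=chosen[-1][0] + chosen[-1][1],
                    tract_starts=tuple(s for s, _ in chosen),
                    tract_lengths=tuple(l for _, l in chosen),
                )
            )
            # Resume strictly after the hit: a consumed run cannot seed the next.
            i += n
        else:
            i += 1
    return hits


def count_g4(
    seq: str,
    params: G4ScanParams | None = None,
    strand_mode: str = "given",
) -> tuple[int, list[G4Hit]]:
    """Count non-overlapping G4 hits; optionally scan both strands.

    With ``strand_mode="both"`` the reverse complement is scanned
    independently and its hits are reported with coordinates mapped back
    onto the given strand and ``strand="reverse_complement"``.
    """
    params = params or G4ScanParams()
    s = clean_sequence(seq)
    hits = scan_g4(s, params)
    if strand_mode == "both":
        L = len(s)
        for h in scan_g4(reverse_complement(s), params):
            hits.append(
                G4Hit(
                    start=L - h.end,
                    end=L - h.start,
                    tract_starts=tuple(L - (ts + tl) for ts, tl in
                                       zip(reversed(h.tract_starts),
                                           reversed(h.tract_lengths))),
                    tract_lengths=tuple(reversed(h.tract_lengths)),
                    strand="reverse_complement",
                )
            )
    elif strand_mode != "given":
        raise ValueError("strand_mode must be 'given' or 'both'")
    return len(hits), hits


def annotate_catalog(records, windows=CATALOG_WINDOWS, base_params: G4ScanParams | None = None):
    """Annotate minisatellite records with per-window G4 counts and strand.

    Each record must carry its array sequence; records without one are
    skipped with a logged warning.  Counts are totals over both strands;
    ``g4_strand`` is "G" (given/Watson strand only), "C" (reverse
    complement only), "GC" (both) or None.  Counts are non-decreasing in
    window size.  Records are modified in place and returned.
    """
    base = base_params or G4ScanParams()
    for rec in records:
        seq = getattr(rec, "sequence", None)
        if not seq:
            logger.warning("record %s has no sequence; skipped", rec)
            continue
        counts: dict[int, int] = {}
        on_g = on_c = False
        for w in windows:
            p = G4ScanParams(base.n_tracts, base.tract_min_g, w, base.loop_min)
            n, hits = count_g4(seq, p, strand_mode="both")
            counts[w] = n
            on_g = on_g or any(h.strand == "given" for h in hits)
            on_c = on_c or any(h.strand == "reverse_complement" for h in hits)
        rec.g4_counts = counts
        rec.g4_strand = ("GC" if on_g and on_c else "G" if on_g else "C" if on_c else None)
    return records
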