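"""De novo telomere-addition junction analysis.

When a broken chromosome end is healed by telomere addition inside a
minisatellite array, the new telomere typically initiates at a short
homology ("seed") between the array and the yeast telomeric repeat:
a TG, GG or GT dinucleotide suffices, and longer homologies (up to the
6-nt GGGTGG shared by CEB1 and the telomeric sequence) facilitate healing.
This module locates those seeds on a motif, measures motif-telomere
homology, parses array-prefix + telomere-suffix junction reads, estimates
the number of motifs remaining from restriction-fragment sizes, and
searches for high-affinity Cdc13 binding sites.

The yeast telomeric repeat is irregular; the minimal grammar adopted here
is one or more repeats of T followed by 1-3 G (TG1-3) on the G-rich
strand, 5'->3', with partial leading/trailing repeats permitted so that
any substring of a telomeric tract still parses.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

from .motifs import NucleotideMotif, clean_sequence
from .seqcomp import FORWARD_SEEDS

__all__ = [
    "TelomereModel",
    "SeedMap",
    "JunctionRead",
    "is_telomeric",
    "seed_map",
    "longest_common_substring",
    "longest_telomere_homology",
    "annotate_junction",
    "remaining_motifs_from_fragment",
    "find_cdc13_sites",
    "CDC13_CONSENSUS",
    "CDC13_CRITICAL_PREFIX",
    "CEB1_G4_REGION",
]

logger = logging.getLogger(__name__)

#: High-affinity Cdc13 binding site; the first four nucleotides are critical.
CDC13_CONSENSUS = "GTGTGGGTGTG"
CDC13_CRITICAL_PREFIX = "GTGT"

#: G-quadruplex-forming block of the CEB1 motif, 1-based inclusive
#: (the 5' G-rich block GGGGGGAGGGAGGGTGG).  A configuration value: the
#: region is figure-derived, not printed as coordinates.
CEB1_G4_REGION = (1, 17)

# TG1-3 grammar with partial edge repeats: an optional leading run of up
# to 3 G (tail of a repeat), full T G{1,3} repeats, optional trailing T.
_TEL_RE = re.compile(r"G{0,3}(?:TG{1,3})*T?")


@dataclass(frozen=True)
class TelomereModel:
    """Telomeric-repeat constants used to interpret junctions and fragments.

    Mean telomere lengths are 300 bp in wild-type and 400 bp in pif1-delta
    cells; flank_bp is the non-array flanking sequence retained by the
    restriction digest (50 bp for the chromosome V CEB1 construct, 1800 bp
    for the CEB25 construct).
    """

    mean_length_wt: int = 300
    mean_length_pif1: int = 400
    flank_bp: int = 50
    alt_flank_bp: int = 1800


def is_telomeric(seq: str) -> bool:
    """Does the whole string parse under the TG1-3 grammar (partial edges ok)?"""
    s = clean_sequence(seq)
    return bool(s) and _TEL_RE.fullmatch(s) is not None


@dataclass(frozen=True)
class SeedMap:
    """Telomere-seed dinucleotide positions on a motif (0-based starts)."""

    positions: tuple[int, ...]
    g4_region: tuple[int, int] | None = None  # 1-based inclusive
    overlap_fraction: float | None = None


def seed_map(motif: NucleotideMotif, g4_region: tuple[int, int] | None = None) -> SeedMap:
    """All TG/GG/GT start positions; overlap fraction with a G4 region.

    A seed dinucleotide overlaps the region if either of its two
    nucleotides falls inside it (region given 1-based inclusive).
    """
    s = motif.sequence
    if len(s) < 2:
        raise ValueError("motif too short for dinucleotides")
    positions = tuple(i for i in range(len(s) - 1) if s[i : i + 2] in FORWARD_SEEDS)
    overlap = None
    if g4_region is not None and positions:
        lo, hi = g4_region[0] - 1, g4_region[1] - 1  # 0-based inclusive
        n_in = sum(1 for p in positions if p <= hi and p + 1 >= lo)
        overlap = n_in / len(positions)
    return SeedMap(positions, g4_region, overlap)


def longest_common_substring(a: str, b: str) -> tuple[str, int, int]:
    """Longest contiguous substring of both; ties broken leftmost in *a*.

    Returns (substring, start_in_a, start_in_b); ("", -1, -1) when the
    strings share no character.
    """
    best_len, best_a, best_b = 0, -1, -1
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len = cur[j]
                    best_a, best_b = i - cur[j], j - cur[j]
        prev = cur
    if best_len == 0:
        return "", -1, -1
    return a[best_a : best_a + best_len], best_a, best_b


def longest_telomere_homology(
    motif: NucleotideMotif, telomere_example: str
) -> tuple[str, int, int]:
    """Longest substring shared by the motif and a telomeric tract."""
    return longest_common_substring(motif.sequence, clean_sequence(telomere_example))


@dataclass(frozen=True)
class JunctionRead:
    """A parsed array-prefix + telomere-suffix read.

    ``junction_index`` is the end (exclusive) of the maximal motif-templated
    prefix; ``shared_span`` the (start, end) interval of nucleotides that
    simultaneously extend the motif and parse as telomere — empty spans are
    ``(junction_index, junction_index)``.  ``snvs`` lists (position,
    read_base, motif_base) mismatches near the junction.
    """

    sequence: str
    motif_name: str
    junction_index: int
    shared_span: tuple[int, int]
    snvs: tuple[tuple[int, str, str], ...] = ()
    phase: int = 0

    @property
    def shared_length(self) -> int:
        return self.shared_span[1] - self.shared_span[0]


def _periodic(motif: str, phase: int, length: int) -> str:
    reps = (phase + length) // len(motif) + 2
    return (motif * reps)[phase : phase + length]


def annotate_junction(
    read_seq: str,
    motif: NucleotideMotif,
    telomere: TelomereModel | None = None,
    max_snvs: int = 0,
    snv_window: int = 30,
) -> JunctionRead:
    """Locate the motif-telomere junction in a read and its shared span.

    The motif-templated prefix is the longest read prefix matching the
    periodic extension of the motif over any starting phase, tolerating up
    to ``max_snvs`` mismatches but required to end on a matching base.
    Among equally long parses the junction resolves to the rightmost
    motif-templated position.  The suffix from the junction onward must
    parse under the TG1-3 grammar, otherwise the read is rejected.

    The shared span extends leftward from the junction for as long as
    nucleotides both match the motif template and leave a telomere-parsing
    suffix; by suffix-closure of the grammar this region is contiguous.
    """
    s = clean_sequence(read_seq)
    m = motif.sequence
    best_len, best_phase, best_mm = -1, 0, ()
    for phase in range(len(m)):
        tmpl = _periodic(m, phase, len(s))
        mismatches: list[int] = []
        last_match = 0
        for i, (rb, tb) in enumerate(zip(s, tmpl)):
            if rb == tb:
                last_match = i + 1
            else:
                mismatches.append(i)
                if len(mismatches) > max_snvs:
                    break
        # prefix ends on a match; mismatches beyond it do not count
        mm = tuple(p for p in mismatches if p < last_match)
        if last_match > best_len:
            best_len, best_phase, best_mm = last_match, phase, mm
    jm = max(best_len, 0)

    if jm < len(s) and not is_telomeric(s[jm:]):
        raise ValueError("no telomeric suffix")
    if jm == len(s):
        # Read ends inside the array (zero-length telomere): junction at end.
        pass

    mm_set = set(best_mm)
    jt = jm
    while jt > 0 and (jt - 1) not in mm_set and is_telomeric(s[jt - 1 :]):
        jt -= 1
    shared = (jt, jm) if jt < jm else (jm, jm)

    tmpl = _periodic(m, best_phase, jm)
    snvs = tuple(
        (p, s[p], tmpl[p]) for p in sorted(mm_set) if p >= jm - snv_window
    )
    return JunctionRead(
        sequence=s,
        motif_name=motif.name,
        junction_index=jm,
        shared_span=shared,
        snvs=snvs,
        phase=best_phase,
    )


def remaining_motifs_from_fragment(
    fragment_bp: float,
    flank_bp: float,
    telomere_mean_bp: float,
    motif_len_bp: float,
) -> int:
    """Motifs remaining in a healed array, from a restriction-fragment size.

    The fragment contains flanking sequence, the residual array, and the
    (mean-length) telomere, so the estimate is
    (fragment - flank - telomere) / motif length, rounded; negative
    remainders are clamped to 0 with a warning.
    """
    if motif_len_bp <= 0:
        raise ValueError("motif length must be positive")
    remainder = fragment_bp - flank_bp - telomere_mean_bp
    if remainder < 0:
        warnings.warn(
            "fragment smaller than flank + mean telomere; reporting 0 motifs",
            stacklevel=2,
        )
        return 0
    return round(remainder / motif_len_bp)


def find_cdc13_sites(seq: str, mode: str = "exact") -> list[int]:
    """Positions of high-affinity Cdc13 binding sites on the given strand.

    ``exact``: occurrences of the 11-mer consensus GTGTGGGTGTG (overlaps
    allowed).  ``critical_prefix``: positions where the critical GTGT
    begins an 11-nt window with at least 9 of 11 bases in {T, G} — a
    relaxed search for near-consensus sites.
    """
    s = clean_sequence(seq)
    if mode == "exact":
        k = len(CDC13_CONSENSUS)
        return [i for i in range(len(s) - k + 1) if s[i : i + k] == CDC13_CONSENSUS]
    if mode == "critical_prefix":
        k = len(CDC13_CONSENSUS)
        out = []
        for i in range(len(s) - k + 1):
            win = s[i : i + k]
            if win.startswith(CDC13_CRITICAL_PREFIX) and sum(
                ch in "TG" for ch in win
            ) >= 9:
                out.append(i)
        return out
    raise ValueError("mode must be 'exact' or 'critical_prefix'")
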