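"""Strand-composition metrics for minisatellite motifs and arrays.

Three metrics summarize how asymmetric a repeat unit is between its two
strands, which matters because de novo telomere addition seeds on short
TG/GG/GT homologies of the G-rich strand:

* **GC content** — (#G + #C) / L.
* **GC bias** — #G / (#G + #C) on the given strand: 1.0 means every
  G/C base is a G (a maximally G-biased strand).
* **TG/GG/GT dinucleotide bias** — overlapping occurrences of the three
  telomere-seed dinucleotides on the given strand versus on the reverse
  complement (equivalently CA/CC/AC on the given strand).

Counting is linear (no wraparound across the tandem junction); applying
the metrics to a concatenated array via :func:`profile_array` naturally
captures junction-spanning dinucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .motifs import NucleotideMotif, TandemArray, clean_sequence

__all__ = [
    "CompositionProfile",
    "gc_content",
    "gc_bias",
    "count_seed_dinucleotides",
    "dinuc_bias",
    "profile",
    "profile_array",
    "round_percent",
]

FORWARD_SEEDS = ("TG", "GG", "GT")
# The same seeds on the reverse complement, read on the given strand.
REVERSE_SEEDS = ("CA", "CC", "AC")


@dataclass(frozen=True)
class CompositionProfile:
    """All three composition metrics for one sequence.

    Undefined biases (no G or C; no qualifying dinucleotide on either
    strand) are NaN, never 0 or 0.5.
    """

    length: int
    gc_content: float
    gc_bias: float
    dinuc_forward: int
    dinuc_reverse: int
    dinuc_bias: float

    @property
    def gc_content_pct(self) -> int:
        return round_percent(self.gc_content)

    @property
    def gc_bias_pct(self) -> float:
        return round_percent(self.gc_bias) if not math.isnan(self.gc_bias) else math.nan

    @property
    def dinuc_bias_pct(self) -> float:
        return (
            round_percent(self.dinuc_bias)
            if not math.isnan(self.dinuc_bias)
            else math.nan
        )


def round_percent(fraction: float) -> int:
    """Fraction -> nearest integer percent, ties away from zero (76.9% -> 77)."""
    return int(math.floor(fraction * 100.0 + 0.5))


def gc_content(seq: str) -> float:
    s = clean_sequence(seq)
    if not s:
        raise ValueError("empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


def gc_bias(seq: str) -> float:
    s = clean_sequence(seq)
    g, c = s.count("G"), s.count("C")
    if g + c == 0:
        raise ValueError("undefined bias: no G or C")
    return g / (g + c)


def count_seed_dinucleotides(seq: str) -> tuple[int, int]:
    """Overlapping TG/GG/GT counts on the given strand and its reverse complement.

    Returns ``(forward, reverse)`` where *reverse* counts CA/CC/AC on the
    given strand (identical, position for position, to TG/GG/GT on the
    reverse complement).
    """
    s = clean_sequence(seq)
    fwd = rev = 0
    for i in range(len(s) - 1):
        d = s[i : i + 2]
        if d in FORWARD_SEEDS:
            fwd += 1
        elif d in REVERSE_SEEDS:
            rev += 1
    return fwd, rev


def dinuc_bias(seq: str) -> float:
    """forward / (forward + reverse); NaN when neither strand has a seed."""
    fwd, rev = count_seed_dinucleotides(seq)
    if fwd + rev == 0:
        return math.nan
    return fwd / (fwd + rev)


def profile(seq: str) -> CompositionProfile:
    s = clean_sequence(seq)
    if not s:
        raise ValueError("empty sequence")
    g, c = s.count("G"), s.count("C")
    gcb = g / (g + c) if g + c else math.nan
    fwd, rev = count_seed_dinucleotides(s)
    db = fwd / (fwd + rev) if fwd + rev else math.nan
    return CompositionProfile(
        length=len(s),
        gc_content=(g + c) / len(s),
        gc_bias=gcb,
        dinuc_forward=fwd,
        dinuc_reverse=rev,
        dinuc_bias=db,
    )


def profile_motif(motif: NucleotideMotif) -> CompositionProfile:
    return profile(motif.sequence)


def profile_array(array: TandemArray) -> CompositionProfile:
    """Metrics on the full concatenated (or variant) array sequence."""
    return profile(array.sequence)
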