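"""Nucleotide motifs and tandem arrays.

Minisatellites are tandem DNA repeats with a unit ("motif") length of
10-100 nt.  All sequence-level operations in this package act on a
:class:`NucleotideMotif` (the consensus repeat unit, given on its G-rich
strand by convention) or a :class:`TandemArray` (the motif concatenated
``copies`` times, possibly carrying variants).

The three human subtelomeric minisatellite motifs studied throughout the
package (CEB1, CEB25 and the HRAS1 promoter minisatellite) are provided
as module constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "NucleotideMotif",
    "TandemArray",
    "clean_sequence",
    "reverse_complement",
    "CEB1",
    "CEB25",
    "HRAS1",
    "MOTIFS",
]

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def clean_sequence(seq: str) -> str:
    """Uppercase *seq* and verify it is a strict A/C/G/T string.

    Ambiguity codes (including N) are rejected: every metric downstream is
    an exact count and has no sensible behaviour on ambiguous bases.
    """
    s = seq.upper()
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideMotif:
    """A repeat-unit sequence, by convention the G-rich strand, 5'->3'."""

    name: str
    sequence: str
    strand_label: str = "G"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))
        if not self.sequence:
            raise ValueError("empty sequence")
        if not 10 <= len(self.sequence) <= 100:
            warnings.warn(
                f"motif {self.name!r} has length {len(self.sequence)} outside "
                "the minisatellite range 10-100 nt",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "NucleotideMotif":
        label = "C" if self.strand_label == "G" else "G"
        return NucleotideMotif(self.name, reverse_complement(self.sequence), label)


@dataclass(frozen=True)
class TandemArray:
    """A minisatellite array: motif x copies in a chromosomal orientation.

    Orientation "G" means the G-rich strand of the motif is co-oriented
    with the G-rich 3' overhang of the distal telomere; orientation "C" is
    the reverse complement.  An explicit ``sequence`` may be supplied for
    arrays carrying variants (point mutations, motif loss); otherwise the
    sequence is the exact concatenation.
    """

    motif: NucleotideMotif
    copies: int
    orientation: str = "G"
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be a positive integer")
        if self.orientation not in ("G", "C"):
            raise ValueError("orientation must be 'G' or 'C'")
        if not self.sequence:
            seq = self.motif.sequence * self.copies
            if self.orientation == "C":
                seq = reverse_complement(seq)
            object.__setattr__(self, "sequence", seq)
        else:
            object.__setattr__(self, "sequence", clean_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


# The three minisatellite consensus motifs (G-rich strand, 5'->3').
CEB1 = NucleotideMotif("CEB1", "GGGGGGAGGGAGGGTGGCCTGCGGAGGTCCCTGGGCTGA")
CEB25 = NucleotideMotif(
    "CEB25", "AAGGGTGGGTGTAAGTGTGGGTGGGTGTGAGTGTGGGTGTGGAGGTAGATGT"
)
HRAS1 = NucleotideMotif("HRAS1", "CCCCTGGAGAGAAGGGGGAGTGTGGCGT")

MOTIFS = {m.name: m for m in (CEB1, CEB25, HRAS1)}
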