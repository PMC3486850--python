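"""Parsing minisatellite-telomere junction reads.

A healed chromosome end reads as: array prefix + telomeric TG1-3 suffix.
The parser finds the junction (end of the maximal motif-templated prefix)
and the shared span - nucleotides that both continue the motif and parse
as telomere, i.e. the homology that seeded the addition.
"""

from minisatkit import CEB1, TandemArray
from minisatkit.junctions import (
    CEB1_G4_REGION,
    annotate_junction,
    find_cdc13_sites,
    longest_telomere_homology,
    remaining_motifs_from_fragment,
    seed_map,
)
from minisatkit import CEB25

sm = seed_map(CEB1, g4_region=CEB1_G4_REGION)
print(f"CEB1 carries {len(sm.positions)} TG/GG/GT seeds; "
      f"{sm.overlap_fraction:.0%} overlap its G4-forming block (nt 1-17)")

sub, pos, _ = longest_telomere_homology(CEB1, "TGTGGGTGGTGTGGG")
print(f"longest CEB1-telomere homology: {sub} ({len(sub)} nt, motif position {pos + 1})")

read = TandemArray(CEB1, 5).sequence[: 39 + 17] + "TGTGGTGGGTGGTG"
jr = annotate_junction(read, CEB1)
print(f"\njunction read of {len(read)} nt: junction at {jr.junction_index} "
      f"(motif position {jr.junction_index % 39}), shared span {jr.shared_span} "
      f"({jr.shared_length} nt shared)")

n = remaining_motifs_from_fragment(1375, flank_bp=50, telomere_mean_bp=350, motif_len_bp=39)
print(f"\na 1375-bp restriction fragment (50-bp flank, ~350-bp telomere) "
      f"implies ~{n} residual motifs")

print(f"\nCdc13 consensus sites in the CEB25 motif: "
      f"exact {find_cdc13_sites(CEB25.sequence)}, "
      f"near-consensus {find_cdc13_sites(CEB25.sequence, 'critical_prefix')}")
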