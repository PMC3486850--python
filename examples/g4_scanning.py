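"""Non-overlapping G-quadruplex-forming sequences in tandem arrays.

The scanner looks for 4 maximal G-runs of >= 3 G within a 30-nt window
(loops 1-16 nt) and counts greedily without overlap.  On tandem repeats
the count grows with copy number: CEB25 carries one complete G4 motif per
repeat unit, while CEB1's G4 motif spans the junction between two units,
so a k-copy CEB1 array yields k-1 hits.
"""

from minisatkit import CEB1, CEB25, HRAS1, TandemArray
from minisatkit.g4scan import count_g4

for motif in (HRAS1, CEB1, CEB25):
    counts = [count_g4(TandemArray(motif, k).sequence)[0] for k in (1, 2, 3, 5)]
    print(f"{motif.name:8} copies 1,2,3,5 -> G4 counts {counts}")

_, hits = count_g4(TandemArray(CEB1, 2).sequence)
h = hits[0]
print(
    f"\nthe single CEB1-dimer hit spans positions {h.start}-{h.end} "
    f"(the 39-nt unit boundary), with G-tracts at {h.tract_starts}"
)
print(
    "\nHRAS1 stays at zero (a single G-run cannot form a quadruplex), which\n"
    "matches its purely G4-independent fragility."
)
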