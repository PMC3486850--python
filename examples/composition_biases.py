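"""Strand-composition biases of the three human subtelomeric minisatellites.

GC content measures overall base composition; GC bias (G/(G+C) on the
G-rich strand) and the TG/GG/GT dinucleotide bias measure how strongly
the telomere-seed potential is concentrated on one strand.
"""

from minisatkit import CEB1, CEB25, HRAS1
from minisatkit.seqcomp import profile

print(f"{'motif':8} {'len':>4} {'GC%':>4} {'GCbias%':>8} {'TG/GG/GT%':>10}")
for motif in (CEB1, CEB25, HRAS1):
    p = profile(motif.sequence)
    print(
        f"{motif.name:8} {p.length:>4} {p.gc_content_pct:>4} "
        f"{p.gc_bias_pct:>8} {p.dinuc_bias_pct:>10}"
    )

print()
print(
    "CEB25 is perfectly strand-asymmetric (all its G/C bases are G and every\n"
    "seed dinucleotide sits on the G-rich strand); CEB1 is strongly but not\n"
    "completely biased. These asymmetries set how often de novo telomere\n"
    "addition can initiate on the strand facing the distal telomere."
)
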