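"""Terminal enrichment of a minisatellite catalog along chromosome arms.

A synthetic catalog with a known linear terminal bias is generated, placed
on the normalized 0(CEN)-1(TEL) arm axis, and tested for enrichment in the
terminal 10% and 5% with the one-tailed chi-square; the G4-count strata
show how enrichment tracks G-quadruplex potential when the generator
couples the two.
"""

from minisatkit.genome_dist import stratify_by_g4, terminal_enrichment
from minisatkit.synthetic import (
    CatalogGenSpec,
    default_arms,
    gen_catalog,
    terminal_fraction_expected,
)

arms = default_arms()
beta = 6.0
recs = gen_catalog(
    CatalogGenSpec(n_records=5000, arms=tuple(arms), terminal_bias_beta=beta, seed=11)
)

for f in (0.10, 0.05):
    res = terminal_enrichment(recs, arms, f=f)
    print(
        f"terminal {f:.0%}: {res.observed}/{res.total} observed "
        f"(expected {res.expected:.0f} under uniform), chi2 = {res.chi2:.1f}, "
        f"one-tailed p = {res.p_one_tailed:.2e}"
    )
print(f"analytic terminal-10% mass at beta={beta:g}: "
      f"{terminal_fraction_expected(beta, 0.10):.3f}")

# a second catalog whose terminal bias grows with G4 count
coupled = gen_catalog(
    CatalogGenSpec(n_records=20_000, arms=tuple(arms), terminal_bias_beta=0.0,
                   g4_terminal_coupling=4.0, gc_rich_weight=0.5, seed=12)
)
print("\nterminal-10% proportion by minimum G4 count (G4-coupled catalog):")
print(stratify_by_g4(coupled, arms, min_g4_values=(0, 1, 3), f=0.10).to_string(index=False))
print("\nthe proportion rises with the G4 threshold while mean GC content of "
      "the strata stays flat: terminal clustering tracks G-quadruplex "
      "potential, not base composition alone.")
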