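"""Molecular variance partition (AMOVA) over the seven panel groups.

PhiPT is the dominant-data analogue of Fst: the share of band variation
that lies among groups rather than among genotypes within groups.
"""

from bandpop.amova import amova
from bandpop.simulate import PanelSpec, simulate_panel

bm, popmap, _ = simulate_panel(PanelSpec(), seed=1)
table = amova(bm, popmap, n_perm=999, seed=2)

print(table.to_dataframe().round(3).to_string(index=False))
print(f"\nPhiPT = {table.phipt:.3f}  "
      f"(p = {table.p_value:.4f}, {table.n_permutations} permutations)")
print(f"{table.percent_among:.0f}% of variation among groups, "
      f"{table.percent_within:.0f}% within groups")
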