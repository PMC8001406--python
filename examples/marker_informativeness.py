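"""Score every primer's discriminatory capacity (PIC, EMR, MI, D, R).

High MI identifies the primers worth keeping in a fingerprinting panel;
D is the probability two random genotypes differ at the primer.
"""

from bandpop.informativeness import informativeness_table
from bandpop.simulate import PanelSpec, simulate_panel

bm, _, _ = simulate_panel(PanelSpec(), seed=1)
table = informativeness_table(bm)

primers = table[table.primer != "Mean"]
best = primers.sort_values("MI", ascending=False).head(3)
print("three most informative primers by marker index (MI = PIC x EMR):")
print(best[["primer", "marker_class", "PIC", "EMR", "MI", "D", "R"]]
      .round(2).to_string(index=False))
print("\nper-class means:")
print(table[table.primer == "Mean"].round(2).to_string(index=False))
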