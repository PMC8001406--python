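"""Within-group diversity: PL%, Na, Ne, He and Shannon's I per group.

He and I use the square-root dominant-marker allele-frequency estimator;
higher values flag more variable germplasm groups.
"""

from bandpop.diversity import diversity_table
from bandpop.simulate import PanelSpec, simulate_panel

bm, popmap, _ = simulate_panel(PanelSpec(), seed=1)
table = diversity_table(bm, popmap)

one_class = table[table.marker_class == "EST-SSR"]
print("diversity per group (EST-SSR class):")
print(one_class.round(2).to_string(index=False))
# PL is the % of bands segregating inside the group; Ne <= 2 per band by
# construction; the Mean row is the unweighted across-group average.
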