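"""Jaccard distances, a bootstrapped NJ tree and PCoA of the panel.

The tree and the ordination should both separate the planted gene
pools; bootstrap supports say how stable each split is under band
resampling.
"""

from bandpop.distances import jaccard_distance
from bandpop.ordination import pcoa
from bandpop.simulate import PanelSpec, simulate_panel
from bandpop.trees import bootstrap_support, nj_tree

bm, popmap, _ = simulate_panel(PanelSpec(), seed=1)
dm = jaccard_distance(bm)

tree = bootstrap_support(bm, nj_tree, n_reps=100, seed=2)
supports = sorted((n.support for n in tree.non_tips(include_self=False)),
                  reverse=True)
print(f"NJ tree on {bm.n_genotypes} genotypes; "
      f"top bipartition supports (%): {[round(s) for s in supports[:5]]}")

ordn = pcoa(dm)
print(f"PCoA: first two axes explain "
      f"{ordn.percent_explained[0]:.1f}% + {ordn.percent_explained[1]:.1f}% "
      f"= {ordn.percent_explained[:2].sum():.1f}% of the variation")
print("first coordinates:")
print(ordn.coordinates.iloc[:4, :2].round(3))
# Genotypes from the same gene pool should share a side of axis 1.
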