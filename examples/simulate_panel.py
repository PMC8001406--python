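"""Simulate a study-scale band panel and describe what it contains.

The generator draws 70 genotypes in 7 groups fingerprinted with 26
primer pairs under a three-gene-pool admixture model, plus three
correlated leaf-biochemistry traits with a few planted marker effects.
"""

from bandpop.simulate import PanelSpec, simulate_panel, simulate_traits

bm, popmap, truth = simulate_panel(PanelSpec(), seed=1)
traits, planted = simulate_traits(bm, popmap, seed=2)

print(f"panel: {bm.n_genotypes} genotypes x {bm.n_bands} bands "
      f"from {len(bm.primers)} primers")
print(f"groups: {', '.join(f'{g} (n={len(popmap.genotypes_in(g))})' for g in popmap.groups)}")
print(f"true admixture sharpness (mean max membership): "
      f"{truth.admixture.max(axis=1).mean():.3f}")
print("planted marker->trait effects (standardized beta):")
for (band, trait), beta in planted.items():
    print(f"  {band} -> {trait}: {beta:+.3f}")
print("\ntrait means by group (first rows):")
print(traits.genotype_means().head(3).round(2))
# The printed betas are the ground truth the association example tries
# to rediscover from the data alone.
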