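"""Bayesian admixture clustering with second-order (Evanno) selection
of the number of gene pools K.

Each K gets several independent Gibbs runs; DeltaK peaks at the K whose
addition changes the model likelihood most sharply relative to the
run-to-run spread.  Desk-scale chain lengths keep this quick.
"""

from bandpop.admixture import best_k, evanno_delta_k, fit_admixture
from bandpop.simulate import PanelSpec, simulate_panel

bm, popmap, truth = simulate_panel(PanelSpec(), seed=1)

lnl = {}
for k in range(1, 6):
    lnl[k] = [fit_admixture(bm, k, burnin=300, iterations=500,
                            seed=100 * k + r).mean_log_likelihood
              for r in range(3)]

table = evanno_delta_k(lnl)
print(table.round(2).to_string(index=False))
k_hat = best_k(table)
print(f"\nselected K = {k_hat} (simulated truth: 3 gene pools)")

res = fit_admixture(bm, k_hat, burnin=500, iterations=1000, seed=7)
print("\nposterior-mean memberships of the first genotypes:")
print(res.q_dataframe().head(5).round(3))
# Rows sum to 1; a row like (0.9, 0.05, 0.05) is a firmly assigned
# genotype, values nearer 1/K indicate admixture.
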