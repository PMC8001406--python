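# Methods

`bandpop` analyses dominant (presence/absence) marker data of the kind
produced by SSR and EST-PCR fingerprinting of polyploid germplasm, where
heterozygote dosage is unreadable from gels and every band is scored 0/1.
This note records the models, the conventions, and the choices made where
the design was genuinely open.

## Data model

A **band matrix** is genotypes x bands with entries in {0, 1, missing};
every band belongs to exactly one primer pair, identified by splitting the
band id on its last underscore (`VCC_K4_6` = band 6 of primer `VCC_K4`).
Missing scores (failed amplification) are allowed on input; every analysis
uses pairwise-complete denominators (a missing score removes that genotype
from that band's count only), and pattern-level statistics drop genotypes
with an incomplete pattern at the primer in question. No imputation is
performed by default.

## Synthetic panels

The generator stands in for a real 70-genotype panel: seven groups of
sizes 10/10/8/8/6/11/17 (four provincial wild-clone collections, a
cultivar group, two hybrid crosses), 26 primer pairs in three marker
classes (10 EST-SSR, 8 genomic SSR, 8 EST-PCR), each producing a uniform
2-8 bands.

Band presence follows the admixture model the inference fits:

* ancestral frequency per band `p̄ ~ Uniform(0.1, 0.9)`;
* cluster frequency `p_kl ~ Beta(p̄(1-F)/F, (1-p̄)(1-F)/F)` — a
  Balding-Nichols-style divergence with spread `F` (default 0.4, strong
  but realistic differentiation);
* membership `q_i ~ Dirichlet(alpha + e_c)` where `e_c` is the indicator
  of the genotype's group cluster and `alpha` (default 0.05) controls
  admixture: `alpha -> 0` gives hard assignment, `alpha -> inf` erases
  group structure;
* presence `x_il ~ Bernoulli(sum_k q_ik p_kl)`; a tetraploid-dominant
  variant (`1 - (1 - a)^4`) is available behind a flag for robustness
  checks.

The default group-to-cluster mapping assigns the two eastern wild
provinces, the remaining wild provinces plus cultivars, and the two hybrid
crosses to three gene pools of 20/22/28 genotypes. Comparable pool sizes
matter: with one dominant pool the first likelihood split swamps the
second-order model-selection statistic and the number of clusters becomes
unidentifiable in practice (see "Model selection" below).

**Traits.** Three leaf-biochemistry traits (TAA, TPC in mg GAE/g fresh
leaf; TFC in mg CE/g fresh leaf) are drawn per genotype as group mean +
planted marker effects + correlated Gaussian residual, with three
replicates of absolute measurement noise (defaults 0.06/0.01/0.05) and a
small positive floor. Planted effects are (band, trait, standardized
beta) triples acting on the standardized band score in units of the
group SD; the defaults plant a strong flavonoid allele whose copy also
raises phenolics, a negative antioxidant allele and a modest independent
phenolic allele. The residual copula is *calibrated*: overall
trait-trait covariance decomposes into the between-group part (fixed by
the group means), the planted-genetic part (shared alleles only) and the
copula part, and the copula correlation is solved so the OVERALL
genotype-level Pearson correlations land on the targets
(TAA-TPC 0.352, TAA-TFC 0.387, TPC-TFC 0.826). A pair whose target is
unreachable given the planted effects is clipped to the nearest valid
correlation; with the default effects the TAA-TFC pair realizes ~0.30
rather than 0.387, the other two pairs land on target.

What the generator does **not** emulate: linkage between bands, allele
dosage, pedigree structure of the crosses, genotyping error, and any
correlation between a band's frequency and its informativeness class.
Passing recovery tests therefore demonstrate correctness of the
estimators under the fitted model, not robustness to those violations.

## Marker informativeness

Per primer: band frequency `p_b` = fraction of scored genotypes showing
the band; a band is polymorphic when `0 < p_b < 1` (no minor-frequency
threshold). EMR = `n_p^2 / n`; MI = PIC x EMR; resolving power
R = `sum_b 1 - 2|0.5 - p_b|`; discrimination power D treats the primer's
full multiband pattern: with pattern counts `k_i` over `N` genotypes,
`D = 1 - sum_i (k_i/N)(k_i - 1)/(N - 1)`, the exact probability that a
random unordered pair differs.

PIC for dominant data has no single accepted formula, so two conventions
ship: the default `mean-band-2pq` (mean over bands of `2p(1-p)`, bounded
by 0.5) and `pattern-heterozygosity` (`1 - sum p_i^2` over pattern
frequencies, which can approach 1 for a primer resolving many patterns
and is the only way published per-primer PIC values above 0.5 can arise
from binary scores). Reports carry the convention used.

## Population diversity

Per group and marker class: PL% (share of bands segregating in the
group), Na (mean observed bands per primer — a per-primer count, since
published group values far exceed 2), Ne, He, Shannon's I. Allele
frequencies come from band frequency under two models: `diploid-sqrt`
(default; `q = sqrt(1 - p_band)`, the standard dominant-data treatment)
or `band-as-allele` (band frequency used directly). Per band,
`He = 2pq`, `I = -p ln p - q ln q`, `Ne = 1/(p^2 + q^2)`; group values
are unweighted means over all bands, so a fixed band contributes
He = I = 0 and Ne = 1 (including fixed bands keeps the published-style
"effective alleles" interpretation coherent). Groups of one genotype are
reported but flagged low-confidence.

## Distances, trees, ordination

Jaccard dissimilarity ignores joint absences (uninformative for dominant
bands); a pair sharing no informative band gets distance 0 with a
warning. Trait distances are Euclidean on z-scores (n-1 SD), making them
scale-free. NJ is the Saitou-Nei Q-criterion agglomeration, written
out so ties break deterministically on the lowest pair index and negative
branch estimates truncate to zero with a warning; UPGMA is average
linkage (scipy), with a cut utility for flat groupings. Bootstrap
supports resample band columns with replacement and report bipartition
frequencies on the point tree; the desk-scale default is 1,000 replicates
(hundreds of times fewer than a production run, adequate for
well-separated groups). PCoA double-centers `-D^2/2`; negative
eigenvalues (non-Euclidean input) are reported but excluded from both
coordinates and the percent-variance denominator. PCA works on the trait
correlation matrix and equals PCoA of the standardized-Euclidean
distances up to sign (a tested identity).

## AMOVA

Two-level partition (among/within groups) on squared Euclidean 0/1
distances, i.e. band mismatch counts — the dominant-data convention,
chosen over Jaccard because the variance algebra assumes squared
distances. Variance components come from the expected mean squares with
`n0 = (N - sum N_g^2/N)/(G-1)`; a negative among-group component
truncates to 0. PhiPT = among/(among+within); its p-value is the share
of group-label permutations (observed configuration included, default
999 permutations) reaching the observed PhiPT. Exact invariance of
PhiPT under dataset duplication does not hold for this moment estimator
(the within df changes), only asymptotically.

## Admixture inference

Bands are independent Bernoulli loci: `x_il ~ Bern(sum_k q_ik p_kl)`.
This deliberately drops the genotypic (recessive-allele) machinery of
codominant clustering programs — dominant 0/1 scores cannot support it.
A Gibbs sampler alternates latent band origins `z_il`, cluster
frequencies `p_kl ~ Beta(1 + n1, 1 + n0)` and memberships
`q_i ~ Dirichlet(alpha + counts)` with `alpha` fixed at 1.0 (inferring
alpha is out of scope). Point estimates are posterior means; note these
are *shrunk*: on sharply structured panels the mean max-membership sits
near 0.82-0.85 even when hard assignments are essentially perfect
(adjusted Rand >= 0.9 against truth). Desk-scale defaults are 2,000
burn-in + 2,000 kept sweeps (a few seconds at 70 x 130); production-scale
values are parameters.

### Model selection

`ln P(X|K)` is approximated by the posterior-mean log-likelihood, and the
Evanno second-order statistic `DeltaK = |L''(K)| / sd(L(K))` is computed
over >= 3 replicate runs per K on a contiguous K range. Two caveats
found while validating:

* the mean-minus-half-variance evidence correction and the plug-in
  likelihood at the posterior mean were both tried and are *noisier*
  selectors here; the posterior-mean log-likelihood stays the default;
* the replicate SD in the denominator is Monte-Carlo error, which is
  systematically smaller at under-fitted K (faster mixing). On ~10-30%
  of simulated panels this inflates DeltaK at K-1 enough to select one
  cluster too few. Longer chains help but do not eliminate it. This is
  a known fragility of the DeltaK heuristic, not of the sampler.

Replicate runs are aligned for reporting by an optimal assignment on
Q-column correlations.

## Association statistics

The Mantel statistic is the Pearson correlation over the off-diagonal
pairs, with rows+columns of the second matrix permuted jointly (999
permutations default, upper tail default for positive-association
hypotheses). Kruskal-Wallis (tie-corrected, all-identical data returns
H = 0, p = 1) and one-way ANOVA with Tukey HSD serve the group
comparisons; letter displays use the insert-and-absorb algorithm, so
groups sharing a letter are not significantly different.

Stepwise marker-trait regression follows the SPSS probability-of-F
convention: enter the candidate allele with the smallest partial-F
p-value while p <= 0.045, then remove any included allele with
p >= 0.099, until stable; `p_enter < p_remove` is enforced against
cycling. Each step reports R, R^2, the R^2 and F change at entry, and
both the at-entry and final-model standardized beta/t/p (published
stepwise tables are ambiguous about which they show; both are emitted).
Two properties a user should know:

* screening ~130 candidate alleles at a fixed per-test 0.045 threshold
  virtually guarantees several false selections under a global null —
  the expected null selection count is ~7 alleles, not zero; SMRA is a
  screening tool, not an error-controlled test;
* traits whose between-group variance is dominated by one group (TFC
  here) let group-indicator bands outcompete genuine within-group
  effects; planted-effect recovery is demonstrated on the trait with the
  mildest group structure.

## Assay arithmetic

DPPH percent inhibition is `100 (A_blank - A_extract)/A_blank` (values
outside [0, 100] are reported and flagged). Standard curves are OLS
lines over >= 3 calibration points; conversion to mg equivalents per g
fresh leaf is `(A - b)/m x dilution x volume / (1000 x mass)` with the
defaults 3 mL pooled extract from 0.5 g leaf; readings mapping outside
the calibrated range are flagged, not rejected.

## Pipeline and reproducibility

`pipeline.run_all` executes all stages into an output directory with a
manifest; every stage seed is SHA-256-derived from the master seed and
the stage name, so independent streams are reproducible and a rerun is
byte-identical. Stage failures are logged and recorded as partial
completion rather than aborting the bundle.

## Numerical notes

* Permutation p-values always include the observed configuration:
  p in [1/(n_perm + 1), 1].
* Gibbs categorical sampling uses inverse-CDF on per-entry cumulative
  sums; likelihoods are clipped away from 0/1 by 1e-12.
* The copula calibration projects any infeasible correlation matrix to
  the nearest valid one by eigenvalue clipping.
* CSV distance output carries 6 decimals; round-trips are lossless at
  that precision.

## Known limitations

Only the two-level AMOVA design is implemented (no deeper nesting, no
pairwise group PhiPT matrices). The admixture model has no linkage or
correlated-frequencies prior. No multiple-testing correction is applied
across traits in SMRA, by design. Tetraploid allele dosage is not
estimated anywhere; the square-root frequency estimator assumes
disomic inheritance and is one documented convention among two.
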