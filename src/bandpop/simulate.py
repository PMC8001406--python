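"""Synthetic band panels and trait tables with known truth.

The generator emulates a germplasm panel of 70 blueberry genotypes in
seven groups (wild clones from four provinces, a cultivar group and two
hybrid crosses) fingerprinted with 26 primer pairs in three marker
classes, each primer producing several dominant 0/1 bands.

Band presence follows an admixture model: each latent cluster ``k`` has a
band frequency ``p_kl`` drawn from a Balding-Nichols-style Beta
distribution around an ancestral frequency, with spread controlled by a
divergence parameter ``F``; each genotype has membership proportions
``q_i`` drawn from a Dirichlet centred on its group's cluster; band
presence is Bernoulli(sum_k q_ik p_kl).  This is exactly the model the
admixture module fits, enabling parameter-recovery tests with recorded
truth.  A tetraploid-dominant variant (presence = 1 - (1 - a)^4 over the
mixed allele frequency a) is available for robustness checks.

Traits are generated as group mean + planted band effects + correlated
Gaussian noise hitting a target trait-trait correlation matrix, with
replicate-level measurement noise on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import BandMatrix, PopulationMap, TraitTable

__all__ = [
    "PanelSpec",
    "TraitSpec",
    "PanelTruth",
    "simulate_panel",
    "simulate_traits",
    "worked_fixture",
    "DEFAULT_PRIMER_CLASSES",
]

# 26 primer pairs in the three marker classes used for blueberry
# fingerprinting (10 EST-SSR, 8 genomic SSR, 8 EST-PCR).
DEFAULT_PRIMER_CLASSES: dict[str, str] = {
    **{p: "EST-SSR" for p in (
        "CA23", "CA112", "CA169", "CA236", "CA421",
        "CA483", "CA787", "NA800", "NA961", "NA1040")},
    **{p: "G-SSR" for p in (
        "VCC_B3", "VCC_I2", "VCC_I8", "VCC_J1",
        "VCC_J3", "VCC_J9", "VCC_K4", "VCC_S10")},
    **{p: "EST-PCR" for p in (
        "CA21", "CA54", "CA227", "CA287",
        "CA791", "CA1029", "CA1423", "NA27")},
}

# Group means and SDs (TAA, TPC in mg GAE/g fl; TFC in mg CE/g fl) for the
# seven panel groups, as observed in the real germplasm.
DEFAULT_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "TAA": {
        "NL": (3.94, 1.02), "PE": (3.34, 1.36), "QC": (3.35, 1.64),
        "NB": (4.29, 1.06), "CV": (4.23, 1.10), "Cross1": (2.55, 1.28),
        "Cross2": (4.08, 0.89),
    },
    "TPC": {
        "NL": (0.16, 0.05), "PE": (0.12, 0.02), "QC": (0.09, 0.04),
        "NB": (0.11, 0.02), "CV": (0.13, 0.03), "Cross1": (0.11, 0.03),
        "Cross2": (0.10, 0.01),
    },
    "TFC": {
        "NL": (5.26, 2.49), "PE": (2.14, 0.79), "QC": (1.88, 1.59),
        "NB": (1.74, 0.46), "CV": (1.84, 0.84), "Cross1": (1.39, 0.18),
        "Cross2": (1.41, 0.29),
    },
}

TRAIT_ORDER = ("TAA", "TPC", "TFC")

# Target Pearson correlations among genotype-level traits.
DEFAULT_TRAIT_CORR = np.array([
    [1.000, 0.352, 0.387],   # TAA
    [0.352, 1.000, 0.826],   # TPC
    [0.387, 0.826, 1.000],   # TFC
])

# Marker->trait effects planted by default: the strongest associations the
# panel is meant to exhibit - a large flavonoid effect whose allele also
# raises phenolics (phenolic pathways overlap), a negative antioxidant
# effect and a modest independent phenolic effect.  Band "_1" of a primer
# always exists, whatever the sampled band count.
DEFAULT_PLANTED_EFFECTS: list[tuple[str, str, float]] = [
    ("VCC_K4_1", "TFC", 0.8),
    ("VCC_K4_1", "TPC", 0.585),
    ("VCC_S10_1", "TAA", -0.49),
    ("CA1423_1", "TPC", 0.28),
]

# Replicate-to-replicate assay noise (absolute SD per trait).
DEFAULT_REPLICATE_SD = {"TAA": 0.06, "TPC": 0.01, "TFC": 0.05}


@dataclass
class PanelSpec:
    """Study conditions for the simulated marker panel.

    Defaults are the panel the analyses assume: 70 genotypes split
    10/10/8/8/6/11/17 over seven groups, 26 primers producing 2-8 bands
    each, three latent clusters with divergence ``divergence_f`` = 0.4 and
    admixture concentration ``alpha`` = 0.05 (sharp but not degenerate
    memberships).
    """

    group_sizes: tuple[int, ...] = (10, 10, 8, 8, 6, 11, 17)
    group_names: tuple[str, ...] = ("NL", "PE", "QC", "NB", "CV", "Cross1", "Cross2")
    primer_classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PRIMER_CLASSES))
    bands_per_primer: tuple[int, int] = (2, 8)
    n_clusters: int = 3
    # latent cluster of each group: the two eastern wild provinces form
    # one gene pool, the remaining wild provinces plus the cultivars a
    # second, the two hybrid crosses a third; this keeps the three pools
    # comparably represented (20/22/28 genotypes)
    group_clusters: tuple[int, ...] = (0, 0, 1, 1, 1, 2, 2)
    divergence_f: float = 0.4
    alpha: float = 0.05
    tetraploid_dominance: bool = False

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_names):
            raise ValueError("group_sizes and group_names lengths differ")
        if len(self.group_clusters) != len(self.group_names):
            raise ValueError("group_clusters and group_names lengths differ")
        if any(s <= 0 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if not (0.0 < self.divergence_f < 1.0):
            raise ValueError("divergence_f must be in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if max(self.group_clusters) >= self.n_clusters:
            raise ValueError("group_clusters refers to a cluster >= n_clusters")
        if self.n_clusters == 1:
            warnings.warn(
                "n_clusters=1: no structure to recover; downstream "
                "recovery tests are degenerate", stacklevel=2)


@dataclass
class PanelTruth:
    """Generating parameters recorded alongside a simulated panel."""

    cluster_freqs: np.ndarray      # (K, n_bands) band frequency per cluster
    admixture: np.ndarray          # (N, K) true membership proportions
    ancestral_freqs: np.ndarray    # (n_bands,)
    group_clusters: dict[str, int]

    @property
    def hard_labels(self) -> np.ndarray:
        """Most-probable cluster per genotype."""
        return self.admixture.argmax(axis=1)


def simulate_panel(
    spec: PanelSpec, seed: int | np.random.Generator = 0
) -> tuple[BandMatrix, PopulationMap, PanelTruth]:
    """Draw a band matrix, population map and the generating truth.

    Pure function of ``(spec, seed)``: the same seed reproduces the same
    matrix byte for byte.
    """
    rng = np.random.default_rng(seed)
    K = spec.n_clusters
    f = spec.divergence_f

    band_ids: list[str] = []
    for primer in spec.primer_classes:
        lo, hi = spec.bands_per_primer
        nb = int(rng.integers(lo, hi + 1))
        band_ids.extend(f"{primer}_{b}" for b in range(1, nb + 1))
    L = len(band_ids)

    p_bar = rng.uniform(0.1, 0.9, size=L)
    shape = (1.0 - f) / f
    p = rng.beta(p_bar * shape, (1.0 - p_bar) * shape, size=(K, L))

    genotypes: list[str] = []
    mapping: dict[str, str] = {}
    cluster_of: list[int] = []
    for name, size, cl in zip(spec.group_names, spec.group_sizes, spec.group_clusters):
        for i in range(1, size + 1):
            gid = f"{name}_{i:02d}"
            genotypes.append(gid)
            mapping[gid] = name
            cluster_of.append(cl)
    N = len(genotypes)

    conc = np.full((N, K), spec.alpha)
    conc[np.arange(N), cluster_of] += 1.0
    q = rng.gamma(conc)
    q /= q.sum(axis=1, keepdims=True)

    a = q @ p  # (N, L) mixed band/allele frequency
    prob = 1.0 - (1.0 - a) ** 4 if spec.tetraploid_dominance else a
    scores = (rng.uniform(size=(N, L)) < prob).astype(float)

    bm = BandMatrix(genotypes, band_ids, scores,
                    primer_classes=dict(spec.primer_classes))
    popmap = PopulationMap(mapping)
    truth = PanelTruth(
        cluster_freqs=p, admixture=q, ancestral_freqs=p_bar,
        group_clusters={g: c for g, c in zip(spec.group_names, spec.group_clusters)},
    )
    return bm, popmap, truth


@dataclass
class TraitSpec:
    """Study conditions for the simulated trait table.

    ``planted_effects`` are (band_id, trait, standardized beta) triples:
    the band's standardized score contributes ``beta`` group-SD units to
    the genotype-level trait.  Residual noise is correlated across traits
    via a Gaussian copula on group-centred residuals; the copula
    correlation is calibrated against the group-mean structure and the
    planted-effect variance so that the OVERALL genotype-level Pearson
    correlations land on ``target_corr`` in expectation (group means and
    SDs are untouched).
    """

    group_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {t: dict(d) for t, d in DEFAULT_GROUP_STATS.items()})
    traits: tuple[str, ...] = TRAIT_ORDER
    target_corr: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    planted_effects: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_PLANTED_EFFECTS))
    n_replicates: int = 3
    replicate_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATE_SD))
    value_floor: float = 1e-3

    def __post_init__(self) -> None:
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        eig = np.linalg.eigvalsh(self.target_corr)
        if eig.min() < -1e-10:
            raise ValueError("target correlation matrix is not positive semidefinite")
        for t, stats in self.group_stats.items():
            for grp, (_, sd) in stats.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {t}/{grp}")


def _nearest_corr(c: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to make a symmetric matrix a valid correlation."""
    c = np.clip((c + c.T) / 2.0, -0.99, 0.99)
    np.fill_diagonal(c, 1.0)
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < 1e-8:
        c = vecs @ np.diag(np.clip(vals, 1e-8, None)) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


def _calibrated_copula(
    spec: "TraitSpec", groups: list[str], h2: np.ndarray, genetic_cov: np.ndarray
) -> np.ndarray:
    """Residual-copula correlation that makes the overall genotype-level
    correlations hit ``spec.target_corr``.

    Total covariance decomposes into a between-group part (fixed by the
    group means) and a within-group part (group SDs times the
    standardized-residual correlation); the standardized residual itself
    splits into the planted genetic contribution (cross-trait covariance
    ``genetic_cov``, shared alleles only) and the Gaussian copula term
    scaled by sqrt(1 - h2).  Solving for the copula correlation and
    clipping to a valid correlation matrix gives the sampler input; an
    infeasible pair (planted effects alone exceed the target) is clipped,
    which slightly caps that pair's realized correlation.
    """
    names, counts = np.unique(groups, return_counts=True)
    w = counts / counts.sum()
    mu = np.array([[spec.group_stats[t][g][0] for g in names] for t in spec.traits])
    sd = np.array([[spec.group_stats[t][g][1] for g in names] for t in spec.traits])
    mu_bar = mu @ w
    cov_between = (mu - mu_bar[:, None]) * w @ (mu - mu_bar[:, None]).T
    within = sd * w @ sd.T
    var = np.diag(cov_between) + np.diag(within)
    target_cov = spec.target_corr * np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        c_res = np.where(within > 0, (target_cov - cov_between) / within, 0.0)
    c_z = (c_res - genetic_cov) / np.sqrt(np.outer(1.0 - h2, 1.0 - h2))
    return _nearest_corr(c_z)


def simulate_traits(
    bm: BandMatrix,
    popmap: PopulationMap,
    spec: TraitSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[TraitTable, dict[tuple[str, str], float]]:
    """Simulate replicate-level traits on top of a band matrix.

    Returns the trait table and the planted truth as a map
    ``(band_id, trait) -> standardized beta``.
    """
    spec = spec or TraitSpec()
    rng = np.random.default_rng(seed)

    for band_id, trait, _ in spec.planted_effects:
        if band_id not in bm.band_ids:
            raise ValueError(f"planted band {band_id!r} not in the band matrix")
        if trait not in spec.traits:
            raise ValueError(f"planted trait {trait!r} unknown")

    n = bm.n_genotypes
    T = len(spec.traits)
    groups = popmap.labels_for(bm.genotype_ids)

    # heritable part: standardized planted-band contributions per trait
    genetic = np.zeros((n, T))
    betas: dict[str, np.ndarray] = {}
    truth: dict[tuple[str, str], float] = {}
    for band_id, trait, beta in spec.planted_effects:
        j = bm.band_ids.index(band_id)
        t = spec.traits.index(trait)
        x = bm.scores[:, j]
        pfreq = np.nanmean(x)
        denom = np.sqrt(pfreq * (1 - pfreq)) if 0 < pfreq < 1 else 1.0
        xs = np.where(np.isnan(x), 0.0, (x - pfreq) / denom)
        genetic[:, t] += beta * xs
        betas.setdefault(band_id, np.zeros(T))[t] += beta
        truth[(band_id, trait)] = beta
    # per-trait planted variance and cross-trait covariance via shared alleles
    # (distinct bands are treated as independent)
    genetic_cov = sum((np.outer(b, b) for b in betas.values()), np.zeros((T, T)))
    h2 = np.diag(genetic_cov).copy()
    if (h2 >= 1.0).any():
        raise ValueError("planted effects explain >= 100% of a trait's variance")

    copula = _calibrated_copula(spec, groups, h2, genetic_cov)
    chol = np.linalg.cholesky(copula + 1e-10 * np.eye(T))
    z = rng.standard_normal((n, T)) @ chol.T
    latent_std = np.sqrt(1.0 - h2) * z + genetic  # unit-variance standardized traits

    rows = []
    for i, (gid, grp) in enumerate(zip(bm.genotype_ids, groups)):
        for t, trait in enumerate(spec.traits):
            mu, sd = spec.group_stats[trait][grp]
            latent = mu + sd * latent_std[i, t]
            for r in range(1, spec.n_replicates + 1):
                v = latent + rng.normal(0.0, spec.replicate_sd.get(trait, 0.0))
                rows.append((gid, trait, r, max(v, spec.value_floor)))

    import pandas as pd

    tt = TraitTable(
        pd.DataFrame(rows, columns=["genotype", "trait", "replicate", "value"]),
        units={"TAA": "mg GAE/g fl", "TPC": "mg GAE/g fl", "TFC": "mg CE/g fl"},
    )
    return tt, truth


def worked_fixture() -> tuple[BandMatrix, PopulationMap, TraitTable]:
    """A fixed 8-genotype, 2-primer (3 bands each) panel whose index
    values, diversity parameters, Jaccard distances and variance
    partition are all small enough to verify by hand.

    Properties relied on by the hand computations:

    * primer P1 shows 5 distinct multiband patterns over the 8 genotypes
      with multiplicities (2, 1, 3, 1, 1) -> 4 identical pairs of 28;
    * band P1_2 is present in 6 of 8 genotypes;
    * band P2_3 is monomorphic, the other 5 bands polymorphic;
    * genotypes g1 and g2 share 2 bands and mismatch on 2.
    """
    band_ids = ["P1_1", "P1_2", "P1_3", "P2_1", "P2_2", "P2_3"]
    scores = np.array([
        # P1_1 P1_2 P1_3 P2_1 P2_2 P2_3
        [1, 1, 0, 1, 0, 0],  # g1
        [1, 1, 0, 0, 1, 0],  # g2
        [1, 0, 1, 1, 0, 0],  # g3
        [0, 1, 0, 1, 0, 0],  # g4
        [0, 1, 0, 1, 0, 0],  # g5
        [0, 1, 0, 0, 1, 0],  # g6
        [1, 1, 1, 0, 1, 0],  # g7
        [0, 0, 1, 0, 0, 0],  # g8
    ], dtype=float)
    genotypes = [f"g{i}" for i in range(1, 9)]
    bm = BandMatrix(genotypes, band_ids, scores)
    popmap = PopulationMap({g: ("X" if i < 4 else "Y") for i, g in enumerate(genotypes)})

    import pandas as pd

    taa = [1, 2, 2, 4, 4, 4, 8, 8]          # fold range 8
    tpc = [0.10, 0.12, 0.08, 0.11, 0.09, 0.13, 0.10, 0.12]
    tfc = [2.0, 2.5, 1.5, 2.2, 1.8, 2.6, 2.1, 2.4]
    rows = []
    for g, a, p_, f_ in zip(genotypes, taa, tpc, tfc):
        rows += [(g, "TAA", 1, a), (g, "TPC", 1, p_), (g, "TFC", 1, f_)]
    tt = TraitTable(pd.DataFrame(rows, columns=["genotype", "trait", "replicate", "value"]))
    return bm, popmap, tt
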