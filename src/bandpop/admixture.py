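"""Bayesian admixture clustering of binary band data, with Evanno-style
model selection over the number of clusters.

Model: band ``l`` of genotype ``i`` is present with probability
``sum_k q_ik p_kl`` where ``q_i`` is the genotype's membership vector
over K latent clusters (Dirichlet(alpha) prior) and ``p_kl`` the
cluster's band frequency (uniform Beta prior).  Each band is an
independent Bernoulli locus - dominant presence/absence scores cannot
support a genotypic (allele-dosage) likelihood, so the recessive-allele
machinery of codominant clustering programs is deliberately absent.

Inference is a collapsed-free Gibbs sampler over the latent per-band
origins z_il:

    z_il | q, p  ~  Categorical_k( q_ik * (p_kl if x=1 else 1-p_kl) )
    p_kl | z     ~  Beta(1 + n_1kl, 1 + n_0kl)
    q_i  | z     ~  Dirichlet(alpha + counts_ik)

Point estimates are posterior means over the post-burn-in sweeps; the
data log-likelihood log P(x | q, p) is recorded at every kept sweep, and
its mean stands in for ln P(X|K) when comparing K (a consistent choice
across K, which is all the second-order Evanno statistic needs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import BandMatrix

__all__ = ["AdmixtureResult", "fit_admixture", "evanno_delta_k", "align_labels"]


@dataclass
class AdmixtureResult:
    k: int
    q: np.ndarray                  # (N, K) posterior-mean memberships
    p: np.ndarray                  # (K, L) posterior-mean band frequencies
    log_likelihood_trace: np.ndarray
    genotype_ids: list[str]
    band_ids: list[str]
    seed: int | None
    burnin: int
    iterations: int
    alpha: float

    @property
    def mean_log_likelihood(self) -> float:
        return float(self.log_likelihood_trace.mean())

    @property
    def hard_labels(self) -> np.ndarray:
        return self.q.argmax(axis=1)

    def q_dataframe(self) -> pd.DataFrame:
        cols = [f"cluster{k + 1}" for k in range(self.k)]
        return pd.DataFrame(self.q, index=self.genotype_ids, columns=cols)


def fit_admixture(
    bm: BandMatrix,
    k: int,
    burnin: int = 2000,
    iterations: int = 2000,
    alpha: float = 1.0,
    seed: int | None = 0,
) -> AdmixtureResult:
    """Gibbs-sample the admixture model at a fixed K.

    Desk-scale defaults (2,000 + 2,000 sweeps) mix well on panels of
    ~70 genotypes x ~100 bands; longer chains are a parameter away.
    Missing scores are ignored in all counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > bm.n_genotypes:
        raise ValueError("k cannot exceed the number of genotypes")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    rng = np.random.default_rng(seed)
    x = bm.scores
    obs = ~np.isnan(x)
    x1 = (x == 1) & obs
    n, L = x.shape

    q = rng.dirichlet(np.full(k, 1.0), size=n)
    p = rng.uniform(0.01, 0.99, size=(k, L))

    q_sum = np.zeros((n, k))
    p_sum = np.zeros((k, L))
    trace = np.empty(iterations)

    lik1 = np.empty((n, k, L))
    for sweep in range(burnin + iterations):
        # z | q, p  -- (N, K, L) unnormalized origin probabilities
        np.multiply(np.where(x1[:, None, :], p[None], 1.0 - p[None]),
                    q[:, :, None], out=lik1)
        tot = lik1.sum(axis=1, keepdims=True)
        np.divide(lik1, np.where(tot > 0, tot, 1.0), out=lik1)
        u = rng.uniform(size=(n, 1, L))
        z = (lik1.cumsum(axis=1) < u).sum(axis=1)  # (N, L) in 0..K-1

        # p | z and q | z
        n1 = np.empty((k, L))
        n0 = np.empty((k, L))
        counts = np.empty((n, k))
        for c in range(k):
            mask = (z == c) & obs
            n1[c] = (mask & x1).sum(axis=0)
            n0[c] = mask.sum(axis=0) - n1[c]
            counts[:, c] = mask.sum(axis=1)
        p = rng.beta(1.0 + n1, 1.0 + n0)
        g = rng.gamma(alpha + counts)
        q = g / g.sum(axis=1, keepdims=True)

        if sweep >= burnin:
            theta = np.clip(q @ p, 1e-12, 1.0 - 1e-12)
            ll = float(np.log(theta[x1]).sum() +
                       np.log1p(-theta[obs & ~x1]).sum())
            it = sweep - burnin
            trace[it] = ll
            q_sum += q
            p_sum += p

    return AdmixtureResult(
        k=k,
        q=q_sum / iterations,
        p=p_sum / iterations,
        log_likelihood_trace=trace,
        genotype_ids=list(bm.genotype_ids),
        band_ids=list(bm.band_ids),
        seed=seed if isinstance(seed, int) else None,
        burnin=burnin,
        iterations=iterations,
        alpha=alpha,
    )


def evanno_delta_k(lnl_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno second-order model selection table.

    ``lnl_by_k`` maps each K in a contiguous range (length >= 3) to >= 3
    replicate mean log-likelihoods.  Returns per K: mean L(K), sd L(K),
    L'(K) = L(K) - L(K-1), |L''(K)| = |L'(K+1) - L'(K)| and
    DeltaK = |L''(K)| / sd(L(K)) (defined for interior K only; an
    all-equal replicate set yields an infinite DeltaK with a warning).
    """
    ks = sorted(lnl_by_k)
    if len(ks) < 3:
        raise ValueError("need a K range of length >= 3")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    short = [k for k, v in lnl_by_k.items() if len(v) < 3]
    if short:
        raise ValueError(f"need >= 3 replicates per K; too few for K={short}")

    mean = np.array([np.mean(lnl_by_k[k]) for k in ks])
    sd = np.array([np.std(lnl_by_k[k], ddof=1) for k in ks])
    lp = np.full(len(ks), np.nan)
    lp[1:] = np.diff(mean)
    lpp = np.full(len(ks), np.nan)
    lpp[1:-1] = np.abs(np.diff(mean, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = lpp / sd
    if np.isinf(delta[1:-1]).any():
        warnings.warn("zero replicate SD: DeltaK reported as infinite", stacklevel=2)
    return pd.DataFrame({
        "K": ks, "mean_lnL": mean, "sd_lnL": sd,
        "Lprime": lp, "abs_Lsecond": lpp, "deltaK": delta,
    })


def best_k(table: pd.DataFrame) -> int:
    """K with the largest DeltaK among interior K values."""
    interior = table.dropna(subset=["deltaK"])
    if interior.empty:
        raise ValueError("no interior K with a defined DeltaK")
    return int(interior.loc[interior["deltaK"].idxmax(), "K"])


def align_labels(results: list[AdmixtureResult]) -> list[AdmixtureResult]:
    """Permute cluster labels of each run to best match the first run.

    The permutation maximizes the total correlation between matched Q
    columns (optimal assignment on the column-correlation matrix).
    Returns new results; the first is unchanged.
    """
    if not results:
        return []
    k = results[0].k
    if any(r.k != k for r in results):
        raise ValueError("all results must share the same K")
    ref = results[0].q
    aligned = [results[0]]
    for res in results[1:]:
        corr = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                ra, rb = ref[:, a], res.q[:, b]
                sa, sb = ra.std(), rb.std()
                corr[a, b] = (np.corrcoef(ra, rb)[0, 1]
                              if sa > 0 and sb > 0 else 0.0)
        _, perm = linear_sum_assignment(-corr)
        aligned.append(AdmixtureResult(
            k=k, q=res.q[:, perm], p=res.p[perm],
            log_likelihood_trace=res.log_likelihood_trace,
            genotype_ids=res.genotype_ids, band_ids=res.band_ids,
            seed=res.seed, burnin=res.burnin, iterations=res.iterations,
            alpha=res.alpha,
        ))
    return aligned
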