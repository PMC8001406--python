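"""Dissimilarity matrices: Jaccard on bands, standardized Euclidean on traits."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import BandMatrix, TraitTable

__all__ = ["jaccard_distance", "standardized_euclidean", "squared_band_distance"]


def jaccard_distance(bm: BandMatrix) -> DistanceMatrix:
    """Jaccard dissimilarity d = 1 - a/(a+b+c) over bands scored in both
    genotypes (a shared presences, b/c one-sided presences).

    Joint absences carry no information for dominant bands and are
    ignored.  A pair with no informative band (a+b+c = 0) is assigned
    distance 0 with a warning.
    """
    if bm.n_genotypes < 2:
        raise ValueError("need >= 2 genotypes")
    x = bm.scores
    obs = ~np.isnan(x)
    x0 = np.where(obs, x, 0.0)
    n = bm.n_genotypes
    d = np.zeros((n, n))
    degenerate = []
    for i in range(n):
        both = obs[i] & obs[i + 1:]
        a = ((x0[i] == 1) & (x0[i + 1:] == 1) & both).sum(axis=1)
        union = (((x0[i] == 1) | (x0[i + 1:] == 1)) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dij = np.where(union > 0, 1.0 - a / np.maximum(union, 1), 0.0)
        if (union == 0).any():
            degenerate.extend(
                (bm.genotype_ids[i], bm.genotype_ids[i + 1 + int(j)])
                for j in np.flatnonzero(union == 0))
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} genotype pair(s) share no informative band; "
            "their Jaccard distance is reported as 0", stacklevel=2)
    return DistanceMatrix(d, bm.genotype_ids)


def standardized_euclidean(tt: TraitTable) -> DistanceMatrix:
    """Euclidean distance on z-scored genotype-mean traits.

    Each trait is centred and scaled by its SD (n-1 denominator) across
    genotypes, making the matrix invariant to the traits' measurement
    scales.
    """
    means = tt.genotype_means()
    if means.shape[0] < 2:
        raise ValueError("need >= 2 genotypes")
    sd = means.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"trait {zero.index[0]!r} has zero SD across genotypes")
    z = (means - means.mean(axis=0)) / sd
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, list(means.index))


def squared_band_distance(bm: BandMatrix) -> DistanceMatrix:
    """Pairwise squared Euclidean distance on 0/1 scores, i.e. band
    mismatch counts - the distance basis of the molecular variance
    partition.

    Pairs with missing scores use the mean mismatch over
    pairwise-complete bands scaled to the full band count.
    """
    x = bm.scores
    obs = ~np.isnan(x)
    n, L = x.shape
    d = np.zeros((n, n))
    x0 = np.where(obs, x, 0.0)
    for i in range(n):
        both = obs[i] & obs[i + 1:]
        mism = ((x0[i] != x0[i + 1:]) & both).sum(axis=1)
        nb = both.sum(axis=1)
        dij = np.where(nb > 0, mism * (L / np.maximum(nb, 1)), 0.0)
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    return DistanceMatrix(d, bm.genotype_ids)
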