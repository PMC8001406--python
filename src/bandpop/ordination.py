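"""Ordination: principal coordinate analysis of a distance matrix and
correlation-matrix PCA of trait data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import TraitTable

__all__ = ["Ordination", "pcoa", "pca"]


@dataclass
class Ordination:
    """Coordinates (items x axes), eigenvalues sorted descending and
    percent variance explained per retained axis."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_explained: np.ndarray
    loadings: pd.DataFrame | None = None

    @property
    def axes(self) -> list[str]:
        return list(self.coordinates.columns)


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> Ordination:
    """Classical metric scaling (Gower double-centering).

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean
    input) are reported but excluded from both the coordinates and the
    percent-variance denominator.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("need >= 3 items")
    d2 = dm.data.astype(float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pct = 100.0 * vals[pos] / vals[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=vals,
        percent_explained=pct,
    )


def pca(tt: TraitTable) -> Ordination:
    """PCA of genotype-mean traits on the correlation matrix.

    Returns standardized-variable scores, per-axis percent variance and
    trait loadings (eigenvectors scaled by sqrt(eigenvalue)), the usual
    biplot ingredients.
    """
    means = tt.genotype_means()
    if means.shape[1] < 2:
        raise ValueError("need >= 2 traits")
    if means.shape[0] < 3:
        raise ValueError("need >= 3 genotypes")
    sd = means.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"trait {constant.index[0]!r} is constant")
    z = ((means - means.mean(axis=0)) / sd).to_numpy()
    corr = np.corrcoef(z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    scores = z @ vecs
    pct = 100.0 * vals / vals.sum()
    cols = [f"PC{i + 1}" for i in range(len(vals))]
    return Ordination(
        coordinates=pd.DataFrame(scores, index=list(means.index), columns=cols),
        eigenvalues=vals,
        percent_explained=pct,
        loadings=pd.DataFrame(
            vecs * np.sqrt(vals), index=list(means.columns), columns=cols),
    )
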