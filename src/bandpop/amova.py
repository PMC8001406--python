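"""Two-level analysis of molecular variance (AMOVA) on binary band data.

The distance basis is the squared Euclidean distance between 0/1 score
vectors (the band mismatch count), the convention for dominant data.
The partition of sums of squares is

    SS_total  = (1/N)   sum_{i<j}       d2_ij
    SS_within = sum_g (1/N_g) sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within

with df = (G-1, N-G).  Variance components follow from the expected mean
squares: sigma2_within = MS_within and
sigma2_among = (MS_among - MS_within)/n0 with
n0 = (N - sum N_g^2/N)/(G-1); a negative among-group component is
truncated to 0.  PhiPT = sigma2_among/(sigma2_among + sigma2_within) is
the dominant-data analogue of Fst, and its p-value is the fraction of
group-label permutations (observed configuration included) whose PhiPT
is at least the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BandMatrix, PopulationMap
from .distances import squared_band_distance

__all__ = ["AmovaTable", "amova", "phipt_from_components"]


@dataclass
class AmovaTable:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    sigma2_among: float
    sigma2_within: float
    phipt: float
    p_value: float
    n_permutations: int

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    @property
    def percent_among(self) -> float:
        total = self.sigma2_among + self.sigma2_within
        return 100.0 * self.sigma2_among / total

    @property
    def percent_within(self) -> float:
        return 100.0 - self.percent_among

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"source": "Among groups", "df": self.df_among, "SS": self.ss_among,
             "MS": self.ms_among, "variance": self.sigma2_among,
             "percent": self.percent_among},
            {"source": "Within groups", "df": self.df_within, "SS": self.ss_within,
             "MS": self.ms_within, "variance": self.sigma2_within,
             "percent": self.percent_within},
            {"source": "Total", "df": self.df_among + self.df_within,
             "SS": self.ss_total, "MS": np.nan,
             "variance": self.sigma2_among + self.sigma2_within,
             "percent": 100.0},
        ])


def _partition(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(SS_among, SS_within, sigma2_among, sigma2_within, PhiPT) for one
    labelling; d2 is the full squared-distance matrix."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    sizes = np.zeros(n_groups)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sizes[g] = len(idx)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, 1).sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes ** 2).sum() / n) / df_among
    s2_within = ms_within
    s2_among = max((ms_among - ms_within) / n0, 0.0)
    denom = s2_among + s2_within
    phipt = s2_among / denom if denom > 0 else 0.0
    return ss_among, ss_within, s2_among, s2_within, phipt


def amova(
    bm: BandMatrix,
    popmap: PopulationMap,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> AmovaTable:
    """AMOVA of the band matrix over the population-map groups."""
    labels = popmap.labels_for(bm.genotype_ids)
    groups = sorted(set(labels))
    n, G = bm.n_genotypes, len(groups)
    if G < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    if G == n:
        raise ValueError("all groups are singletons: no within-group variation")
    if n < 3:
        raise ValueError("AMOVA needs >= 3 genotypes")

    codes = np.array([groups.index(l) for l in labels])
    d2 = squared_band_distance(bm).data
    ss_a, ss_w, s2_a, s2_w, phipt = _partition(d2, codes, G)

    rng = np.random.default_rng(seed)
    hits = 1  # the observed configuration counts
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        *_, phi_p = _partition(d2, perm, G)
        if phi_p >= phipt - 1e-12:
            hits += 1
    p = hits / (n_perm + 1)

    return AmovaTable(
        df_among=G - 1, df_within=n - G,
        ss_among=ss_a, ss_within=ss_w,
        ms_among=ss_a / (G - 1), ms_within=ss_w / (n - G),
        sigma2_among=s2_a, sigma2_within=s2_w,
        phipt=phipt, p_value=p, n_permutations=n_perm,
    )


def phipt_from_components(
    sigma_among: float, sigma_within: float
) -> tuple[float, float, float]:
    """(PhiPT, percent among, percent within) from variance components."""
    if sigma_among < 0 or sigma_within < 0:
        raise ValueError("variance components must be >= 0")
    total = sigma_among + sigma_within
    if total == 0:
        raise ValueError("both variance components are zero")
    phipt = sigma_among / total
    return phipt, 100.0 * phipt, 100.0 * (1.0 - phipt)
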