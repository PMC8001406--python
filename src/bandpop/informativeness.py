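"""Per-primer discriminatory indices for dominant marker data.

For each primer pair the battery comprises:

* PIC  - polymorphic information content, the primer's capacity to reveal
  polymorphism (banded high > 0.5, moderate 0.25-0.5, low < 0.25);
* EMR  - effective multiplex ratio, n_p^2 / n over polymorphic (n_p) and
  total (n) bands;
* MI   - marker index, PIC x EMR;
* D    - discrimination power, the probability that two randomly chosen
  genotypes show different multiband patterns at the primer;
* R    - resolving power, sum over bands of Ib = 1 - 2|0.5 - p|.

Band frequencies use pairwise-complete denominators: a missing score
drops that genotype from that band's count only.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .io import BandMatrix

__all__ = [
    "band_frequencies",
    "emr",
    "marker_index",
    "discrimination_power",
    "resolving_power",
    "pic_primer",
    "pic_class",
    "informativeness_table",
]

PIC_CONVENTIONS = ("mean-band-2pq", "pattern-heterozygosity")


def band_frequencies(bm: BandMatrix, primer: str) -> np.ndarray:
    """Fraction of scored genotypes showing each band of ``primer``."""
    if bm.n_genotypes < 1:
        raise ValueError("band matrix has no genotypes")
    cols = bm.band_columns(primer)
    sub = bm.scores[:, cols]
    n_scored = np.sum(~np.isnan(sub), axis=0)
    if (n_scored == 0).any():
        bad = bm.band_ids[cols[int(np.argmax(n_scored == 0))]]
        raise ValueError(f"band {bad!r} has no scored genotypes")
    return np.nansum(sub, axis=0) / n_scored


def emr(n_p: int, n: int) -> float:
    """Effective multiplex ratio n_p^2 / n."""
    if n < 1:
        raise ValueError("total band count n must be >= 1")
    if not 0 <= n_p <= n:
        raise ValueError("need 0 <= n_p <= n")
    return n_p * n_p / n


def marker_index(pic: float, emr_value: float) -> float:
    """Marker index MI = PIC x EMR."""
    return pic * emr_value


def _patterns(bm: BandMatrix, primer: str) -> Counter:
    """Multiband pattern multiplicities at a primer.

    Genotypes with any missing score at the primer are excluded (a partial
    pattern is not comparable with a complete one).
    """
    cols = bm.band_columns(primer)
    sub = bm.scores[:, cols]
    complete = ~np.isnan(sub).any(axis=1)
    return Counter(tuple(int(v) for v in row) for row in sub[complete])


def discrimination_power(bm: BandMatrix, primer: str) -> float:
    """Probability a uniformly random unordered genotype pair differs in
    banding pattern at ``primer``.

    With pattern frequencies p_i over N genotypes, the confusion
    probability is C = sum_i p_i (N p_i - 1)/(N - 1) and D = 1 - C.
    """
    counts = _patterns(bm, primer)
    n = sum(counts.values())
    if n < 2:
        raise ValueError("discrimination power needs >= 2 scored genotypes")
    c = sum((k / n) * (k - 1) / (n - 1) for k in counts.values())
    return 1.0 - c


def resolving_power(bm: BandMatrix, primer: str) -> float:
    """Sum over the primer's bands of Ib = 1 - 2|0.5 - p|."""
    p = band_frequencies(bm, primer)
    return float(np.sum(1.0 - 2.0 * np.abs(0.5 - p)))


def pic_primer(bm: BandMatrix, primer: str, convention: str = "mean-band-2pq") -> float:
    """Primer-level PIC under one of two dominant-data conventions.

    ``mean-band-2pq`` (default) averages the per-band dominant PIC
    2p(1-p); ``pattern-heterozygosity`` is 1 - sum_i p_i^2 over the
    primer's multiband pattern frequencies, which can exceed 0.5 when a
    primer resolves many patterns.
    """
    if convention == "mean-band-2pq":
        p = band_frequencies(bm, primer)
        return float(np.mean(2.0 * p * (1.0 - p)))
    if convention == "pattern-heterozygosity":
        counts = _patterns(bm, primer)
        n = sum(counts.values())
        if n == 0:
            raise ValueError("no complete patterns at primer")
        return 1.0 - sum((k / n) ** 2 for k in counts.values())
    raise ValueError(f"unknown PIC convention {convention!r}")


def pic_class(pic: float) -> str:
    """Informativeness band: high (>0.5), moderate (0.25-0.5), low (<0.25)."""
    if pic > 0.5:
        return "high"
    if pic >= 0.25:
        return "moderate"
    return "low"


def informativeness_table(
    bm: BandMatrix,
    pic_convention: str = "mean-band-2pq",
    primer_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per primer (PIC, EMR, MI, D, R, n, n_p, class) plus
    unweighted per-marker-class mean rows.

    A band is polymorphic when its frequency is strictly between 0 and 1
    within the analysed genotype set.
    """
    classes = primer_classes or bm.primer_classes or {}
    rows = []
    for primer in bm.primers:
        p = band_frequencies(bm, primer)
        n = len(p)
        n_p = int(np.sum((p > 0) & (p < 1)))
        pic = pic_primer(bm, primer, pic_convention)
        e = emr(n_p, n)
        rows.append({
            "primer": primer,
            "marker_class": classes.get(primer, "All"),
            "PIC": pic,
            "EMR": e,
            "MI": marker_index(pic, e),
            "D": discrimination_power(bm, primer),
            "R": resolving_power(bm, primer),
            "n": n,
            "n_p": n_p,
            "PIC_class": pic_class(pic),
        })
    table = pd.DataFrame(rows)
    means = (
        table.groupby("marker_class", sort=False)[["PIC", "EMR", "MI", "D", "R"]]
        .mean()
        .reset_index()
    )
    means.insert(0, "primer", "Mean")
    return pd.concat([table, means], ignore_index=True)
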