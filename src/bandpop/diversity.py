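"""Within-group diversity parameters for dominant marker data.

Per group: percentage of polymorphic loci (PL), observed alleles per
primer (Na), effective alleles per band (Ne), expected heterozygosity /
Nei gene diversity (He) and Shannon's information index (I).

Because a dominant band hides heterozygote dosage, allele frequencies are
estimated from band frequency ``p_band``.  Two conventions ship:

* ``diploid-sqrt`` (default): assume band absence is the homozygous
  recessive class, q = sqrt(1 - p_band) - the standard treatment of
  binary data in diversity software;
* ``band-as-allele``: take the band frequency itself as the allele
  frequency (every band one biallelic presence/absence locus), the
  convention under which all bands of a primer are "alleles".

Na is defined per primer (bands observed in the group), not per band,
which is why group values can far exceed 2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import BandMatrix, PopulationMap
from .informativeness import band_frequencies

__all__ = [
    "dominant_allele_freq",
    "percent_polymorphic",
    "allele_counts",
    "he_shannon",
    "diversity_table",
]

FREQ_MODELS = ("diploid-sqrt", "band-as-allele")


def dominant_allele_freq(p_band: float, model: str = "diploid-sqrt") -> tuple[float, float]:
    """Estimate (p_hat, q_hat) for the band-presence allele from the band
    frequency."""
    if not 0.0 <= p_band <= 1.0:
        raise ValueError("band frequency must be in [0, 1]")
    if model == "diploid-sqrt":
        q = float(np.sqrt(1.0 - p_band))
        return 1.0 - q, q
    if model == "band-as-allele":
        return float(p_band), 1.0 - float(p_band)
    raise ValueError(f"unknown frequency model {model!r}")


def _group_matrix(bm: BandMatrix, popmap: PopulationMap, group: str) -> BandMatrix:
    genos = [g for g in bm.genotype_ids if g in popmap and popmap[g] == group]
    if not genos:
        raise ValueError(f"group {group!r} has no genotypes in the matrix")
    return bm.subset(genos)


def _all_band_freqs(bm: BandMatrix) -> np.ndarray:
    return np.concatenate([band_frequencies(bm, p) for p in bm.primers])


def percent_polymorphic(bm: BandMatrix, popmap: PopulationMap, group: str) -> float:
    """100 x (bands with 0 < p < 1 within the group) / total bands."""
    freqs = _all_band_freqs(_group_matrix(bm, popmap, group))
    return 100.0 * float(np.mean((freqs > 0) & (freqs < 1)))


def allele_counts(
    bm: BandMatrix, popmap: PopulationMap, group: str, model: str = "diploid-sqrt"
) -> tuple[float, float]:
    """(Na, Ne) for a group.

    Na: mean over primers of the number of bands observed (p > 0) in the
    group.  Ne: mean over bands of 1/(p_hat^2 + q_hat^2); a fixed band
    contributes 1.0, a band at p_hat = q_hat = 0.5 contributes 2.0.
    """
    sub = _group_matrix(bm, popmap, group)
    per_primer = [float(np.sum(band_frequencies(sub, pr) > 0)) for pr in sub.primers]
    na = float(np.mean(per_primer))
    freqs = _all_band_freqs(sub)
    ne_terms = []
    for pb in freqs:
        p_hat, q_hat = dominant_allele_freq(pb, model)
        ne_terms.append(1.0 / (p_hat ** 2 + q_hat ** 2))
    return na, float(np.mean(ne_terms))


def he_shannon(
    bm: BandMatrix, popmap: PopulationMap, group: str, model: str = "diploid-sqrt"
) -> tuple[float, float]:
    """(He, I) for a group: per band He = 2 p q and
    I = -p ln p - q ln q (zero-frequency terms contribute 0), averaged
    unweighted over all bands."""
    freqs = _all_band_freqs(_group_matrix(bm, popmap, group))
    he_terms, i_terms = [], []
    for pb in freqs:
        p_hat, q_hat = dominant_allele_freq(pb, model)
        he_terms.append(2.0 * p_hat * q_hat)
        i_val = 0.0
        for f in (p_hat, q_hat):
            if f > 0:
                i_val -= f * np.log(f)
        i_terms.append(i_val)
    return float(np.mean(he_terms)), float(np.mean(i_terms))


def diversity_table(
    bm: BandMatrix,
    popmap: PopulationMap,
    model: str = "diploid-sqrt",
    primer_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per group (per marker class when a class map is known),
    plus an unweighted across-group mean row per class."""
    classes = primer_classes or bm.primer_classes
    if classes:
        by_class: dict[str, list[str]] = {}
        for b in bm.band_ids:
            by_class.setdefault(classes.get(bm.primer_of_band[b], "All"), []).append(b)
        class_matrices = {
            cl: BandMatrix(
                list(bm.genotype_ids), bands,
                bm.scores[:, [bm.band_ids.index(b) for b in bands]].copy())
            for cl, bands in by_class.items()
        }
    else:
        class_matrices = {"All": bm}

    rows = []
    for cl, sub in class_matrices.items():
        for group in popmap.groups:
            size = len([g for g in sub.genotype_ids
                        if g in popmap and popmap[g] == group])
            if size == 0:
                continue
            if size == 1:
                warnings.warn(
                    f"group {group!r} has a single genotype: He/I are "
                    "low-confidence", stacklevel=2)
            na, ne = allele_counts(sub, popmap, group, model)
            he, shannon = he_shannon(sub, popmap, group, model)
            rows.append({
                "marker_class": cl, "group": group, "sample_size": size,
                "PL_percent": percent_polymorphic(sub, popmap, group),
                "Na": na, "Ne": ne, "He": he, "I": shannon,
            })
    table = pd.DataFrame(rows)
    means = (
        table.groupby("marker_class", sort=False)[["PL_percent", "Na", "Ne", "He", "I"]]
        .mean()
        .reset_index()
    )
    means.insert(1, "group", "Mean")
    return pd.concat([table, means], ignore_index=True)
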