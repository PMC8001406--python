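"""Validated containers and file formats for band-score analyses.

The central object is the :class:`BandMatrix`: genotypes x binary band
scores, with every band column assigned to the primer pair that produced
it.  Dominant markers (SSR and EST-PCR products scored on gels) cannot
distinguish heterozygote dosage, so a cell is only ever present (1),
absent (0) or missing.

Band identifiers follow the field convention ``PRIMER_band`` where the
primer name may itself contain underscores (``VCC_K4_6`` is band ``6`` of
primer ``VCC_K4``): the split is always on the *last* underscore.

Also here: the population map (genotype -> group), replicate-level trait
tables, square/PHYLIP distance-matrix round-trips, Newick trees and a
one-row-per-individual export for Bayesian-clustering interoperability.
Distance matrices are :class:`skbio.DistanceMatrix`; trees are
:class:`skbio.TreeNode`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "BandMatrix",
    "PopulationMap",
    "TraitTable",
    "SchemaError",
    "read_band_matrix",
    "write_band_matrix",
    "read_population_map",
    "write_population_map",
    "read_trait_table",
    "write_trait_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_newick",
    "write_newick",
    "export_structure_format",
    "split_band_id",
]

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class SchemaError(ValueError):
    """An input file violates the documented schema."""


def split_band_id(band_id: str) -> tuple[str, str]:
    """Split ``PRIMER_band`` on the last underscore.

    >>> split_band_id("VCC_K4_6")
    ('VCC_K4', '6')
    """
    if "_" not in band_id:
        raise SchemaError(
            f"band id {band_id!r} is not of the form PRIMER_band "
            "(no underscore found)"
        )
    primer, band = band_id.rsplit("_", 1)
    if not primer or not band:
        raise SchemaError(f"band id {band_id!r} has an empty primer or band part")
    return primer, band


@dataclass
class BandMatrix:
    """Genotypes x binary band scores, with bands grouped by primer.

    Parameters
    ----------
    genotype_ids
        Ordered, unique genotype labels (matrix rows).
    band_ids
        Ordered, unique band labels of the form ``PRIMER_band``.
    scores
        Float array of shape ``(n_genotypes, n_bands)`` holding 0.0, 1.0
        or ``nan`` for missing (failed amplification).
    primer_classes
        Optional map primer -> marker class (e.g. ``"EST-SSR"``), carried
        along for class-wise summaries.
    """

    genotype_ids: list[str]
    band_ids: list[str]
    scores: np.ndarray
    primer_classes: dict[str, str] | None = None
    primer_of_band: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.band_ids = [str(b) for b in self.band_ids]
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise SchemaError("duplicate genotype ids")
        if len(set(self.band_ids)) != len(self.band_ids):
            raise SchemaError("duplicate band ids")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genotype_ids), len(self.band_ids)):
            raise SchemaError(
                f"score shape {self.scores.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.band_ids)} bands"
            )
        ok = np.isnan(self.scores) | (self.scores == 0) | (self.scores == 1)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise SchemaError(
                f"non-binary score {self.scores[i, j]!r} at genotype "
                f"{self.genotype_ids[i]!r}, band {self.band_ids[j]!r}"
            )
        self.primer_of_band = {b: split_band_id(b)[0] for b in self.band_ids}

    # -- basic accessors ------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_bands(self) -> int:
        return len(self.band_ids)

    @property
    def primers(self) -> list[str]:
        """Primer ids in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for b in self.band_ids:
            seen.setdefault(self.primer_of_band[b], None)
        return list(seen)

    def band_columns(self, primer: str) -> np.ndarray:
        """Column indices of the bands produced by ``primer``."""
        idx = [i for i, b in enumerate(self.band_ids) if self.primer_of_band[b] == primer]
        if not idx:
            raise KeyError(f"primer {primer!r} has no bands in this matrix")
        return np.asarray(idx)

    def subset(self, genotypes: list[str]) -> "BandMatrix":
        """Row subset preserving band (column) order."""
        pos = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in genotypes if g not in pos]
        if missing:
            raise KeyError(f"genotypes not in matrix: {missing}")
        rows = [pos[g] for g in genotypes]
        return BandMatrix(
            list(genotypes), list(self.band_ids), self.scores[rows].copy(),
            primer_classes=self.primer_classes,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genotype_ids, columns=self.band_ids)


class PopulationMap:
    """Mapping genotype -> group label, insertion ordered."""

    def __init__(self, mapping: dict[str, str]):
        if not mapping:
            raise SchemaError("empty population map")
        self._map = {str(g): str(p) for g, p in mapping.items()}

    def __getitem__(self, genotype: str) -> str:
        return self._map[genotype]

    def __contains__(self, genotype: str) -> bool:
        return genotype in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @property
    def genotypes(self) -> list[str]:
        return list(self._map)

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self._map.values():
            seen.setdefault(p, None)
        return list(seen)

    def genotypes_in(self, group: str) -> list[str]:
        return [g for g, p in self._map.items() if p == group]

    def labels_for(self, genotypes: list[str]) -> list[str]:
        """Group label per genotype; every genotype must be mapped."""
        unmapped = [g for g in genotypes if g not in self._map]
        if unmapped:
            raise SchemaError(f"genotypes without a group: {unmapped}")
        return [self._map[g] for g in genotypes]


class TraitTable:
    """Replicate-level trait measurements (genotype, trait, replicate, value).

    Values are non-negative reals in the assay's calibration units
    (e.g. mg GAE/g fresh leaf for antioxidant activity and phenolics,
    mg CE/g fresh leaf for flavonoids).
    """

    def __init__(self, data: pd.DataFrame, units: dict[str, str] | None = None):
        required = ["genotype", "trait", "replicate", "value"]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise SchemaError(f"trait table missing columns: {missing}")
        df = data[required].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if (df["value"] < 0).any():
            bad = df.loc[df["value"] < 0].iloc[0]
            raise SchemaError(
                f"negative trait value {bad['value']} for genotype "
                f"{bad['genotype']!r}, trait {bad['trait']!r}"
            )
        self.data = df.reset_index(drop=True)
        self.units = dict(units or {})

    @property
    def traits(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.data["trait"]:
            seen.setdefault(t, None)
        return list(seen)

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data["genotype"]:
            seen.setdefault(g, None)
        return list(seen)

    def genotype_means(self) -> pd.DataFrame:
        """Genotypes x traits table of replicate means."""
        wide = self.data.pivot_table(
            index="genotype", columns="trait", values="value", aggfunc="mean"
        )
        return wide.loc[self.genotypes, self.traits]

    def genotype_sds(self) -> pd.DataFrame:
        wide = self.data.pivot_table(
            index="genotype", columns="trait", values="value", aggfunc=lambda v: v.std(ddof=1)
        )
        return wide.loc[self.genotypes, self.traits]

    def values_by_group(self, popmap: PopulationMap, trait: str) -> dict[str, np.ndarray]:
        """Genotype-mean trait values split by group."""
        means = self.genotype_means()[trait]
        out: dict[str, np.ndarray] = {}
        for grp in popmap.groups:
            gs = [g for g in popmap.genotypes_in(grp) if g in means.index]
            if gs:
                out[grp] = means.loc[gs].to_numpy()
        return out


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def read_band_matrix(path: str | Path, primer_classes: dict[str, str] | None = None) -> BandMatrix:
    """Read a band-score CSV: first column genotype id, remaining columns
    PRIMER_band headers with cells in {0, 1, NA}."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need a genotype column plus at least one band")
    band_ids = list(df.columns[1:])
    for b in band_ids:
        split_band_id(b)  # raises SchemaError naming the column
    genotypes = df.iloc[:, 0].astype(str).tolist()
    scores = np.empty((len(genotypes), len(band_ids)))
    for j, b in enumerate(band_ids):
        col = df[b].str.strip()
        for i, cell in enumerate(col):
            if cell in MISSING_TOKENS:
                scores[i, j] = np.nan
            elif cell in ("0", "1"):
                scores[i, j] = float(cell)
            else:
                raise SchemaError(
                    f"{path}: non-binary cell {cell!r} at row {genotypes[i]!r}, "
                    f"column {b!r}"
                )
    return BandMatrix(genotypes, band_ids, scores, primer_classes=primer_classes)


def write_band_matrix(bm: BandMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["genotype", *bm.band_ids])
        for g, row in zip(bm.genotype_ids, bm.scores):
            w.writerow([g] + ["NA" if np.isnan(v) else str(int(v)) for v in row])


def read_population_map(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected columns genotype,group")
    genos = df.iloc[:, 0].astype(str)
    if genos.duplicated().any():
        dup = genos[genos.duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate genotype {dup!r}")
    return PopulationMap(dict(zip(genos, df.iloc[:, 1].astype(str))))


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["genotype", "group"])
        for g, p in popmap.items():
            w.writerow([g, p])


def read_trait_table(path: str | Path) -> TraitTable:
    return TraitTable(pd.read_csv(path))


def write_trait_table(tt: TraitTable, path: str | Path) -> None:
    tt.data.to_csv(path, index=False)


def write_distance_matrix(
    dm: DistanceMatrix, path: str | Path, dialect: str = "square-csv"
) -> None:
    """Write a distance matrix at 6-decimal precision.

    ``square-csv`` is a labelled square CSV; ``phylip`` has a leading
    taxon count and one space-separated row per taxon.
    """
    if dialect == "square-csv":
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            path, float_format="%.6f"
        )
    elif dialect == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{dm.shape[0]}\n")
            for label, row in zip(dm.ids, dm.data):
                fh.write(label + " " + " ".join(f"{v:.6f}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(path: str | Path, dialect: str = "square-csv") -> DistanceMatrix:
    if dialect == "square-csv":
        df = pd.read_csv(path, index_col=0)
        return DistanceMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])
    if dialect == "phylip":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        if len(labels) != n:
            raise SchemaError(f"{path}: header says {n} taxa, found {len(labels)}")
        return DistanceMatrix(np.asarray(rows), labels)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick; internal-node names carry supports."""
    for tip in tree.tips():
        if not tip.name:
            raise ValueError("tree has an unlabeled leaf")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# Bayesian-clustering interoperability export
# ---------------------------------------------------------------------------


def export_structure_format(bm: BandMatrix, path: str | Path) -> None:
    """One whitespace-separated data row per genotype, one column per band,
    0/1 entries with missing coded -9 (haploid-style single row)."""
    with open(path, "w") as fh:
        for g, row in zip(bm.genotype_ids, bm.scores):
            toks = ["-9" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(g + "\t" + " ".join(toks) + "\n")
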