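"""End-to-end orchestration: simulate or ingest a panel, then run every
analysis stage and write its tables to an output directory.

Stage order: marker-informativeness indices -> within-group diversity ->
Jaccard/trait distances, NJ + UPGMA trees -> PCoA/PCA ordination ->
AMOVA -> admixture over a K range with Evanno DeltaK -> Mantel test of
biochemical vs genetic distances -> stepwise marker-trait regression per
trait.  Every stage draws its seed deterministically from the master
seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import admixture as adx
from . import amova as amova_mod
from . import association as assoc
from . import distances, diversity, informativeness, ordination, simulate, trees
from . import io as bio

log = logging.getLogger("bandpop")

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of (master seed, stage name),
    reduced below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips through YAML/JSON."""

    out_dir: str = "bandpop_run"
    seed: int = 1
    # either simulate...
    simulate: bool = True
    divergence_f: float = 0.4
    alpha: float = 0.05
    # ...or ingest
    bands_csv: str | None = None
    pops_csv: str | None = None
    traits_csv: str | None = None
    # stage parameters
    pic_convention: str = "mean-band-2pq"
    freq_model: str = "diploid-sqrt"
    amova_permutations: int = 999
    bootstrap_reps: int = 200
    k_min: int = 1
    k_max: int = 5
    k_replicates: int = 3
    mcmc_burnin: int = 300
    mcmc_iterations: int = 500
    mantel_permutations: int = 999
    smra_p_enter: float = 0.045
    smra_p_remove: float = 0.099

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _timed(manifest: dict, name: str):
    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            status = "ok" if exc_type is None else f"failed: {exc}"
            manifest["stages"][name] = {
                "status": status,
                "seconds": round(time.perf_counter() - self.t0, 3),
            }
            log.info("stage %-12s %s (%.2fs)", name, status,
                     time.perf_counter() - self.t0)
            return exc_type is not None  # swallow, record partial completion

    return _Stage()


def run_all(config: RunConfig) -> dict:
    """Run every stage, write tables under ``config.out_dir`` and return
    the manifest (also written as ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": []}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    # ---- inputs ----------------------------------------------------------
    with _timed(manifest, "inputs"):
        if config.simulate:
            spec = simulate.PanelSpec(divergence_f=config.divergence_f,
                                      alpha=config.alpha)
            bm, popmap, truth = simulate.simulate_panel(
                spec, seed=stage_seed(config.seed, "panel"))
            tt, planted = simulate.simulate_traits(
                bm, popmap, seed=stage_seed(config.seed, "traits"))
            emit("bands.csv", lambda p: bio.write_band_matrix(bm, p))
            emit("pops.csv", lambda p: bio.write_population_map(popmap, p))
            emit("traits.csv", lambda p: bio.write_trait_table(tt, p))
            emit("truth.json", lambda p: p.write_text(json.dumps({
                "group_clusters": truth.group_clusters,
                "planted_effects": {f"{b}:{t}": v for (b, t), v in planted.items()},
            }, indent=2)))
        else:
            bm = bio.read_band_matrix(config.bands_csv)
            popmap = bio.read_population_map(config.pops_csv)
            tt = bio.read_trait_table(config.traits_csv)

    with _timed(manifest, "indices"):
        table = informativeness.informativeness_table(bm, config.pic_convention)
        emit("informativeness.csv", lambda p: table.to_csv(p, index=False))

    with _timed(manifest, "diversity"):
        div = diversity.diversity_table(bm, popmap, config.freq_model)
        emit("diversity.csv", lambda p: div.to_csv(p, index=False))

    with _timed(manifest, "distances"):
        dj = distances.jaccard_distance(bm)
        de = distances.standardized_euclidean(tt)
        emit("jaccard.csv", lambda p: bio.write_distance_matrix(dj, p))
        emit("euclidean_traits.csv", lambda p: bio.write_distance_matrix(de, p))

    with _timed(manifest, "trees"):
        nj = trees.bootstrap_support(
            bm, trees.nj_tree, n_reps=config.bootstrap_reps,
            seed=stage_seed(config.seed, "bootstrap"))
        emit("nj_jaccard.nwk", lambda p: bio.write_newick(nj, p))
        up = trees.upgma_tree(de)
        emit("upgma_traits.nwk", lambda p: bio.write_newick(up, p))

    with _timed(manifest, "ordination"):
        pco = ordination.pcoa(dj)
        emit("pcoa.csv", lambda p: pco.coordinates.to_csv(p))
        pc = ordination.pca(tt)
        emit("pca.csv", lambda p: pc.coordinates.to_csv(p))

    with _timed(manifest, "amova"):
        am = amova_mod.amova(bm, popmap, n_perm=config.amova_permutations,
                             seed=stage_seed(config.seed, "amova"))
        df = am.to_dataframe()
        df.attrs["PhiPT"] = am.phipt
        emit("amova.csv", lambda p: df.assign(
            PhiPT=am.phipt, p_value=am.p_value).to_csv(p, index=False))

    with _timed(manifest, "admixture"):
        lnl_by_k: dict[int, list[float]] = {}
        for k in range(config.k_min, config.k_max + 1):
            lnl_by_k[k] = []
            for rep in range(config.k_replicates):
                res = adx.fit_admixture(
                    bm, k, burnin=config.mcmc_burnin,
                    iterations=config.mcmc_iterations,
                    seed=stage_seed(config.seed, f"mcmc:{k}:{rep}"))
                lnl_by_k[k].append(res.mean_log_likelihood)
                if rep == 0:
                    emit(f"q_K{k}.csv", lambda p, r=res: r.q_dataframe().to_csv(p))
        dk = adx.evanno_delta_k(lnl_by_k)
        emit("delta_k.csv", lambda p: dk.to_csv(p, index=False))
        manifest["best_k"] = adx.best_k(dk)

    with _timed(manifest, "mantel"):
        mres = assoc.mantel(de, dj, n_perm=config.mantel_permutations,
                            seed=stage_seed(config.seed, "mantel"))
        emit("mantel.json", lambda p: p.write_text(json.dumps({
            "r": mres.r, "p": mres.p_value, "permutations": mres.n_permutations,
            "tail": mres.tail}, indent=2)))

    with _timed(manifest, "smra"):
        for trait in tt.traits:
            rep = assoc.smra(tt, bm, trait, config.smra_p_enter,
                             config.smra_p_remove)
            emit(f"smra_{trait}.csv",
                 lambda p, r=rep: r.steps.to_csv(p, index=False))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["outputs"].append("manifest.json")
    return manifest
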