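"""End-to-end pipeline: simulate/load → preprocess → classify → assembly →
diversity → networks, with deterministic per-stage seeds and an output
manifest of checksums."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly as asm
from . import diversity as dv
from . import network as net
from . import niche
from . import synthetic
from .core_io import (CommunityTable, SALINITY_CATEGORIES, rarefy,
                      read_count_table, read_metadata, read_tree,
                      write_count_table, write_metadata, write_tree)

logger = logging.getLogger(__name__)

STAGES = ("inputs", "preprocess", "classify", "assembly", "diversity", "network")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults mirror the analysis conventions this pipeline implements:
    rarefaction at the minimum library size, 1000 niche permutations, 999
    assembly randomisations, 999 PERMANOVA permutations, alpha 0.05 and
    salinity category edges at 40 and 100 g/L.
    """

    out_dir: str = "halo_run"
    # either simulation parameters ...
    simulate: bool = True
    n_taxa: int = 300
    n_sites: int = 9
    n_seasons: int = 4
    n_replicates: int = 1
    library_size: int = 11400
    w: float = 0.2
    bm_rate: float = 2.0
    frac_generalist: float = 0.2
    # ... or input paths
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    # analysis parameters
    rarefy_depth: int | None = None  # None -> minimum library size
    n_perm_niche: int = 1000
    niche_mode: str = "triple"
    n_null_assembly: int = 999
    n_perm_permanova: int = 999
    alpha: float = 0.05
    category_edges: tuple[float, float] = (40.0, 100.0)
    network_min_rel_abund: float = 1e-4
    stars_threshold: float = 0.05
    stars_reps: int = 20
    seed: int = 0
    stage_seeds: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_perm_niche < 100:
            raise ValueError("n_perm_niche must be >= 100")
        if self.n_null_assembly < 1:
            raise ValueError("n_null_assembly must be >= 1")
        if self.n_perm_permanova < 1:
            raise ValueError("n_perm_permanova must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not self.category_edges[0] < self.category_edges[1]:
            raise ValueError("category edges must be strictly increasing")
        if self.rarefy_depth is not None and self.rarefy_depth < 1:
            raise ValueError("rarefy_depth must be >= 1")
        if not self.simulate:
            for p in (self.table_path, self.tree_path, self.metadata_path):
                if p is None or not Path(p).exists():
                    raise ValueError(f"missing input path: {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "category_edges" in data:
            data["category_edges"] = tuple(data["category_edges"])
        return cls(**data)


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    if stage in cfg.stage_seeds:
        return int(cfg.stage_seeds[stage])
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(cfg.seed).spawn(len(STAGES))[idx]
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    Every output file is listed in ``manifest.json`` with its sha256, so a
    rerun with the same config and seed reproduces identical checksums for
    the deterministic stages.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timers: dict[str, float] = {}

    def record(name: str, path: Path):
        artifacts[name] = str(path)

    def stage(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timers[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s finished in %.2fs", name, timers[name])
        return _T()

    # -- inputs ------------------------------------------------------------
    with stage("inputs"):
        if config.simulate:
            table, tree, meta, niches, truth = synthetic.simulate_dataset(
                n_taxa=config.n_taxa, n_sites=config.n_sites,
                n_seasons=config.n_seasons, n_replicates=config.n_replicates,
                library_size=config.library_size, w=config.w,
                bm_rate=config.bm_rate, frac_generalist=config.frac_generalist,
                seed=_stage_seed(config, "inputs"))
            truth.to_csv(out / "truth.tsv", sep="\t")
            record("truth", out / "truth.tsv")
        else:
            table = read_count_table(config.table_path)
            tree = read_tree(config.tree_path)
            meta = read_metadata(config.metadata_path)
        write_count_table(table, out / "table.tsv")
        write_tree(tree, out / "tree.nwk")
        write_metadata(meta, out / "metadata.tsv")
        for n in ("table.tsv", "tree.nwk", "metadata.tsv"):
            record(n.split(".")[0], out / n)

    # -- preprocess --------------------------------------------------------
    with stage("preprocess"):
        depth = config.rarefy_depth or int(table.sample_totals.min())
        rare = rarefy(table, depth, _stage_seed(config, "preprocess"))
        meta = meta.loc[rare.sample_ids]
        write_count_table(rare, out / "table_rarefied.tsv")
        record("table_rarefied", out / "table_rarefied.tsv")

    # -- niche classification ---------------------------------------------
    with stage("classify"):
        env_of = {s: s for s in rare.sample_ids}
        obs = niche.niche_indices(rare, env_of)
        null = niche.permutation_null(rare, env_of, n_perm=config.n_perm_niche,
                                      seed=_stage_seed(config, "classify"))
        profiles = niche.classify_taxa(obs, null, alpha=config.alpha,
                                       mode=config.niche_mode)
        profiles.to_csv(out / "niche_profiles.tsv", sep="\t")
        record("niche_profiles", out / "niche_profiles.tsv")
        labels = profiles["label"].to_dict()

    # -- assembly ----------------------------------------------------------
    with stage("assembly"):
        pairs = asm.pairwise_assembly(rare, tree, n_null=config.n_null_assembly,
                                      seed=_stage_seed(config, "assembly"))
        pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        record("assembly_pairs", out / "assembly_pairs.tsv")
        summ_all = asm.summarize_processes(pairs, group_by="all")
        summ_cat = asm.summarize_processes(pairs, meta=meta,
                                           group_by="salinity_category")
        summ = pd.concat([summ_all, summ_cat])
        summ.to_csv(out / "assembly_summary.tsv", sep="\t", index=False)
        record("assembly_summary", out / "assembly_summary.tsv")

    # -- diversity ---------------------------------------------------------
    with stage("diversity"):
        seed_div = _stage_seed(config, "diversity")
        bc = dv.bray_curtis(rare)
        cont_terms = ["salinity", "organic_matter", "dissolved_oxygen",
                      "temperature", "ph"]
        perma_cont = dv.permanova(bc, meta, cont_terms,
                                  n_perm=config.n_perm_permanova, seed=seed_div)
        perma_fact = dv.permanova(
            bc, meta, ["salinity_category", "season",
                       "salinity_category:season"],
            n_perm=config.n_perm_permanova, seed=seed_div)
        perma_cont.to_csv(out / "permanova_continuous.tsv", sep="\t")
        perma_fact.to_csv(out / "permanova_factorial.tsv", sep="\t")
        alpha_df = dv.alpha_diversity(table, tree)
        alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t")
        season_of = meta["season"].to_dict()
        ddr_geo = dv.distance_decay(bc, dv.geographic_distance(meta), season_of)
        ddr_sal = dv.distance_decay(bc, dv.salinity_distance(meta), season_of)
        ddr_geo.insert(0, "predictor", "geographic_km")
        ddr_sal.insert(0, "predictor", "salinity_euclidean")
        pd.concat([ddr_geo, ddr_sal]).to_csv(out / "distance_decay.tsv",
                                             sep="\t", index=False)
        for n in ("permanova_continuous", "permanova_factorial",
                  "alpha_diversity", "distance_decay"):
            record(n, out / f"{n}.tsv")

    # -- networks per salinity category -------------------------------------
    with stage("network"):
        seed_net = _stage_seed(config, "network")
        topo_all = {}
        for cat in SALINITY_CATEGORIES:
            n_cat = int((meta["salinity_category"] == cat).sum())
            if n_cat < 8:
                warnings.warn(f"category {cat!r} has {n_cat} samples (< 8); "
                              "network skipped")
                continue
            sub = net.subnetwork_by_category(
                table, meta, cat, min_rel_abund=config.network_min_rel_abund)
            clr = net.clr_transform(sub)
            G = net.infer_network(clr, stars_threshold=config.stars_threshold,
                                  stars_reps=config.stars_reps, seed=seed_net)
            net.write_edge_list(G, out / f"network_edges_{cat}.tsv")
            record(f"network_edges_{cat}", out / f"network_edges_{cat}.tsv")
            topo_all[cat] = net.topology_summary(G, labels)
        with open(out / "network_topology.json", "w") as fh:
            json.dump(topo_all, fh, indent=2, default=float)
        record("network_topology", out / "network_topology.json")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stage_seconds": timers,
        "artifacts": {k: {"path": v, "sha256": _sha256(Path(v))}
                      for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
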