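"""End-to-end pipeline: prep -> diversity -> indicators -> assembly ->
per-subset networks -> robustness, with TSV outputs and a JSON manifest.

Diversity and assembly stages run on counts rarefied to a common depth;
network stages run on relative abundances of the unrarefied (depth-filtered)
counts. Identical config + seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import assembly as asm
from . import diversity as dv
from . import indicator as ind
from . import network as net
from . import robustness as rb
from .core import (CommunityMatrix, SampleMetadata, TaxonomyTable,
                   filter_low_depth, load_community_matrix, load_metadata,
                   load_taxonomy, load_tree, rarefy, to_relative)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat run configuration; defaults follow the study protocol."""

    counts: str = ""
    metadata: str = ""
    taxonomy: str = ""
    tree: str = ""
    outdir: str = "phyllonet_out"
    min_reads: int = 500
    rarefy_depth: int = 514
    min_abund: float = 0.0005
    p_thresh: float = 0.01
    q_thresh: float = 0.05
    n_null_beta_nti: int = 999
    n_null_rc: int = 1000
    n_perm_indval: int = 1000
    n_perm_permanova: int = 999
    robustness_step: float = 0.1
    robustness_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.robustness_step <= 0.5:
            raise ValueError("robustness_step must be in (0, 0.5]")
        for name in ("min_reads", "rarefy_depth", "n_null_beta_nti", "n_null_rc",
                     "n_perm_indval", "n_perm_permanova", "robustness_reps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f'{f.name} = "{v}"' if isinstance(v, str) else f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(dataclasses.asdict(self),
                                         sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    stages: list[str] = field(default_factory=list)
    tables: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)


def _seed_for(cfg: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    s = int.from_bytes(h[:4], "big") % (2**31)
    logger.info("stage %s uses derived seed %d", stage, s)
    return s


def run_pipeline(cfg: PipelineConfig,
                 data: tuple | None = None) -> PipelineResult:
    """Execute all stages; ``data`` may inject in-memory
    (counts, metadata, tree, taxonomy) instead of reading cfg paths."""
    res = PipelineResult(cfg)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- prep -------------------------------------------------------------
    try:
        if data is not None:
            counts, metadata, tree, taxonomy = data
        else:
            counts = load_community_matrix(cfg.counts)
            metadata = load_metadata(cfg.metadata)
            taxonomy = load_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
            tree = load_tree(cfg.tree) if cfg.tree else None
        if tree is None:
            raise ValueError("a phylogeny is required for Faith PD, weighted "
                             "UniFrac and betaNTI; provide `tree`")
        deep = filter_low_depth(counts, cfg.min_reads)
        rare = rarefy(deep, cfg.rarefy_depth, _seed_for(cfg, "rarefy"))
        meta_r = metadata.aligned_to(rare)
    except Exception as exc:
        raise RuntimeError(f"stage prep failed: {exc}") from exc
    res.stages.append("prep")

    # --- diversity --------------------------------------------------------
    try:
        alpha = dv.alpha_diversity_table(rare, tree)
        bc = dv.bray_curtis_matrix(rare)
        wu = dv.weighted_unifrac_matrix(rare, tree)
        ord_bc = dv.pcoa(bc)
        tests = []
        for metric, d in (("bray_curtis", bc), ("weighted_unifrac", wu)):
            for factor in ("host", "habitat_size", "habitat_class"):
                labels = meta_r[factor].to_numpy()
                r = dv.permanova(d, labels, cfg.n_perm_permanova,
                                 _seed_for(cfg, f"permanova:{metric}:{factor}"))
                tests.append({"metric": metric, "factor": factor, "test": "permanova",
                              "statistic": r.statistic, "r2": r.r2, "p_value": r.p_value})
                r = dv.permdisp(d, labels, cfg.n_perm_permanova,
                                _seed_for(cfg, f"permdisp:{metric}:{factor}"))
                tests.append({"metric": metric, "factor": factor, "test": "permdisp",
                              "statistic": r.statistic, "r2": r.r2, "p_value": r.p_value})
        res.tables["alpha_diversity"] = alpha
        res.tables["braycurtis"] = dv.distance_matrix_to_frame(bc)
        res.tables["wunifrac"] = dv.distance_matrix_to_frame(wu)
        res.tables["pcoa"] = ord_bc.coordinates
        res.tables["beta_tests"] = pd.DataFrame(tests)
    except Exception as exc:
        raise RuntimeError(f"stage diversity failed: {exc}") from exc
    res.stages.append("diversity")

    # --- indicator --------------------------------------------------------
    try:
        iv = ind.indval(rare, meta_r["host"].to_numpy(), cfg.n_perm_indval,
                        _seed_for(cfg, "indval"))
        res.tables["indval"] = iv
        res.tables["host_specific"] = ind.host_specific_taxa(iv)
    except Exception as exc:
        raise RuntimeError(f"stage indicator failed: {exc}") from exc
    res.stages.append("indicator")

    # --- assembly ---------------------------------------------------------
    try:
        pairs = asm.pair_assembly_table(rare, tree, cfg.n_null_beta_nti,
                                        cfg.n_null_rc, _seed_for(cfg, "assembly"))
        res.tables["assembly_pairs"] = pairs
        res.tables["table1_process_fractions"] = asm.process_fractions(
            pairs, meta_r["habitat_size"])
    except Exception as exc:
        raise RuntimeError(f"stage assembly failed: {exc}") from exc
    res.stages.append("assembly")

    # --- networks per host x habitat_class --------------------------------
    try:
        meta_d = metadata.aligned_to(deep)
        topo_cols, roles_tables, key_tables = {}, {}, {}
        for host in sorted(meta_d["host"].unique()):
            for hclass in ("small", "large"):
                mask = ((meta_d["host"] == host) & (meta_d["habitat_class"] == hclass)).to_numpy()
                if mask.sum() < 5:
                    logger.warning("subset %s/%s has <5 samples; skipped", host, hclass)
                    continue
                name = f"{host}_{hclass}"
                sub = deep.select_samples(mask)
                network = net.build_network(sub, cfg.min_abund, cfg.p_thresh,
                                            cfg.q_thresh,
                                            seed=_seed_for(cfg, f"net:{name}"))
                res.networks[name] = network
                topo_cols[name] = net.topology(network)
                if network.n_edges:
                    roles = net.zi_pi(network)
                    roles_tables[name] = roles
                    key_tables[name] = key_species_table(network, roles)
        res.tables["table2_topology"] = pd.DataFrame(topo_cols)
        if len(res.networks) >= 2:
            res.tables["network_comparison"] = net.compare_networks(res.networks)
        key_tables = {k: v for k, v in key_tables.items() if not v.empty}
        res.tables["table3_key_species"] = (
            pd.concat(key_tables, names=["network"]) if key_tables
            else pd.DataFrame())
        res.tables["node_roles"] = (pd.concat(roles_tables, names=["network"])
                                    if roles_tables else pd.DataFrame())
        # cohesion: small vs large within each host
        coh_rows = []
        for host in sorted(meta_d["host"].unique()):
            mask = (meta_d["host"] == host).to_numpy()
            if mask.sum() < 5:
                continue
            sub = net.filter_taxa(deep.select_samples(mask), cfg.min_abund)
            coh = net.cohesion(sub, seed=_seed_for(cfg, f"cohesion:{host}"))
            labels = meta_d.loc[mask, "habitat_class"].to_numpy()
            test = net.cohesion_group_test(coh["samples"], labels,
                                           seed=_seed_for(cfg, f"cohtest:{host}"))
            coh_rows.append({"host": host, **test})
        res.tables["cohesion_tests"] = pd.DataFrame(coh_rows)
    except Exception as exc:
        raise RuntimeError(f"stage network failed: {exc}") from exc
    res.stages.append("network")

    # --- robustness -------------------------------------------------------
    try:
        curves = {}
        for name, network in res.networks.items():
            if network.n_edges == 0:
                continue
            roles = roles_tables.get(name)
            strategies = list(rb.STRATEGIES)
            if roles is None or not (roles["role"] == "module_hub").any():
                strategies.remove("node_hub")
            curves[name] = rb.robustness_curves(
                network.graph, strategies, step=cfg.robustness_step,
                n_replicates=cfg.robustness_reps,
                seed=_seed_for(cfg, f"robustness:{name}"), roles=roles)
        res.tables["robustness"] = (pd.concat(curves, names=["network"])
                                    if curves else pd.DataFrame())
    except Exception as exc:
        raise RuntimeError(f"stage robustness failed: {exc}") from exc
    res.stages.append("robustness")

    emit_tables(res, out)
    res.stages.append("report")
    manifest = {"stages": res.stages, "seed": cfg.seed,
                "config_hash": cfg.digest(),
                "config": dataclasses.asdict(cfg)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return res


def key_species_table(network: net.CoNetwork, roles: pd.DataFrame) -> pd.DataFrame:
    """Table-3 style report for module hubs: centralities, abundance,
    module and Z-value (unweighted graph)."""
    hubs = roles.index[roles["role"] == "module_hub"]
    g = network.graph
    if len(hubs) == 0:
        return pd.DataFrame(columns=["degree", "betweenness", "closeness",
                                     "eigenvector", "abundance", "module", "z_value"])
    btw = nx.betweenness_centrality(g)
    cls = nx.closeness_centrality(g)
    try:
        eig = nx.eigenvector_centrality_numpy(g)
    except Exception:
        eig = dict.fromkeys(g, float("nan"))
    rows = {}
    for n in hubs:
        rows[n] = {"degree": g.degree(n), "betweenness": btw[n], "closeness": cls[n],
                   "eigenvector": eig[n],
                   "abundance": g.nodes[n].get("mean_rel_abund", float("nan")),
                   "module": f"M{roles.loc[n, 'module']}",
                   "z_value": roles.loc[n, "zi"]}
    return pd.DataFrame.from_dict(rows, orient="index").sort_values(
        "z_value", ascending=False)


def emit_tables(res: PipelineResult, outdir: str | Path) -> None:
    """Write every result table as TSV under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in res.tables.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(out / f"{name}.tsv", sep="\t")
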