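"""Synthetic metacommunity generator.

Emulates the structure of a host-associated nifH ASV survey: two liverwort
host species sampled across four habitat sizes, a shared regional species
pool with log-normal abundances, a pure-birth phylogeny, and host/habitat
selection acting on traits that evolve by Brownian motion on that tree (so
selection regimes leave a phylogenetic signal detectable by betaNTI).

Local communities mix the selected regional pool (weight ``m``, dispersal
mixing) with a site-local pool perturbed by repeated neutral multinomial
resampling (ecological drift, Hubbell-style). Reads are drawn multinomially
at log-normal depths. A fraction ``f`` of taxa can be planted as
host-specific indicators: zero expected abundance in the wrong host,
boosted abundance in the target host, and genus labels forming one block
per host (a "Hassallia"-like block for host A, "Fischerella"-like for
host B).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import (HABITAT_SIZES, CommunityMatrix, SampleMetadata, TaxonomyTable)

HOST_A = "C_surinamensis"
HOST_B = "R_flaccida"

#: genus labels for the planted host-specific blocks and the background pool
INDICATOR_GENUS = {HOST_A: "Hassallia", HOST_B: "Fischerella"}
BACKGROUND_GENERA = ("Nostoc", "Brasilonema", "Stigonema", "Tolypothrix",
                     "Calothrix", "Scytonema", "Anabaena", "Desmonostoc")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults are the scaled-down study layout
    (2 hosts x 4 habitat sizes x 5 samples = 40 samples, 300 taxa)."""

    n_taxa: int = 300
    samples_per_cell: int = 5
    hosts: tuple[str, str] = (HOST_A, HOST_B)
    habitat_sizes: tuple[str, ...] = HABITAT_SIZES
    # regional pool: log-normal abundance spectrum over taxa
    pool_mu: float = 0.0
    pool_sigma: float = 1.5
    # Brownian-motion rate for the host / habitat affinity traits
    trait_bm_rate: float = 1.0
    # selection strength s >= 0: weight = pool * exp(-s/2 * (trait-opt)^2)
    selection_strength: float = 0.0
    host_optima: tuple[float, float] = (1.5, -1.5)
    habitat_optima: dict = field(default_factory=lambda: dict.fromkeys(HABITAT_SIZES, 0.0))
    # dispersal mixing m in [0,1]: fraction of each local community drawn
    # from the shared regional (selected) pool vs the site-local drifted pool
    dispersal_mixing: float = 1.0
    drift_steps: int = 0
    drift_pool_size: int = 2000
    # read-depth model (log-normal, clipped)
    depth_mean: float = 7000.0
    depth_sigma: float = 1.0
    depth_min: int = 500
    depth_max: int = 41000
    # planted indicators; pool abundance of planted taxa is floored at the
    # pool median before boosting so indicators are detectable in principle
    host_specific_fraction: float = 0.0
    indicator_boost: float = 20.0
    # co-fluctuating clade blocks: per sample each block's weight is scaled
    # by exp(N(0, block_sd^2)), planting positive co-occurrence modules
    covariance_blocks: int = 0
    block_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dispersal_mixing <= 1.0:
            raise ValueError("dispersal_mixing must be in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if not 0.0 <= self.host_specific_fraction <= 1.0:
            raise ValueError("host_specific_fraction must be in [0, 1]")
        if 0 < self.host_specific_fraction and self.host_specific_fraction * self.n_taxa < 1:
            raise ValueError("host_specific_fraction * n_taxa < 1: no indicator can be planted")
        if self.drift_steps < 0:
            raise ValueError("drift_steps must be >= 0")


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule, rate 1) ultrametric tree with ``n_taxa`` tips.

    Tip names are ``t0000 .. t{n-1}``; reproducible under ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    root.birth = 0.0
    t = 0.0
    active = [root]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(rng.integers(k))
        node.length = t - node.birth
        for _ in range(2):
            child = TreeNode()
            child.birth = t
            node.append(child)
            active.append(child)
    t += rng.exponential(1.0 / n_taxa)  # stem time for the final tips
    for i, tip in enumerate(active):
        tip.length = t - tip.birth
        tip.name = f"t{i:04d}"
    for node in root.traverse(include_self=True):
        if hasattr(node, "birth"):
            del node.birth
    root.length = None
    return root


def brownian_trait(tree: TreeNode, rate: float, rng: np.random.Generator) -> dict[str, float]:
    """Trait values at the tips after Brownian motion from a root value of 0."""
    values: dict[int, float] = {id(tree): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        v = parent_val + rng.normal(0.0, np.sqrt(rate * max(node.length or 0.0, 0.0)))
        values[id(node)] = v
        if node.is_tip():
            out[node.name] = v
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _drift(pool: np.ndarray, steps: int, n_ind: int, rng: np.random.Generator) -> np.ndarray:
    """Neutral drift: repeated multinomial resampling of a finite community."""
    p = pool
    for _ in range(steps):
        draw = rng.multinomial(n_ind, p)
        tot = draw.sum()
        if tot == 0:
            break
        p = draw / tot
    return p


def simulate_metacommunity(p: SimulationParams
                           ) -> tuple[CommunityMatrix, SampleMetadata, TreeNode, TaxonomyTable]:
    """Draw one metacommunity: counts, metadata, tree and taxonomy."""
    ss = np.random.SeedSequence(p.seed)
    s_tree, s_trait, s_comm = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    tree = simulate_tree(p.n_taxa, s_tree)
    taxa = tuple(t.name for t in tree.tips())
    rng_t = np.random.default_rng(s_trait)
    pool = rng_t.lognormal(p.pool_mu, p.pool_sigma, size=p.n_taxa)
    pool /= pool.sum()
    order = {t: i for i, t in enumerate(taxa)}
    z_map = brownian_trait(tree, p.trait_bm_rate, rng_t)   # host-affinity trait
    w_map = brownian_trait(tree, p.trait_bm_rate, rng_t)   # habitat-affinity trait
    z = _standardize(np.array([z_map[t] for t in taxa]))
    w = _standardize(np.array([w_map[t] for t in taxa]))

    # planted indicators: the most host-A-like / host-B-like taxa by trait,
    # which Brownian motion keeps phylogenetically clustered
    indicator_host = np.full(p.n_taxa, "", dtype=object)
    if p.host_specific_fraction > 0:
        k = max(1, round(p.host_specific_fraction * p.n_taxa))
        k_a = (k + 1) // 2
        k_b = k - k_a
        by_z = np.argsort(z)
        indicator_host[by_z[::-1][:k_a]] = p.hosts[0]
        if k_b:
            indicator_host[by_z[:k_b]] = p.hosts[1]

    rng = np.random.default_rng(s_comm)
    host_opt = dict(zip(p.hosts, p.host_optima))
    # co-fluctuation blocks: contiguous runs of tips (clade-ish in tree order)
    block_of = covariance_block_assignment(p)
    rows, sample_ids, meta_rows = [], [], []
    s = p.selection_strength
    pool_floor = np.median(pool)
    for host in p.hosts:
        for size in p.habitat_sizes:
            base = pool.copy()
            planted = indicator_host != ""
            # common planted abundance keeps the planted mass balanced across
            # hosts, so background taxa are not compositionally distorted
            base[planted & (indicator_host == host)] = pool_floor * p.indicator_boost
            weight = base * np.exp(-0.5 * s * (z - host_opt[host]) ** 2
                                   - 0.5 * s * (w - p.habitat_optima[size]) ** 2)
            weight[planted & (indicator_host != host)] = 0.0
            selected = weight / weight.sum()
            for rep in range(p.samples_per_cell):
                site = f"{host}_{size}_s{rep}"
                local = _drift(selected, p.drift_steps, p.drift_pool_size, rng)
                expected = p.dispersal_mixing * selected + (1 - p.dispersal_mixing) * local
                if block_of is not None:
                    expected = expected * np.exp(rng.normal(0.0, p.block_sd,
                                                            p.covariance_blocks))[block_of]
                    expected = expected / expected.sum()
                depth = int(np.clip(rng.lognormal(np.log(p.depth_mean) - p.depth_sigma**2 / 2,
                                                  p.depth_sigma),
                                    p.depth_min, p.depth_max))
                rows.append(rng.multinomial(depth, expected))
                sid = f"{host}_{size}_{rep:02d}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "host": host,
                                  "habitat_size": size, "site": site})

    counts = CommunityMatrix(tuple(sample_ids), taxa, np.array(rows, dtype=float))
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    taxonomy = _make_taxonomy(taxa, indicator_host, z, order, p)
    return counts, metadata, tree, taxonomy


def covariance_block_assignment(p: SimulationParams) -> np.ndarray | None:
    """Block index per taxon (tree tip order), or None when no blocks."""
    if p.covariance_blocks <= 0:
        return None
    return np.repeat(np.arange(p.covariance_blocks),
                     -(-p.n_taxa // p.covariance_blocks))[:p.n_taxa]


def _make_taxonomy(taxa, indicator_host, z, order, p: SimulationParams) -> TaxonomyTable:
    # indicator blocks get one genus per host; background taxa are binned
    # along the host-affinity trait so genera are phylogenetically coherent
    genera = []
    edges = np.quantile(z, np.linspace(0, 1, len(BACKGROUND_GENERA) + 1))
    for i, t in enumerate(taxa):
        if indicator_host[i]:
            genera.append(INDICATOR_GENUS.get(indicator_host[i], "Indicator"))
        else:
            b = int(np.clip(np.searchsorted(edges, z[i], side="right") - 1,
                            0, len(BACKGROUND_GENERA) - 1))
            genera.append(BACKGROUND_GENERA[b])
    df = pd.DataFrame({
        "taxon_id": taxa,
        "phylum": "Cyanobacteria",
        "class": "Cyanophyceae",
        "order": "Nostocales",
        "family": [g + "ceae" for g in genera],
        "genus": genera,
    }).set_index("taxon_id")
    return TaxonomyTable(df)


#: named parameter presets for the five assembly regimes. The preset is the
#: regime definition: e.g. homogenizing dispersal is full mixing with no
#: selection, so every sample draws from one shared pool at high depth.
_SCENARIOS = {
    "homogenizing_dispersal": dict(dispersal_mixing=1.0, selection_strength=0.0,
                                   drift_steps=0),
    "variable_selection": dict(dispersal_mixing=1.0, selection_strength=6.0,
                               drift_steps=0,
                               host_optima=(1.5, -1.5),
                               habitat_optima={"1-ha": 1.5, "10-ha": 1.5,
                                               "100-ha": -1.5, "continuous": -1.5}),
    # homogeneous selection needs membership turnover (drift) so that the
    # shared phylogenetic constraint is visible against the tip-shuffle null,
    # and an extreme shared optimum so the selected taxa form one clade
    # (mid-trait taxa are polyphyletic under Brownian motion)
    "homogeneous_selection": dict(dispersal_mixing=0.3, selection_strength=6.0,
                                  drift_steps=20, host_optima=(1.5, 1.5),
                                  habitat_optima=dict.fromkeys(HABITAT_SIZES, 1.5)),
    "dispersal_limitation": dict(dispersal_mixing=0.02, selection_strength=0.0,
                                 drift_steps=60, drift_pool_size=500),
    "drift": dict(dispersal_mixing=0.2, selection_strength=0.0, drift_steps=6),
}


def scenario(name: str, seed: int = 0, **overrides) -> SimulationParams:
    """Parameter preset for a named assembly regime.

    ``homogenizing_dispersal`` -> m = 1, s = 0 (one shared pool);
    ``variable_selection`` -> strong selection towards opposite trait optima
    between habitat classes (and hosts); ``homogeneous_selection`` -> strong
    selection towards one common optimum; ``dispersal_limitation`` -> m near
    0 with long site-local drift; ``drift`` -> m small, s = 0, moderate
    drift.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {sorted(_SCENARIOS)}")
    kwargs = dict(_SCENARIOS[name])
    kwargs.update(overrides)
    return SimulationParams(seed=seed, **kwargs)
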