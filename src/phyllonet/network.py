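"""Co-occurrence network construction and analysis.

Edges are Spearman rank correlations between taxa passing an abundance
filter (mean relative abundance >= 0.05% by default); an edge is retained
when its two-sided p < 0.01 and its Benjamini-Hochberg q < 0.05 (and
optionally |rho| above a random-matrix-theory threshold). Node roles come
from the Zi-Pi plane (within-module degree z-score vs among-module
connectivity); community cohesion summarises sample-level connectivity via
null-corrected correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CommunityMatrix, to_relative

logger = logging.getLogger(__name__)

ROLE_ZI = 2.5
ROLE_PI = 0.65


@dataclass
class CoNetwork:
    """Signed weighted undirected co-occurrence graph over taxa."""

    graph: nx.Graph
    partition: dict = field(default_factory=dict)
    modularity: float = float("nan")
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def filter_taxa(m: CommunityMatrix, min_mean_rel: float = 0.0005) -> CommunityMatrix:
    """Keep taxa whose mean relative abundance is >= ``min_mean_rel``."""
    rel = to_relative(m)
    keep = rel.counts.mean(axis=0) >= min_mean_rel
    if not keep.any():
        raise ValueError(f"no taxon reaches mean relative abundance {min_mean_rel}")
    return m.select_taxa(keep)


def spearman_edges(m: CommunityMatrix, p_thresh: float = 0.01, q_thresh: float = 0.05,
                   min_rho: float = 0.0) -> pd.DataFrame:
    """All-pairs Spearman correlations with BH-FDR edge calling.

    Returns the full tested-pair table with columns ``taxon_a, taxon_b,
    rho, p, q, sign, kept``; constant taxa are skipped with a warning.
    """
    if m.n_samples < 5:
        raise ValueError("need at least 5 samples for rank correlation")
    x = to_relative(m).counts
    variable = x.std(axis=0) > 0
    if not variable.all():
        logger.warning("%d constant taxa skipped (rho undefined)", int((~variable).sum()))
    idx = np.flatnonzero(variable)
    if idx.size < 2:
        raise ValueError("fewer than 2 non-constant taxa")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x[:, idx])
    if idx.size == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    pairs = list(combinations(range(idx.size), 2))
    rows = []
    for a, b in pairs:
        rows.append((m.taxon_ids[idx[a]], m.taxon_ids[idx[b]], rho[a, b], p[a, b]))
    out = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p"])
    out = out.dropna(subset=["rho", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["sign"] = np.sign(out["rho"]).astype(int)
    out["kept"] = (out["p"] < p_thresh) & (out["q"] < q_thresh) & (out["rho"].abs() >= min_rho)
    return out


def spearman_matrix(m: CommunityMatrix) -> pd.DataFrame:
    """Full Spearman correlation matrix over taxa (for RMT thresholding)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(to_relative(m).counts)
    rho = np.atleast_2d(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=list(m.taxon_ids), columns=list(m.taxon_ids))


# ---------------------------------------------------------------------------
# random-matrix-theory threshold

def _spacing_fit(eigs: np.ndarray) -> tuple[float, float] | None:
    """Chi-squared fit of nearest-neighbour spacings to Poisson vs
    Wigner-Dyson after local unfolding (spacings scaled to unit mean).

    Degenerate (repeated) eigenvalues give zero spacings, which the
    exponential accommodates and the Wigner surmise cannot — exactly the
    clustered spectrum of a modular thresholded matrix."""
    if eigs.size < 20:
        return None
    s = np.diff(np.sort(eigs))
    if s.mean() <= 1e-12 or np.allclose(s.std(), 0):
        return None
    s = s / s.mean()
    edges = np.append(np.arange(0.0, 3.0, 0.25), np.inf)
    obs, _ = np.histogram(s, bins=edges)
    n = s.size
    cdf_p = 1 - np.exp(-edges)                    # Poisson (exponential spacings)
    cdf_w = 1 - np.exp(-np.pi * edges ** 2 / 4)   # Wigner-Dyson surmise
    exp_p = np.diff(cdf_p) * n
    exp_w = np.diff(cdf_w) * n
    chi_p = float(np.sum((obs - exp_p) ** 2 / np.maximum(exp_p, 1e-9)))
    chi_w = float(np.sum((obs - exp_w) ** 2 / np.maximum(exp_w, 1e-9)))
    return chi_p, chi_w


def rmt_threshold(cor: pd.DataFrame | np.ndarray, t_min: float = 0.30,
                  t_max: float = 0.90, step: float = 0.01) -> float:
    """Smallest |rho| cutoff at which the thresholded correlation matrix's
    eigenvalue spacing follows Poisson statistics better than Wigner-Dyson.

    Returns ``t_max`` with a warning when the scan finds no transition.
    """
    c = np.asarray(cor, dtype=float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    for t in np.arange(t_min, t_max + step / 2, step):
        a = np.where(np.abs(c) >= t, c, 0.0)
        np.fill_diagonal(a, 1.0)
        fit = _spacing_fit(np.linalg.eigvalsh(a))
        if fit is not None and fit[0] < fit[1]:
            return round(float(t), 10)
    logger.warning("RMT scan found no Poisson transition in [%.2f, %.2f]; "
                   "returning upper bound", t_min, t_max)
    return t_max


# ---------------------------------------------------------------------------
# graph construction, modules, roles

def build_network(m: CommunityMatrix, min_mean_rel: float = 0.0005,
                  p_thresh: float = 0.01, q_thresh: float = 0.05,
                  min_rho: float = 0.0, use_rmt: bool = False,
                  seed: int = 0) -> CoNetwork:
    """Filter taxa, call edges, build the signed graph, detect modules.

    Nodes are the taxa incident to at least one retained edge; node
    attribute ``mean_rel_abund`` stores the taxon's mean relative abundance.
    """
    filt = filter_taxa(m, min_mean_rel)
    if use_rmt:
        min_rho = max(min_rho, rmt_threshold(spearman_matrix(filt).to_numpy()))
    edges = spearman_edges(filt, p_thresh, q_thresh, min_rho)
    kept = edges[edges["kept"]]
    mean_rel = dict(zip(filt.taxon_ids, to_relative(filt).counts.mean(axis=0)))
    g = nx.Graph()
    for row in kept.itertuples():
        g.add_edge(row.taxon_a, row.taxon_b, weight=abs(row.rho),
                   sign=int(row.sign), rho=row.rho, p=row.p, q=row.q)
    nx.set_node_attributes(g, {n: mean_rel.get(n, 0.0) for n in g}, "mean_rel_abund")
    net = CoNetwork(g, provenance={"min_mean_rel": min_mean_rel, "p": p_thresh,
                                   "q": q_thresh, "min_rho": min_rho, "seed": seed})
    if g.number_of_edges():
        net.partition, net.modularity = detect_modules(net, seed=seed)
    return net


def detect_modules(net: CoNetwork, seed: int = 0) -> tuple[dict, float]:
    """Greedy modularity maximisation on the unsigned weighted graph.

    Returns (node -> module id, modularity Q). Deterministic for a given
    graph; ``seed`` is accepted for interface stability.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("cannot detect modules in an empty graph")
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    partition = {n: i for i, c in enumerate(comms) for n in sorted(c)}
    q = nx.community.modularity(g, comms, weight="weight")
    return partition, float(q)


def zi_pi(net: CoNetwork, partition: dict | None = None) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    Zi = (k_within - mean_module) / sd_module (0 for degenerate modules);
    Pi = 1 - sum_s (k_is / k_i)^2. Roles: module_hub (Zi > 2.5, Pi <= 0.65),
    network_hub (Zi > 2.5, Pi > 0.65), connector (Zi <= 2.5, Pi > 0.65),
    peripheral otherwise.
    """
    g = net.graph
    cols = ["module", "degree", "k_within", "zi", "pi", "role"]
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="node"))
    part = partition if partition is not None else net.partition
    missing = [n for n in g if n not in part]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    nodes = list(g.nodes)
    k_within = {}
    k_per_module: dict[str, dict] = {}
    for n in nodes:
        mod_counts: dict = {}
        for nb in g.neighbors(n):
            mod_counts[part[nb]] = mod_counts.get(part[nb], 0) + 1
        k_per_module[n] = mod_counts
        k_within[n] = mod_counts.get(part[n], 0)
    by_module: dict = {}
    for n in nodes:
        by_module.setdefault(part[n], []).append(k_within[n])
    stats_mod = {mo: (np.mean(v), np.std(v)) for mo, v in by_module.items()}
    rows = []
    for n in nodes:
        mu, sd = stats_mod[part[n]]
        zi = (k_within[n] - mu) / sd if sd > 0 else 0.0
        k = g.degree(n)
        pi = 1.0 - sum((c / k) ** 2 for c in k_per_module[n].values()) if k > 0 else 0.0
        if zi > ROLE_ZI:
            role = "module_hub" if pi <= ROLE_PI else "network_hub"
        else:
            role = "connector" if pi > ROLE_PI else "peripheral"
        rows.append({"node": n, "module": part[n], "degree": k,
                     "k_within": k_within[n], "zi": zi, "pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# topology, comparison, cohesion

def topology(net: CoNetwork) -> pd.Series:
    """Whole-network topological attributes (Table-2 style).

    Path length and diameter are unweighted and computed on the largest
    connected component; heterogeneity is the coefficient of variation of
    degree; centralization is Freeman degree centralization.
    """
    g = net.graph
    v, e = g.number_of_nodes(), g.number_of_edges()
    if v == 0:
        raise ValueError("empty network")
    degrees = np.array([d for _, d in g.degree()])
    comp = max(nx.connected_components(g), key=len)
    gc = g.subgraph(comp)
    apl = nx.average_shortest_path_length(gc) if len(comp) > 1 else 0.0
    diam = nx.diameter(gc) if len(comp) > 1 else 0
    if v > 2:
        centralization = float((degrees.max() - degrees).sum() / ((v - 1) * (v - 2)))
    else:
        logger.warning("centralization undefined for V < 3; reported as 0")
        centralization = 0.0
    out = {
        "vertices": v,
        "edges": e,
        "average_degree": 2 * e / v,
        "average_path_length": apl,
        "diameter": diam,
        "clustering_coefficient": nx.average_clustering(g),
        "density": 2 * e / (v * (v - 1)) if v > 1 else 0.0,
        "heterogeneity": float(degrees.std() / degrees.mean()) if degrees.mean() > 0 else 0.0,
        "centralization": centralization,
        "modularity": net.modularity,
    }
    if net.partition:
        roles = zi_pi(net)
        out["module_hubs"] = int((roles["role"] == "module_hub").sum())
        out["peripheral_nodes"] = int((roles["role"] == "peripheral").sum())
    return pd.Series(out)


def compare_networks(nets: dict[str, CoNetwork],
                     pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Unique / shared node and edge counts across named networks.

    Percentages use the total number of node (edge) instances summed over
    all compared networks as denominator.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to compare")
    node_sets = {k: set(n.graph.nodes) for k, n in nets.items()}
    edge_sets = {k: {frozenset(e) for e in n.graph.edges} for k, n in nets.items()}
    tot_nodes = sum(len(s) for s in node_sets.values())
    tot_edges = sum(len(s) for s in edge_sets.values())
    rows = []
    for k in nets:
        others_n = set().union(*(node_sets[o] for o in nets if o != k))
        others_e = set().union(*(edge_sets[o] for o in nets if o != k))
        un = len(node_sets[k] - others_n)
        ue = len(edge_sets[k] - others_e)
        rows.append({"comparison": f"unique:{k}", "nodes": un, "edges": ue,
                     "nodes_pct": 100 * un / max(tot_nodes, 1),
                     "edges_pct": 100 * ue / max(tot_edges, 1)})
    if pairs is None:
        keys = list(nets)
        pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]]
    for a, b in pairs:
        sn = len(node_sets[a] & node_sets[b])
        se = len(edge_sets[a] & edge_sets[b])
        rows.append({"comparison": f"shared:{a}|{b}", "nodes": sn, "edges": se,
                     "nodes_pct": 100 * sn / max(tot_nodes, 1),
                     "edges_pct": 100 * se / max(tot_edges, 1)})
    return pd.DataFrame(rows).set_index("comparison")


def cohesion(m: CommunityMatrix, n_null: int = 200, seed: int = 0) -> dict:
    """Community cohesion from null-corrected pairwise correlations.

    Each taxon's positive (negative) connectedness c+ (c-) is the mean of
    its positive (negative) null-corrected correlations with all other
    taxa; sample cohesion C+/- = sum_t r_st * c_t+/-. The null shuffles
    each taxon's abundances independently across samples.
    """
    if m.n_samples < 5:
        raise ValueError("cohesion needs at least 5 samples")
    x = to_relative(m).counts
    t = x.shape[1]

    def corr(mat):
        sd = mat.std(axis=0)
        ok = sd > 0
        c = np.zeros((t, t))
        if ok.sum() >= 2:
            sub = np.corrcoef(mat[:, ok], rowvar=False)
            c[np.ix_(ok, ok)] = np.nan_to_num(sub, nan=0.0)
        np.fill_diagonal(c, 0.0)
        return c

    obs = corr(x)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    for _ in range(n_null):
        shuffled = np.column_stack([rng.permutation(x[:, j]) for j in range(t)])
        null_sum += corr(shuffled)
    corrected = obs - null_sum / n_null
    np.fill_diagonal(corrected, 0.0)
    pos = np.where(corrected > 0, corrected, 0.0)
    neg = np.where(corrected < 0, corrected, 0.0)
    c_plus = pos.sum(axis=0) / max(t - 1, 1)
    c_minus = neg.sum(axis=0) / max(t - 1, 1)
    connectedness = pd.DataFrame({"c_plus": c_plus, "c_minus": c_minus},
                                 index=pd.Index(m.taxon_ids, name="taxon_id"))
    samples = pd.DataFrame({"cohesion_pos": x @ c_plus, "cohesion_neg": x @ c_minus},
                           index=pd.Index(m.sample_ids, name="sample_id"))
    return {"connectedness": connectedness, "samples": samples}


def cohesion_group_test(samples: pd.DataFrame, labels, column: str = "cohesion_pos",
                        n_perm: int = 999, seed: int = 0) -> dict:
    """Two-group permutation test on mean sample cohesion."""
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError("cohesion group test expects exactly 2 groups")
    vals = samples[column].to_numpy()
    obs = abs(vals[labels == names[0]].mean() - vals[labels == names[1]].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = labels[rng.permutation(len(labels))]
        if abs(vals[p == names[0]].mean() - vals[p == names[1]].mean()) >= obs:
            hits += 1
    return {"difference": float(obs), "p_value": (1 + hits) / (n_perm + 1)}


# ---------------------------------------------------------------------------
# optional bootstrap stability filtering

def bootstrap_edge_stability(m: CommunityMatrix, p_thresh: float = 0.01,
                             q_thresh: float = 0.05, min_rho: float = 0.0,
                             n_boot: int = 100, min_stability: float = 0.8,
                             seed: int = 0) -> pd.DataFrame:
    """Fraction of sample-bootstrap resamples in which each edge is called.

    Returns the full-data edge table with a ``stability`` column and
    ``kept`` further requiring stability >= ``min_stability``, plus a
    Brown-style combined p-value across resamples (Fisher statistic with an
    empirical scale correction for the dependence between resamples).
    """
    base = spearman_edges(m, p_thresh, q_thresh, min_rho)
    key = list(zip(base["taxon_a"], base["taxon_b"]))
    index = {k: i for i, k in enumerate(key)}
    called = np.zeros(len(base))
    logp = np.zeros((n_boot, len(base)))
    rng = np.random.default_rng(seed)
    for b in range(n_boot):
        take = rng.integers(0, m.n_samples, size=m.n_samples)
        boot = CommunityMatrix(tuple(f"b{j}" for j in range(m.n_samples)),
                               m.taxon_ids, m.counts[take], m.is_relative)
        try:
            eb = spearman_edges(boot, p_thresh, q_thresh, min_rho)
        except ValueError:
            continue
        for row in eb.itertuples():
            i = index.get((row.taxon_a, row.taxon_b))
            if i is None:
                i = index.get((row.taxon_b, row.taxon_a))
            if i is not None:
                called[i] += row.kept
                logp[b, i] = -2 * np.log(max(row.p, 1e-300))
    stability = called / n_boot
    fisher = logp.sum(axis=0)
    mean_x, var_x = fisher.mean(), fisher.var()
    if var_x > 0 and mean_x > 0:
        c = var_x / (2 * mean_x)
        df = 2 * mean_x ** 2 / var_x
        p_brown = stats.chi2.sf(fisher / c, df)
    else:
        p_brown = np.ones_like(fisher)
    out = base.copy()
    out["stability"] = stability
    out["p_brown"] = p_brown
    out["kept"] = out["kept"] & (out["stability"] >= min_stability)
    return out
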