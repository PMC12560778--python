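"""Null-model inference of community assembly processes.

Per sample pair the pipeline computes the abundance-weighted beta mean
nearest taxon distance (betaMNTD), its z-score against a tip-shuffle null
(betaNTI), and the Raup-Crick metric on Bray-Curtis distances (RCbray)
against a null that preserves each sample's richness and read total while
drawing taxa by regional occurrence frequency and filling reads by regional
relative abundance. Pairs are then classified into the five-process scheme:

* betaNTI > +2            -> variable selection
* betaNTI < -2            -> homogeneous selection
* |betaNTI| <= 2 and RCbray > +0.95 -> dispersal limitation
* |betaNTI| <= 2 and RCbray < -0.95 -> homogenizing dispersal
* otherwise               -> ecological drift

Boundary values (betaNTI exactly +/-2, RCbray exactly +/-0.95) fall on the
stochastic / drift side.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .core import CommunityMatrix, check_tree_covers, to_relative

logger = logging.getLogger(__name__)

PROCESSES = ("variable_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "drift")


def patristic_matrix(tree: TreeNode, taxon_ids) -> np.ndarray:
    """Tip-to-tip (patristic) distances ordered like ``taxon_ids``."""
    check_tree_covers(tree, taxon_ids)
    dm = tree.tip_tip_distances()
    idx = [dm.index(t) for t in taxon_ids]
    return dm.data[np.ix_(idx, idx)]


def _communities(m: CommunityMatrix, abundance_weighted: bool
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    rel = to_relative(m)
    present, freqs = [], []
    for row in rel.counts:
        idx = np.flatnonzero(row > 0)
        if idx.size == 0:
            raise ValueError("community with zero taxa")
        present.append(idx)
        if abundance_weighted:
            f = row[idx]
            freqs.append(f / f.sum())
        else:
            freqs.append(np.full(idx.size, 1.0 / idx.size))
    return present, freqs


def _pairwise_bmntd(dist: np.ndarray, present, freqs) -> np.ndarray:
    n = len(present)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        sub = dist[np.ix_(present[i], present[j])]
        v = 0.5 * (freqs[i] @ sub.min(axis=1) + freqs[j] @ sub.min(axis=0))
        out[i, j] = out[j, i] = v
    return out


def beta_mntd(m: CommunityMatrix, tree: TreeNode,
              abundance_weighted: bool = True) -> DistanceMatrix:
    """Between-community mean nearest-taxon phylogenetic distance.

    betaMNTD(A,B) = 1/2 [ sum_i f_iA min_j D_ij + sum_j f_jB min_i D_ij ]
    with f the within-community relative abundances (or equal weights in
    unweighted mode) and D the patristic distance.
    """
    dist = patristic_matrix(tree, m.taxon_ids)
    present, freqs = _communities(m, abundance_weighted)
    return DistanceMatrix(_pairwise_bmntd(dist, present, freqs), ids=list(m.sample_ids))


def beta_nti(m: CommunityMatrix, tree: TreeNode, n_null: int = 999, seed: int = 0,
             abundance_weighted: bool = True) -> pd.DataFrame:
    """betaNTI z-scores: (obs - null mean) / null sd under a tip-shuffle null.

    Each null replicate permutes taxon labels across the whole phylogeny
    (rows/columns of the patristic matrix). A degenerate null (sd = 0, e.g.
    a star tree) yields betaNTI = 0.
    """
    if n_null < 99:
        raise ValueError("n_null < 99 gives unstable z-scores")
    dist = patristic_matrix(tree, m.taxon_ids)
    present, freqs = _communities(m, abundance_weighted)
    obs = _pairwise_bmntd(dist, present, freqs)
    rng = np.random.default_rng(seed)
    n = m.n_samples
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for _ in range(n_null):
        perm = rng.permutation(m.n_taxa)
        null = _pairwise_bmntd(dist[np.ix_(perm, perm)], present, freqs)
        acc += null
        acc2 += null ** 2
    mean = acc / n_null
    var = np.clip(acc2 / n_null - mean ** 2, 0.0, None)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    np.fill_diagonal(z, 0.0)
    # z-score matrices are signed; wrap symmetric values without the
    # DistanceMatrix non-negativity constraint
    return pd.DataFrame(z, index=list(m.sample_ids), columns=list(m.sample_ids))


def _null_community(rng, richness, depth, occ_w, abund_w) -> np.ndarray:
    """One Stegen-style null assembly: pick ``richness`` taxa by occurrence
    weight, seed each with one read, fill to ``depth`` by abundance weight."""
    n = occ_w.size
    richness = min(richness, int((occ_w > 0).sum()))
    # Efraimidis-Spirakis weighted sampling without replacement via Gumbel keys
    with np.errstate(divide="ignore"):
        keys = np.log(occ_w) + rng.gumbel(size=n)
    chosen = np.argpartition(-keys, richness - 1)[:richness]
    counts = np.zeros(n)
    counts[chosen] = 1
    remaining = depth - richness
    if remaining > 0:
        w = abund_w[chosen]
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def raup_crick_bray(m: CommunityMatrix, n_null: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Raup-Crick standardized Bray-Curtis, in [-1, 1].

    RC = 2 [ #(null < obs) + 0.5 #(null = obs) ] / n_null - 1; null pairs
    share the draw of one null community per sample per replicate.
    """
    counts = np.rint(m.counts).astype(np.int64)
    if not np.allclose(counts, m.counts):
        raise ValueError("raup_crick_bray requires integer counts (rarefied reads)")
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("sample with zero total reads")
    richness = (counts > 0).sum(axis=1)
    occ_w = (counts > 0).sum(axis=0).astype(float)
    abund_w = counts.sum(axis=0).astype(float)

    rel = counts / totals[:, None]
    n = m.n_samples
    iu = np.triu_indices(n, 1)
    obs = np.zeros((n, n))
    for i in range(n):
        obs[i, i + 1:] = np.abs(rel[i + 1:] - rel[i]).sum(axis=1) / 2.0
    obs_c = obs[iu]

    rng = np.random.default_rng(seed)
    less = np.zeros_like(obs_c)
    equal = np.zeros_like(obs_c)
    for _ in range(n_null):
        null_rel = np.empty_like(rel)
        for s in range(n):
            c = _null_community(rng, int(richness[s]), int(totals[s]), occ_w, abund_w)
            null_rel[s] = c / c.sum()
        nb = np.empty_like(obs_c)
        k = 0
        for i in range(n):
            span = n - i - 1
            nb[k:k + span] = np.abs(null_rel[i + 1:] - null_rel[i]).sum(axis=1) / 2.0
            k += span
        less += nb < obs_c - 1e-12
        equal += np.abs(nb - obs_c) <= 1e-12
    rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    out = np.zeros((n, n))
    out[iu] = rc
    out = out + out.T
    return pd.DataFrame(out, index=list(m.sample_ids), columns=list(m.sample_ids))


def classify_processes(beta_nti_value: float, rc_bray_value: float) -> str:
    """Five-way assembly-process label from (betaNTI, RCbray)."""
    b, r = float(beta_nti_value), float(rc_bray_value)
    if np.isnan(b) or np.isnan(r):
        raise ValueError("NaN input to classify_processes")
    if b > 2:
        return "variable_selection"
    if b < -2:
        return "homogeneous_selection"
    if r > 0.95:
        return "dispersal_limitation"
    if r < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def pair_assembly_table(m: CommunityMatrix, tree: TreeNode, n_null_bnti: int = 999,
                        n_null_rc: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-pair betaMNTD, betaNTI, RCbray and process label (long format)."""
    bm = beta_mntd(m, tree)
    bn = beta_nti(m, tree, n_null=n_null_bnti, seed=seed)
    rc = raup_crick_bray(m, n_null=n_null_rc, seed=seed + 1)
    rows = []
    ids = list(m.sample_ids)
    for i, j in combinations(range(len(ids)), 2):
        b = bn.iloc[i, j]
        r = rc.iloc[i, j]
        rows.append({"sample_i": ids[i], "sample_j": ids[j],
                     "beta_mntd_obs": bm[ids[i], ids[j]],
                     "beta_nti": b, "rc_bray": r,
                     "process": classify_processes(b, r)})
    return pd.DataFrame(rows)


def process_fractions(pairs: pd.DataFrame, groups: dict | pd.Series) -> pd.DataFrame:
    """Percentage of within-group pairs assigned to each process.

    ``groups`` maps sample id -> habitat group. Only pairs whose two samples
    share a group count; groups contributing fewer than 2 samples are
    omitted with a warning. Columns sum to 100; a final ``n_samples`` row
    records the group sizes.
    """
    groups = dict(groups)
    gi = pairs["sample_i"].map(groups)
    gj = pairs["sample_j"].map(groups)
    within = pairs[gi.notna() & (gi == gj)].assign(group=gi)
    cols = {}
    sizes = pd.Series(groups).value_counts()
    for g in sorted(sizes.index):
        if sizes[g] < 2:
            logger.warning("group %r has < 2 samples; omitted from fraction table", g)
            continue
        sub = within[within["group"] == g]
        frac = sub["process"].value_counts(normalize=True) * 100.0
        cols[g] = [frac.get(pr, 0.0) for pr in PROCESSES] + [int(sizes[g])]
    out = pd.DataFrame(cols, index=list(PROCESSES) + ["n_samples"])
    out.index.name = "process"
    return out
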