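"""Alpha/beta diversity, ordination and permutation tests.

Alpha diversity follows the Hill-number family (observed richness,
exp-Shannon, inverse Simpson) plus bias-corrected Chao1 and Faith
phylogenetic diversity. Beta diversity covers Bray-Curtis and normalized
weighted UniFrac; ordination is classical PCoA (Gower double-centering);
group tests are distance-based PERMANOVA and PERMDISP with add-one
permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .core import CommunityMatrix, check_tree_covers, to_relative

__all__ = [
    "chao1", "hill_shannon", "hill_simpson", "faith_pd", "alpha_diversity_table",
    "bray_curtis", "bray_curtis_matrix", "weighted_unifrac", "weighted_unifrac_matrix",
    "pcoa", "PcoaResult", "permanova", "permanova_pairwise", "permdisp", "PermTestResult",
]


# ---------------------------------------------------------------------------
# alpha diversity

def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts; requires integer read counts
    (undefined on proportions).
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("negative counts")
    if not np.allclose(c, np.rint(c)):
        raise ValueError("Chao1 requires integer counts, not proportions")
    c = np.rint(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _as_proportions(vec) -> np.ndarray:
    p = np.asarray(vec, dtype=float)
    tot = p.sum()
    if tot <= 0:
        raise ValueError("zero-sum abundance vector")
    return p / tot


def hill_shannon(rel) -> float:
    """Hill number of order 1: exp(-sum p ln p)."""
    p = _as_proportions(rel)
    p = p[p > 0]
    return float(np.exp(-np.sum(p * np.log(p))))


def hill_simpson(rel) -> float:
    """Hill number of order 2: inverse Simpson concentration, 1 / sum p^2."""
    p = _as_proportions(rel)
    return float(1.0 / np.sum(p ** 2))


def faith_pd(present_taxa, tree: TreeNode) -> float:
    """Sum of branch lengths of the minimal subtree spanning the present
    taxa and the root."""
    present = set(present_taxa)
    if not present:
        return 0.0
    check_tree_covers(tree, present)
    total = 0.0
    has_present: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            hit = node.name in present
        else:
            hit = any(has_present[id(c)] for c in node.children)
        has_present[id(node)] = hit
        if hit and node.parent is not None:
            total += node.length or 0.0
    return total


def alpha_diversity_table(m: CommunityMatrix, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample S_obs, Chao1, Hill-Shannon, Hill-Simpson and (with a tree)
    Faith PD."""
    rows = []
    for i, sid in enumerate(m.sample_ids):
        c = m.counts[i]
        row = {
            "sample_id": sid,
            "observed_richness": int((c > 0).sum()),
            "chao1": chao1(c) if not m.is_relative else np.nan,
            "hill_shannon": hill_shannon(c),
            "hill_simpson": hill_simpson(c),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd([t for t, x in zip(m.taxon_ids, c) if x > 0], tree)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(m: CommunityMatrix) -> DistanceMatrix:
    rel = to_relative(m)
    x = rel.counts
    # pairwise sum|xi-xj| / sum(xi+xj); row sums are 1 so denominator is 2
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = np.abs(x[i + 1:] - x[i]).sum(axis=1) / 2.0
    d = d + d.T
    return DistanceMatrix(d, ids=list(m.sample_ids))


def _branch_table(tree: TreeNode, taxon_ids) -> tuple[np.ndarray, list[np.ndarray]]:
    """Branch lengths and, per branch, indices of the taxa beneath it."""
    order = {t: i for i, t in enumerate(taxon_ids)}
    lengths, below = [], []
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            idx = [order[node.name]] if node.name in order else []
        else:
            idx = [i for c in node.children for i in tipsets[id(c)]]
        tipsets[id(node)] = idx
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            below.append(np.array(idx, dtype=int))
    return np.array(lengths), below


def _branch_incidence(tree: TreeNode, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    lengths, below = _branch_table(tree, taxon_ids)
    inc = np.zeros((len(lengths), len(taxon_ids)))
    for b, idx in enumerate(below):
        inc[b, idx] = 1.0
    return lengths, inc


def weighted_unifrac(x, y, tree: TreeNode, taxon_ids) -> float:
    """Normalized weighted UniFrac between two proportion vectors.

    sum_b l_b |pA(b) - pB(b)| / sum_b l_b (pA(b) + pB(b)) where p(b) is the
    proportion of the community beneath branch b.
    """
    check_tree_covers(tree, taxon_ids)
    pa = _as_proportions(x)
    pb = _as_proportions(y)
    lengths, inc = _branch_incidence(tree, taxon_ids)
    ma, mb = inc @ pa, inc @ pb
    denom = float(lengths @ (ma + mb))
    if denom == 0:
        return 0.0
    return float(lengths @ np.abs(ma - mb) / denom)


def weighted_unifrac_matrix(m: CommunityMatrix, tree: TreeNode) -> DistanceMatrix:
    check_tree_covers(tree, m.taxon_ids)
    rel = to_relative(m)
    lengths, inc = _branch_incidence(tree, m.taxon_ids)
    mass = inc @ rel.counts.T          # branches x samples
    n = m.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        num = lengths @ np.abs(mass[:, i + 1:] - mass[:, [i]])
        den = lengths @ (mass[:, i + 1:] + mass[:, [i]])
        d[i, i + 1:] = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    d = d + d.T
    return DistanceMatrix(d, ids=list(m.sample_ids))


# ---------------------------------------------------------------------------
# ordination

@dataclass(frozen=True)
class PcoaResult:
    """Principal-coordinate analysis output.

    ``eigenvalues`` includes negative values (not silently dropped);
    ``proportion_explained`` is over the positive eigenvalues only.
    ``coordinates`` has one column per positive-eigenvalue axis.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def negative_axes(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical metric MDS: eigendecomposition of the Gower-centered
    -d^2/2 matrix, axes ordered by decreasing eigenvalue."""
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    a = -0.5 * d.data ** 2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(centered)
    idx = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[idx], eigvec[:, idx]
    pos = eigval > 1e-10 * max(abs(eigval[0]), 1.0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = np.where(pos, eigval / eigval[pos].sum(), 0.0)
    return PcoaResult(pd.DataFrame(coords, index=list(d.ids), columns=cols),
                      eigval, prop)


# ---------------------------------------------------------------------------
# permutation tests

@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int
    method: str

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")


def _group_info(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    groups, inv = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv)
    if sizes.min() < 2:
        small = groups[np.argmin(sizes)]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    return groups, inv


def _permanova_f(d2: np.ndarray, inv: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(inv == g)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    f = (ss_a / (n_groups - 1)) / (ss_w / (n - n_groups))
    return f, ss_a / ss_t


def permanova(d: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    """Distance-based PERMANOVA pseudo-F with a label-permutation p-value.

    SS_T = sum_{i<j} d_ij^2 / N; SS_W = sum_g sum_{i<j in g} d_ij^2 / n_g;
    pseudo-F = (SS_A/(a-1)) / (SS_W/(N-a)); p = (1 + #{F_perm >= F_obs}) /
    (n_perm + 1).
    """
    groups, inv = _group_info(labels)
    d2 = d.data ** 2
    f_obs, r2 = _permanova_f(d2, inv, len(groups))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(inv))
        f_p, _ = _permanova_f(d2, inv[perm], len(groups))
        if f_p >= f_obs:
            hits += 1
    return PermTestResult(f_obs, r2, (1 + hits) / (n_perm + 1), n_perm, seed, "permanova")


def permanova_pairwise(d: DistanceMatrix, labels, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """All pairwise two-group PERMANOVAs with Bonferroni-adjusted p-values."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    ids = np.asarray(d.ids)
    rows = []
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    for k, (a, b) in enumerate(pairs):
        mask = np.isin(labels, [a, b])
        sub = d.filter(ids[mask])
        res = permanova(sub, labels[mask], n_perm=n_perm, seed=seed + k)
        rows.append({"group_a": a, "group_b": b, "pseudo_f": res.statistic,
                     "r2": res.r2, "p_value": res.p_value,
                     "p_bonferroni": min(1.0, res.p_value * len(pairs))})
    return pd.DataFrame(rows)


def _dispersion_distances(d: DistanceMatrix, inv: np.ndarray, n_groups: int) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space, with the
    imaginary-axis correction (squared negative-axis components subtracted)."""
    a = -0.5 * d.data ** 2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(centered)
    pos = eigval > 1e-10 * max(abs(eigval).max(), 1.0)
    neg = eigval < -1e-10 * max(abs(eigval).max(), 1.0)
    y_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    y_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])
    z = np.empty(d.shape[0])
    for g in range(n_groups):
        idx = np.flatnonzero(inv == g)
        dp = y_pos[idx] - y_pos[idx].mean(axis=0)
        dn = y_neg[idx] - y_neg[idx].mean(axis=0) if y_neg.size else np.zeros((len(idx), 0))
        z2 = (dp ** 2).sum(axis=1) - (dn ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.clip(z2, 0.0, None))
    return z


def permdisp(d: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    """Homogeneity-of-dispersion test (PERMDISP2 style, group centroids).

    One-way ANOVA F on distances-to-centroid; p-value by permuting group
    labels of those distances (equivalent to residual permutation in the
    one-way layout).
    """
    groups, inv = _group_info(labels)
    z = _dispersion_distances(d, inv, len(groups))

    def anova_f(vals, assign):
        gm = vals.mean()
        ss_b = ss_w = 0.0
        for g in range(len(groups)):
            v = vals[assign == g]
            ss_b += len(v) * (v.mean() - gm) ** 2
            ss_w += ((v - v.mean()) ** 2).sum()
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / (len(groups) - 1)) / (ss_w / (len(vals) - len(groups)))

    f_obs = anova_f(z, inv)
    ss_tot = ((z - z.mean()) ** 2).sum()
    a = len(groups)
    r2 = 0.0
    if ss_tot > 0 and np.isfinite(f_obs):
        # recover R^2 from F: R2 = F(a-1) / (F(a-1) + (N-a))
        r2 = f_obs * (a - 1) / (f_obs * (a - 1) + (len(z) - a))
    rng = np.random.default_rng(seed)
    hits = sum(anova_f(z, inv[rng.permutation(len(inv))]) >= f_obs for _ in range(n_perm))
    return PermTestResult(float(f_obs), float(min(r2, 1.0)), (1 + hits) / (n_perm + 1),
                          n_perm, seed, "permdisp")


def distance_matrix_to_frame(d: DistanceMatrix) -> pd.DataFrame:
    return pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids))


def condensed(d: DistanceMatrix) -> np.ndarray:
    return squareform(d.data, checks=False)
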