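"""Dufrene-Legendre indicator value (IndVal) analysis.

For each taxon t and group g, specificity A_tg is the group-mean relative
abundance of t divided by the sum of group means over all groups, and
fidelity B_tg is the fraction of group-g samples in which t occurs.
IndVal_t = max_g A_tg * B_tg, tested by permuting group labels. Abundances
are converted to per-sample proportions first, so the index is invariant to
sequencing depth; ties in the best group are broken towards the lowest
group index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CommunityMatrix, to_relative


def _group_means_occupancy(x: np.ndarray, inv: np.ndarray, n_groups: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Group-wise mean abundance and occupancy, shape (n_groups, n_taxa)."""
    means = np.empty((n_groups, x.shape[1]))
    occ = np.empty((n_groups, x.shape[1]))
    for g in range(n_groups):
        sub = x[inv == g]
        means[g] = sub.mean(axis=0)
        occ[g] = (sub > 0).mean(axis=0)
    return means, occ


def _indval_components(x: np.ndarray, inv: np.ndarray, n_groups: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    means, occ = _group_means_occupancy(x, inv, n_groups)
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / total, 0.0)
    iv = a * occ
    best = iv.argmax(axis=0)  # argmax takes the lowest index on ties
    cols = np.arange(x.shape[1])
    return iv[best, cols], best, a[best, cols], occ[best, cols]


def indval(m: CommunityMatrix, groups, n_perm: int = 1000, seed: int = 0,
           use_relative: bool = True, alpha: float = 0.01) -> pd.DataFrame:
    """IndVal per taxon with a group-label permutation p-value.

    Returns a DataFrame indexed by taxon with columns ``best_group``,
    ``specificity_A``, ``fidelity_B``, ``indval``, ``p_value`` and
    ``significant`` (p <= alpha). Taxa absent everywhere get IndVal 0 and
    p = 1.
    """
    groups = np.asarray(groups)
    if len(groups) != m.n_samples:
        raise ValueError("one group label per sample required")
    names, inv = np.unique(groups, return_inverse=True)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    x = to_relative(m).counts if use_relative else m.counts

    iv_obs, best, a_best, b_best = _indval_components(x, inv, len(names))
    absent = x.sum(axis=0) == 0

    rng = np.random.default_rng(seed)
    exceed = np.zeros(m.n_taxa, dtype=int)
    for _ in range(n_perm):
        iv_p, _, _, _ = _indval_components(x, inv[rng.permutation(len(inv))], len(names))
        exceed += iv_p >= iv_obs
    p = (1 + exceed) / (n_perm + 1)
    p[absent] = 1.0

    out = pd.DataFrame({
        "best_group": names[best],
        "specificity_A": a_best,
        "fidelity_B": b_best,
        "indval": iv_obs,
        "p_value": p,
    }, index=pd.Index(m.taxon_ids, name="taxon_id"))
    out.loc[absent, ["specificity_A", "fidelity_B", "indval"]] = 0.0
    out["significant"] = out["p_value"] <= alpha
    return out


def host_specific_taxa(result: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Subset of the IndVal table flagged host-specific at ``alpha``."""
    return result[result["p_value"] <= alpha].sort_values("indval", ascending=False)
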