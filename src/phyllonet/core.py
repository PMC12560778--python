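"""Core data model, file I/O and count-matrix preprocessing.

The central object is :class:`CommunityMatrix`, a samples x taxa table of
read counts (or relative abundances after :func:`to_relative`). Sample
metadata carries the study design factors (host species, habitat size,
habitat class, site). Phylogenies are scikit-bio ``TreeNode`` objects whose
tips are taxon ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: habitat_size -> habitat_class mapping: 1- and 10-ha fragments are
#: "small", 100-ha fragments and continuous forest are "large".
HABITAT_CLASS = {"1-ha": "small", "10-ha": "small", "100-ha": "large", "continuous": "large"}

HABITAT_SIZES = ("1-ha", "10-ha", "100-ha", "continuous")


class CommunityMatrixError(ValueError):
    """Raised for invalid community-matrix contents."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    sample_ids : list of str
        Unique ordered sample identifiers (rows).
    taxon_ids : list of str
        Unique ordered taxon identifiers (columns).
    counts : ndarray, shape (n_samples, n_taxa)
        Non-negative reads, or proportions when ``is_relative``.
    is_relative : bool
        When True every row sums to 1 (within 1e-9).
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    counts: np.ndarray
    is_relative: bool = False

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        if counts.ndim != 2:
            raise CommunityMatrixError("counts must be 2-D (samples x taxa)")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise CommunityMatrixError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CommunityMatrixError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise CommunityMatrixError("duplicate taxon ids")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise CommunityMatrixError(
                f"negative entry at sample {self.sample_ids[i]!r}, taxon {self.taxon_ids[j]!r}"
            )
        if self.is_relative:
            sums = counts.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise CommunityMatrixError(
                    f"relative matrix row {self.sample_ids[bad]!r} sums to {sums[bad]!r}, not 1"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, is_relative: bool = False) -> "CommunityMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float), is_relative)

    def select_samples(self, keep: "list[str] | np.ndarray") -> "CommunityMatrix":
        """Subset (and reorder) samples by id list or boolean mask."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return replace(self, sample_ids=tuple(self.sample_ids[i] for i in idx),
                       counts=self.counts[idx])

    def select_taxa(self, keep: "list[str] | np.ndarray") -> "CommunityMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {t: i for i, t in enumerate(self.taxon_ids)}
            idx = np.array([pos[t] for t in keep], dtype=int)
        return replace(self, taxon_ids=tuple(self.taxon_ids[i] for i in idx),
                       counts=self.counts[:, idx])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design factors.

    ``habitat_class`` is always derived from ``habitat_size`` (1-/10-ha ->
    small; 100-ha/continuous -> large); a stored column that disagrees is
    rejected.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("host", "habitat_size", "site")

    def __post_init__(self):
        df = self.table.copy()
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        unknown = set(df["habitat_size"]) - set(HABITAT_CLASS)
        if unknown:
            raise ValueError(f"unknown habitat_size values: {sorted(unknown)}")
        derived = df["habitat_size"].map(HABITAT_CLASS)
        if "habitat_class" in df.columns:
            if not (df["habitat_class"] == derived).all():
                raise ValueError("habitat_class column inconsistent with habitat_size")
        df["habitat_class"] = derived
        object.__setattr__(self, "table", df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(map(str, self.table.index))

    def aligned_to(self, m: CommunityMatrix) -> pd.DataFrame:
        """Metadata rows in matrix sample order; every sample must be present."""
        missing = set(m.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        return self.table.loc[list(m.sample_ids)]

    def column(self, m: CommunityMatrix, name: str) -> np.ndarray:
        return self.aligned_to(m)[name].to_numpy()


@dataclass(frozen=True)
class TaxonomyTable:
    """taxon_id -> rank labels (phylum..genus); missing ranks allowed."""

    table: pd.DataFrame = field(repr=False)

    RANKS = ("phylum", "class", "order", "family", "genus")

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("duplicate taxon ids in taxonomy")

    def genus_of(self, taxon_id: str) -> str | None:
        if "genus" in self.table.columns and taxon_id in self.table.index:
            g = self.table.loc[taxon_id, "genus"]
            return None if pd.isna(g) else str(g)
        return None


# ---------------------------------------------------------------------------
# I/O

def load_community_matrix(path: str | Path, samples_as_rows: bool = True) -> CommunityMatrix:
    """Read a TSV community matrix (header row, first column = ids).

    ``samples_as_rows=False`` transposes a taxa-as-rows table into the
    internal samples-as-rows convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = df.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna() & df.notna()
    if non_numeric.any().any():
        i, j = np.argwhere(non_numeric.to_numpy())[0]
        raise CommunityMatrixError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    df = df.astype(float)
    if not samples_as_rows:
        df = df.T
    return CommunityMatrix.from_frame(df)


def save_community_matrix(m: CommunityMatrix, path: str | Path) -> None:
    m.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def load_sparse_community_matrix(path: str | Path) -> CommunityMatrix:
    """Read a BIOM-style sparse triplet TSV: columns sample_id, taxon_id, count."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "taxon_id": str})
    wide = df.pivot_table(index="sample_id", columns="taxon_id", values="count",
                          aggfunc="sum", fill_value=0.0)
    return CommunityMatrix.from_frame(wide)


def load_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", index_col=0, dtype=str))


def save_metadata(md: SampleMetadata, path: str | Path) -> None:
    md.table.rename_axis("sample_id").to_csv(path, sep="\t")


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    return TaxonomyTable(pd.read_csv(path, sep="\t", index_col=0, dtype=str))


def save_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.table.rename_axis("taxon_id").to_csv(path, sep="\t")


def load_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels in tree")
    return tree


def save_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def check_tree_covers(tree: TreeNode, taxon_ids) -> None:
    tips = {t.name for t in tree.tips()}
    missing = set(taxon_ids) - tips
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)[:5]} "
                         f"({len(missing)} total)")


# ---------------------------------------------------------------------------
# Preprocessing

def filter_low_depth(m: CommunityMatrix, min_reads: int) -> CommunityMatrix:
    """Drop samples whose total read count is below ``min_reads``."""
    if m.is_relative:
        raise CommunityMatrixError("filter_low_depth requires read counts, not proportions")
    keep = m.sample_sums() >= min_reads
    if not keep.any():
        raise CommunityMatrixError(f"no sample reaches {min_reads} reads")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_depth: dropped %d/%d samples below %d reads",
                    dropped, m.n_samples, min_reads)
    return m.select_samples(keep)


def rarefy(m: CommunityMatrix, depth: int, seed: int) -> CommunityMatrix:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (logged).
    Sampling is multivariate hypergeometric; identical seed gives identical
    output.
    """
    if depth < 1:
        raise CommunityMatrixError("rarefaction depth must be >= 1")
    if m.is_relative:
        raise CommunityMatrixError("rarefy requires read counts, not proportions")
    counts = np.rint(m.counts).astype(np.int64)
    if not np.allclose(counts, m.counts):
        raise CommunityMatrixError("rarefy requires integer read counts")
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise CommunityMatrixError(f"no sample has >= {depth} reads to rarefy")
    dropped = [s for s, k in zip(m.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropped %d samples shallower than %d: %s",
                    len(dropped), depth, dropped[:5])
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), m.n_taxa), dtype=np.int64)
    for r, i in enumerate(np.flatnonzero(keep)):
        out[r] = rng.multivariate_hypergeometric(counts[i], depth)
    return CommunityMatrix(tuple(np.array(m.sample_ids)[keep]), m.taxon_ids,
                           out.astype(float))


def to_relative(m: CommunityMatrix) -> CommunityMatrix:
    """Convert each row to proportions of its total. Idempotent."""
    if m.is_relative:
        return m
    sums = m.sample_sums()
    if np.any(sums <= 0):
        bad = m.sample_ids[int(np.argmin(sums))]
        raise CommunityMatrixError(f"sample {bad!r} has zero total; cannot normalise")
    return CommunityMatrix(m.sample_ids, m.taxon_ids, m.counts / sums[:, None],
                           is_relative=True)
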