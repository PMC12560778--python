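import numpy as np
import pytest
from skbio import TreeNode

from phyllonet.core import CommunityMatrix


@pytest.fixture
def small_matrix() -> CommunityMatrix:
    counts = np.array([
        [10, 0, 5, 1],
        [2, 8, 0, 4],
        [0, 3, 7, 2],
    ], dtype=float)
    return CommunityMatrix(("s1", "s2", "s3"), ("a", "b", "c", "d"), counts)


@pytest.fixture
def star_tree() -> TreeNode:
    return TreeNode.read(["(a:1,b:1,c:1);"])


def random_community(rng: np.random.Generator, n_samples: int, n_taxa: int,
                     depth: int = 200) -> CommunityMatrix:
    """Random multinomial community with log-normal per-sample pools."""
    rows = []
    for _ in range(n_samples):
        w = rng.lognormal(0, 1, n_taxa) * (rng.random(n_taxa) > 0.3)
        if w.sum() == 0:
            w[rng.integers(n_taxa)] = 1.0
        rows.append(rng.multinomial(depth, w / w.sum()))
    return CommunityMatrix(tuple(f"s{i}" for i in range(n_samples)),
                           tuple(f"t{j:04d}" for j in range(n_taxa)),
                           np.array(rows, dtype=float))


def random_tree(rng: np.random.Generator, taxa) -> TreeNode:
    """Random bifurcating tree over the given tip names (agglomerative)."""
    nodes = [TreeNode(name=t, length=float(rng.uniform(0.1, 2.0))) for t in taxa]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[max(i, j)], nodes[min(i, j)]
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.append(a)
        parent.append(b)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    root = nodes[0]
    root.length = None
    return root
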