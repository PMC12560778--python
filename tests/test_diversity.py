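import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.diversity.beta import weighted_unifrac as skbio_wunifrac
from skbio.stats.distance import permanova as skbio_permanova

from phyllonet.core import CommunityMatrix
from phyllonet.diversity import (PermTestResult, alpha_diversity_table, bray_curtis,
                                 bray_curtis_matrix, chao1, faith_pd, hill_shannon,
                                 hill_simpson, pcoa, permanova, permanova_pairwise,
                                 permdisp, weighted_unifrac)
from conftest import random_community, random_tree


class TestChao1:
    def test_hand_evaluated_formula(self):
        # 10 observed, 4 singletons, 2 doubletons -> 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 3, 5, 7, 9]
        assert chao1(counts) == pytest.approx(12.0)

    def test_no_singletons_equals_observed(self):
        assert chao1([2, 3, 4]) == 3.0

    def test_all_zero_vector(self):
        assert chao1([0, 0]) == 0.0

    def test_rejects_proportions(self):
        with pytest.raises(ValueError, match="integer"):
            chao1([0.5, 0.5])


class TestHillNumbers:
    def test_uniform_equals_richness(self):
        p = [0.25] * 4
        assert hill_shannon(p) == pytest.approx(4.0)
        assert hill_simpson(p) == pytest.approx(4.0)

    def test_two_even_taxa(self):
        assert hill_shannon([0.5, 0.5]) == pytest.approx(2.0)
        assert hill_simpson([0.5, 0.5]) == pytest.approx(2.0)

    def test_skewed_pair_hand_values(self):
        assert hill_shannon([0.8, 0.2]) == pytest.approx(1.64938, abs=1e-4)
        assert hill_simpson([0.8, 0.2]) == pytest.approx(1.47059, abs=1e-4)

    def test_hill_ordering_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(0, 50, size=30)
            if c.sum() == 0:
                continue
            s_obs = (c > 0).sum()
            assert hill_simpson(c) <= hill_shannon(c) + 1e-9 <= s_obs + 1e-9


class TestFaithPD:
    def test_star_tree_all_present(self, star_tree):
        assert faith_pd({"a", "b", "c"}, star_tree) == pytest.approx(3.0)

    def test_single_taxon_root_path(self):
        from skbio import TreeNode
        tree = TreeNode.read(["((a:1,b:2):3,c:4);"])
        assert faith_pd({"a"}, tree) == pytest.approx(4.0)  # 1 + 3

    def test_empty_set_is_zero(self, star_tree):
        assert faith_pd(set(), star_tree) == 0.0

    def test_unknown_tip_errors(self, star_tree):
        with pytest.raises(ValueError, match="missing"):
            faith_pd({"zz"}, star_tree)


class TestBrayCurtis:
    def test_hand_value(self):
        assert bray_curtis([1, 0, 3], [2, 2, 0]) == pytest.approx(0.75)

    def test_identical_zero_disjoint_one(self):
        assert bray_curtis([1, 2], [1, 2]) == 0.0
        assert bray_curtis([1, 0], [0, 5]) == 1.0

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestWeightedUnifrac:
    def test_identical_communities_zero(self, star_tree):
        assert weighted_unifrac([0.5, 0.3, 0.2], [0.5, 0.3, 0.2], star_tree,
                                ("a", "b", "c")) == pytest.approx(0.0)

    def test_disjoint_single_tips_on_star(self):
        from skbio import TreeNode
        tree = TreeNode.read(["(a:1,b:1);"])
        assert weighted_unifrac([1, 0], [0, 1], tree, ("a", "b")) == pytest.approx(1.0)

    def test_agrees_with_skbio_on_random_trees(self):
        rng = np.random.default_rng(42)
        taxa = [f"t{i}" for i in range(10)]
        for _ in range(20):
            tree = random_tree(rng, taxa)
            x = rng.multinomial(80, np.full(10, 0.1)).astype(float)
            y = rng.multinomial(80, rng.dirichlet(np.ones(10))).astype(float)
            mine = weighted_unifrac(x, y, tree, taxa)
            ref = skbio_wunifrac(x, y, taxa=taxa, tree=tree, normalized=True)
            assert mine == pytest.approx(float(ref), abs=1e-10)


class TestPcoa:
    def test_reconstructs_euclidean_configuration(self):
        pts = np.array([[0, 0], [1, 0], [0, 2], [3, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=list("wxyz")))
        coords = res.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_equilateral_triangle_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-10)

    def test_duplicate_points_coincide(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        np.testing.assert_allclose(res.coordinates.iloc[0], res.coordinates.iloc[1],
                                   atol=1e-8)

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(np.zeros((2, 2)), ids=list("ab")))


def _brute_force_pseudo_f(d, labels):
    """Explicit double-loop PERMANOVA pseudo-F."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_w += sum(d[i, j] ** 2 for k, i in enumerate(idx)
                    for j in idx[k + 1:]) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))


class TestPermanova:
    def test_single_group_errors(self):
        d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        with pytest.raises(ValueError):
            permanova(d, ["g"] * 4, n_perm=9, seed=0)

    def test_complete_separation_gives_min_p(self):
        rng = np.random.default_rng(1)
        # 10+10 so the chance a permutation reproduces the exact partition
        # (and ties F_obs) is ~1e-5
        pts = np.vstack([rng.normal(0, 0.01, (10, 2)), rng.normal(10, 0.01, (10, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        labels = ["a"] * 10 + ["b"] * 10
        # a permutation reproducing the exact partition ties F_obs; that
        # event has probability ~1e-5 per draw and is absent for this seed
        res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(20)]),
                        labels, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(0.001)
        assert res.r2 > 0.9

    def test_statistic_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.normal(size=(8, 3))
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            labels = rng.permutation(["a"] * 4 + ["b"] * 2 + ["c"] * 2)
            res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(8)]),
                            labels, n_perm=9, seed=0)
            assert res.statistic == pytest.approx(_brute_force_pseudo_f(d, labels),
                                                  abs=1e-10)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        mine = permanova(dm, labels, n_perm=9, seed=0).statistic
        ref = skbio_permanova(dm, list(labels), permutations=9)["test statistic"]
        assert mine == pytest.approx(float(ref), abs=1e-10)

    def test_pairwise_applies_bonferroni(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(c, 0.05, (4, 2)) for c in (0, 5, 10)])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        table = permanova_pairwise(DistanceMatrix(d, ids=[str(i) for i in range(12)]),
                                   labels, n_perm=99, seed=0)
        assert len(table) == 3
        np.testing.assert_allclose(table["p_bonferroni"],
                                   np.minimum(1.0, table["p_value"] * 3))


class TestPermdisp:
    def test_equal_dispersion_not_significant(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(8, 1, (10, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = permdisp(DistanceMatrix(d, ids=[str(i) for i in range(20)]),
                       ["a"] * 10 + ["b"] * 10, n_perm=199, seed=0)
        assert res.p_value > 0.05

    def test_contrasting_dispersion_detected(self):
        rng = np.random.default_rng(4)
        tight = np.tile([0.0, 0.0], (8, 1)) + rng.normal(0, 1e-4, (8, 2))
        loose = rng.normal(0, 3.0, (8, 2))
        pts = np.vstack([tight, loose])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = permdisp(DistanceMatrix(d, ids=[str(i) for i in range(16)]),
                       ["t"] * 8 + ["l"] * 8, n_perm=199, seed=0)
        assert res.p_value < 0.05


class TestAlphaTable:
    def test_hill_ordering_invariant(self, small_matrix, star_tree):
        m = CommunityMatrix(("s1", "s2"), ("a", "b", "c"),
                            np.array([[5.0, 3.0, 2.0], [10.0, 0.0, 0.0]]))
        table = alpha_diversity_table(m, star_tree)
        assert (table["hill_simpson"] <= table["hill_shannon"] + 1e-9).all()
        assert (table["hill_shannon"] <= table["observed_richness"] + 1e-9).all()
        assert table.loc["s2", "faith_pd"] == pytest.approx(1.0)


class TestResultInvariants:
    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            PermTestResult(1.0, 0.5, 0.0, 99, 0, "x")

    def test_distance_matrix_properties(self):
        rng = np.random.default_rng(6)
        m = random_community(rng, 6, 15)
        d = bray_curtis_matrix(m)
        assert np.allclose(d.data, d.data.T)
        assert np.all(np.diag(d.data) == 0)
        assert d.data.max() <= 1.0
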