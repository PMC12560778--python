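import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyllonet.core import CommunityMatrix
from phyllonet.network import (CoNetwork, bootstrap_edge_stability, build_network,
                               cohesion, cohesion_group_test, compare_networks,
                               detect_modules, filter_taxa, rmt_threshold,
                               spearman_edges, topology, zi_pi)


def matrix(rows, taxa=None):
    rows = np.asarray(rows, dtype=float)
    taxa = taxa or tuple(f"t{j}" for j in range(rows.shape[1]))
    return CommunityMatrix(tuple(f"s{i}" for i in range(rows.shape[0])), taxa, rows)


def net_from_edges(edges) -> CoNetwork:
    g = nx.Graph()
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=e[2])
        else:
            g.add_edge(*e, weight=1.0)
    return CoNetwork(g)


class TestFilterTaxa:
    def test_threshold_boundary_inclusive(self):
        # taxon mean relative abundance 0.0004 (dropped) vs 0.0005 (kept)
        m = matrix(np.array([[4, 5, 4996, 4995]] * 2, dtype=float))
        out = filter_taxa(m, 0.0005)
        assert "t0" not in out.taxon_ids
        assert "t1" in out.taxon_ids

    def test_zero_threshold_identity(self):
        m = matrix([[1, 2], [3, 4]])
        out = filter_taxa(m, 0.0)
        assert out.taxon_ids == m.taxon_ids

    def test_nothing_survives_errors(self):
        m = matrix([[1, 1], [1, 1]])
        with pytest.raises(ValueError):
            filter_taxa(m, 0.9)


class TestSpearmanEdges:
    def test_monotone_pair_kept(self):
        x = np.arange(1, 11, dtype=float)
        rows = np.column_stack([x, 2 * x, np.full(10, 7.0) + np.sin(x)])
        edges = spearman_edges(matrix(rows), p_thresh=0.01, q_thresh=0.05)
        pair = edges[(edges.taxon_a == "t0") & (edges.taxon_b == "t1")].iloc[0]
        assert pair.rho == pytest.approx(1.0)
        assert pair.kept

    def test_rho_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 5, size=(12, 6)).astype(float) + 0.01  # many ties
        edges = spearman_edges(matrix(rows), p_thresh=1.0, q_thresh=1.0)
        rel = rows / rows.sum(axis=1, keepdims=True)  # edges rank proportions
        for row in edges.itertuples():
            a = rel[:, int(row.taxon_a[1:])]
            b = rel[:, int(row.taxon_b[1:])]
            ref = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
            assert row.rho == pytest.approx(ref, abs=1e-10)

    def test_constant_taxon_skipped(self):
        rows = np.column_stack([np.arange(8.0), np.ones(8), np.arange(8.0)[::-1]])
        edges = spearman_edges(matrix(rows), p_thresh=1.0, q_thresh=1.0)
        assert not ((edges.taxon_a == "t1") | (edges.taxon_b == "t1")).any()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_edges(matrix(np.ones((4, 3))))


class TestRmtThreshold:
    def test_identity_matrix_hits_upper_bound(self, caplog):
        t = rmt_threshold(np.eye(60))
        assert t == pytest.approx(0.9)

    def test_block_structure_detected_below_block_value(self):
        # noise correlations reach ~0.55, planted blocks sit at 0.75: the
        # Poisson transition must appear at or below the block value
        rng = np.random.default_rng(1)
        n, block = 60, 0.75
        c = rng.uniform(-0.55, 0.55, (n, n))
        c = (c + c.T) / 2
        for start in range(0, n, 10):
            c[start:start + 10, start:start + 10] = block
        np.fill_diagonal(c, 1.0)
        t = rmt_threshold(c)
        assert 0.30 <= t <= block

    def test_result_within_scan_range(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-1, 1, (40, 40))
        c = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(c, 1.0)
        assert 0.30 <= rmt_threshold(c) <= 0.90

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            rmt_threshold(np.arange(9.0).reshape(3, 3))


class TestModules:
    def test_two_cliques_recovered(self):
        g = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(0, 5, weight=1.0)
        part, q = detect_modules(CoNetwork(g))
        assert len({part[i] for i in range(5)}) == 1
        assert len({part[i] for i in range(5, 10)}) == 1
        assert part[0] != part[5]
        assert q > 0.3

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        part, q = detect_modules(CoNetwork(g))
        assert abs(q) < 0.2
        assert -0.5 <= q <= 1.0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            detect_modules(CoNetwork(nx.Graph()))


class TestZiPi:
    def test_internal_node_zero_pi(self):
        net = net_from_edges([("a", "b"), ("a", "c"), ("b", "c")])
        roles = zi_pi(net, {"a": 0, "b": 0, "c": 0})
        assert (roles["pi"] == 0).all()

    def test_even_split_pi_half(self):
        # hub with 4 edges split evenly over modules 0 and 1
        net = net_from_edges([("h", "a"), ("h", "b"), ("h", "c"), ("h", "d")])
        part = {"h": 0, "a": 0, "b": 0, "c": 1, "d": 1}
        roles = zi_pi(net, part)
        assert roles.loc["h", "pi"] == pytest.approx(0.5)

    def test_uniform_module_degree_zero_zi(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        roles = zi_pi(net, {"a": 0, "b": 0, "c": 0})
        assert (roles["zi"] == 0).all()

    def test_roles_stable_under_relabeling(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        nx.set_edge_attributes(g, 1.0, "weight")
        net = CoNetwork(g)
        part, _ = detect_modules(net)
        roles = zi_pi(net, part)
        mapping = {n: f"x{n}" for n in g.nodes}
        g2 = nx.relabel_nodes(g, mapping)
        roles2 = zi_pi(CoNetwork(g2), {f"x{n}": m for n, m in part.items()})
        for n in g.nodes:
            assert roles.loc[n, "role"] == roles2.loc[f"x{n}", "role"]
            assert roles.loc[n, "zi"] == pytest.approx(roles2.loc[f"x{n}", "zi"])


class TestTopology:
    def test_path_graph_hand_values(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        t = topology(net)
        assert t["diameter"] == 2
        assert t["average_degree"] == pytest.approx(4 / 3)

    def test_complete_graph_symmetry(self):
        g = nx.complete_graph(4)
        t = topology(CoNetwork(g))
        assert t["density"] == pytest.approx(1.0)
        assert t["clustering_coefficient"] == pytest.approx(1.0)
        assert t["centralization"] == pytest.approx(0.0)

    def test_star_centralization_one(self):
        g = nx.star_graph(4)  # S5: center + 4 leaves
        t = topology(CoNetwork(g))
        assert t["centralization"] == pytest.approx(1.0)
        assert t["heterogeneity"] > 0


class TestCompareNetworks:
    def test_identical_networks_fully_shared(self):
        a = net_from_edges([("x", "y"), ("y", "z")])
        b = net_from_edges([("x", "y"), ("y", "z")])
        rep = compare_networks({"a": a, "b": b})
        assert rep.loc["shared:a|b", "nodes"] == 3
        assert rep.loc["shared:a|b", "edges"] == 2
        assert rep.loc["unique:a", "nodes"] == 0

    def test_disjoint_networks_nothing_shared(self):
        a = net_from_edges([("x", "y")])
        b = net_from_edges([("p", "q")])
        rep = compare_networks({"a": a, "b": b})
        assert rep.loc["shared:a|b", "nodes"] == 0
        assert rep.loc["unique:a", "nodes"] == 2
        assert rep.loc["unique:a", "nodes_pct"] == pytest.approx(50.0)

    def test_set_algebra_oracle(self):
        a = net_from_edges([(1, 2), (2, 3), (3, 4)])
        b = net_from_edges([(2, 3), (4, 5)])
        rep = compare_networks({"a": a, "b": b})
        sa = {frozenset(e) for e in a.graph.edges}
        sb = {frozenset(e) for e in b.graph.edges}
        assert rep.loc["shared:a|b", "edges"] == len(sa & sb)
        assert rep.loc["unique:b", "edges"] == len(sb - sa)


class TestCohesion:
    def test_sign_invariants_on_random_data(self):
        rng = np.random.default_rng(5)
        m = matrix(rng.integers(1, 50, size=(10, 15)))
        res = cohesion(m, n_null=50, seed=0)
        assert (res["samples"]["cohesion_pos"] >= -1e-12).all()
        assert (res["samples"]["cohesion_neg"] <= 1e-12).all()
        assert (res["connectedness"]["c_plus"] >= 0).all()
        assert (res["connectedness"]["c_minus"] <= 0).all()

    def test_planted_covarying_block_high_connectedness(self):
        # a block of 4 co-varying low-abundance taxa among independent noise
        # taxa; block members' positive connectedness exceeds the noise 95th
        # percentile (block kept small so compositional closure is mild)
        rng = np.random.default_rng(6)
        driver = rng.lognormal(0, 1.2, 30)
        block = driver[:, None] * rng.lognormal(0, 0.15, (30, 4)) * 0.05
        noise = rng.lognormal(0, 1, (30, 10))
        res = cohesion(matrix(np.column_stack([block, noise])), n_null=100, seed=1)
        c = res["connectedness"]["c_plus"]
        cut = c.iloc[4:].quantile(0.95)
        assert (c.iloc[:4] > cut).all()

    def test_group_test_two_groups_only(self):
        samples = pd.DataFrame({"cohesion_pos": np.arange(6.0)},
                               index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError):
            cohesion_group_test(samples, ["a", "b", "c"] * 2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cohesion(matrix(np.ones((3, 4))), n_null=10, seed=0)


class TestBuildNetwork:
    def test_planted_blocks_produce_modular_network(self):
        rng = np.random.default_rng(7)
        n_blocks, per_block, n_samp = 4, 8, 24
        drivers = rng.lognormal(0, 1.5, (n_samp, n_blocks))
        cols = []
        for b in range(n_blocks):
            for _ in range(per_block):
                cols.append(drivers[:, b] * rng.lognormal(0, 0.2, n_samp))
        counts = np.column_stack(cols)
        m = matrix(counts / counts.sum(axis=1, keepdims=True) * 5000)
        net = build_network(m, min_mean_rel=0.0, seed=0)
        assert net.n_edges > 0
        assert net.modularity > 0.4
        # edges should connect same-block taxa far more often than not
        same = sum(int(a[1:]) // per_block == int(b[1:]) // per_block
                   for a, b in net.graph.edges)
        assert same / net.n_edges > 0.8

    def test_bootstrap_stability_flags_stable_edges(self):
        rng = np.random.default_rng(8)
        x = np.arange(1.0, 16.0)
        rows = np.column_stack([x, x * 2 + rng.normal(0, 0.01, 15),
                                rng.lognormal(0, 1, 15)])
        out = bootstrap_edge_stability(matrix(rows), n_boot=20, seed=0)
        pair = out[(out.taxon_a == "t0") & (out.taxon_b == "t1")].iloc[0]
        assert pair.stability > 0.8
        assert pair.kept
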