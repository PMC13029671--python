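import numpy as np
import pandas as pd
import pytest

from rhizonet import io as rio
from rhizonet import network as nw
from rhizonet import simulate as sim
from tests import _oracles as oracle
from tests.conftest import build_network


def rel_pair(x, y):
    """Two focal OTU proportion columns (shapes preserved exactly) plus a
    filler absorbing the remainder, as bacterial and fungal tables."""
    n = len(x)
    rng = np.random.default_rng(99)
    b1 = np.asarray(x, dtype=float) / (4 * max(x))
    b2 = np.asarray(y, dtype=float) / (4 * max(y))
    bact = pd.DataFrame({"B1": b1, "B2": b2, "B3": 1.0 - b1 - b2},
                        index=[f"S{i}" for i in range(n)])
    f1 = rng.uniform(0.2, 0.8, n)
    fungi = pd.DataFrame({"F1": f1, "F2": 1.0 - f1}, index=bact.index)
    return (rio.RelAbundanceTable(values=bact, kingdom="bacteria"),
            rio.RelAbundanceTable(values=fungi, kingdom="fungi"))


class TestSpearmanEdges:
    def test_perfect_monotone_pair_becomes_positive_edge(self):
        bact, fungi = rel_pair([1, 2, 3, 4, 5, 6], [2, 3, 5, 8, 9, 12])
        net = nw.spearman_edges(bact, fungi, prevalence_min=1)
        assert net.graph.has_edge("B1", "B2")
        d = net.graph.edges["B1", "B2"]
        assert d["rho"] == pytest.approx(1.0)
        assert d["sign"] == 1
        assert d["p"] == pytest.approx(2 / 720)  # exact enumeration at n=6

    def test_sub_threshold_rho_excluded(self):
        # ranks [1,2,3,4,5,6] vs [3,2,1,4,5,6]: rho = 1 - 6*8/210 = 0.771
        bact, fungi = rel_pair([1, 2, 3, 4, 5, 6], [3, 2, 1, 4, 5, 6])
        net = nw.spearman_edges(bact, fungi, prevalence_min=1)
        assert not net.graph.has_edge("B1", "B2")

    def test_monotone_transform_invariance(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        bact1, fungi = rel_pair(x, 2 * x)
        bact2, _ = rel_pair(np.exp(x / 3), 2 * x)
        n1 = nw.spearman_edges(bact1, fungi, prevalence_min=1)
        n2 = nw.spearman_edges(bact2, fungi, prevalence_min=1)
        e1 = n1.graph.edges["B1", "B2"]
        e2 = n2.graph.edges["B1", "B2"]
        assert e1["rho"] == pytest.approx(e2["rho"])
        assert e1["p"] == pytest.approx(e2["p"])

    def test_too_few_shared_samples(self):
        bact, fungi = rel_pair([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="4 shared"):
            nw.spearman_edges(bact, fungi)

    def test_planted_block_recovery(self):
        pool_b, pool_f = sim.default_otu_ids(60, 30)
        blocks = sim.make_blocks(pool_b + pool_f, 3, 6, strength=0.95,
                                 signs=[1, 1, 1, 1, -1, -1])
        params = sim.NetworkSimParams(n_bacterial_otus=60, n_fungal_otus=30,
                                      n_samples=20, blocks=blocks, seed=4)
        bact, fungi, tax, truth = sim.simulate_otu_tables(params)
        net = nw.spearman_edges(rio.to_relative_abundance(bact),
                                rio.to_relative_abundance(fungi),
                                taxonomy=tax)
        pred = {frozenset(e) for e in net.graph.edges}
        true = {frozenset((a, b)) for a, b, _ in truth.associated_pairs}
        tp = len(pred & true)
        assert tp / len(true) >= 0.9
        assert tp / len(pred) >= 0.9
        # planted signs propagate to the recovered edges
        for a, b, s in truth.associated_pairs:
            if net.graph.has_edge(a, b):
                assert net.graph.edges[a, b]["sign"] == s


class TestTopology:
    def test_triangle(self):
        net = build_network([("a", "b", 1.0), ("b", "c", 1.0),
                             ("a", "c", 1.0)])
        for _, _, d in net.graph.edges(data=True):
            d["distance"] = 1.0
        m = nw.topology(net)
        assert m.density == pytest.approx(1.0)
        assert m.clustering_coefficient == pytest.approx(1.0)
        assert m.diameter == pytest.approx(1.0)
        assert m.avg_path_length == pytest.approx(1.0)

    def test_two_disjoint_triangles_modularity(self):
        net = build_network([("a", "b", 1.0), ("b", "c", 1.0),
                             ("a", "c", 1.0), ("x", "y", 1.0),
                             ("y", "z", 1.0), ("x", "z", 1.0)])
        m = nw.topology(net)
        # Q of the 2-module partition: 2*(3/6 - (6/12)^2) = 0.5
        assert m.modularity == pytest.approx(0.5)
        assert m.n_modules == 2

    def test_star_betweenness_centralization(self):
        net = build_network([("hub", f"leaf{i}", 0.95) for i in range(5)])
        m = nw.topology(net)
        assert m.betweenness_centralization == pytest.approx(1.0)

    def test_edge_sign_partition(self):
        net = build_network([("a", "b", 0.95), ("b", "c", -0.93),
                             ("c", "d", 0.99), ("a", "d", -0.91)])
        m = nw.topology(net)
        assert m.positive_edges + m.negative_edges == m.edges == 4
        assert m.pos_neg_ratio == pytest.approx(1.0)

    def test_empty_network_missing_metrics(self):
        m = nw.topology(build_network([]))
        assert m.edges == 0
        assert np.isnan(m.density)

    def test_matches_brute_force_oracle(self):
        """Weighted/unweighted topology against exhaustive enumeration on
        small random graphs (the deep 200-graph sweep runs in the
        acceptance suite)."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            nodes, edges = oracle.random_test_graph(rng, max_nodes=10)
            net = build_network([(u, v, 1 - w) for u, v, w in edges])
            net.graph.add_nodes_from(nodes)  # keep isolated nodes too
            for u, v, w in edges:
                net.graph.edges[u, v]["distance"] = w
            m = nw.topology(net)
            dists = oracle.shortest_distances(nodes, edges)
            assert m.avg_path_length == pytest.approx(
                np.mean(list(dists.values())))
            assert m.diameter == pytest.approx(max(dists.values()))
            assert m.density == pytest.approx(oracle.density(nodes, edges))
            assert m.clustering_coefficient == pytest.approx(
                oracle.transitivity(nodes, edges))
            b = oracle.betweenness_normalized(nodes, edges)
            assert m.betweenness_centralization == pytest.approx(
                oracle.centralization(b))
            part = nw.modules(net)
            assert m.modularity == pytest.approx(
                oracle.modularity_q(nodes, edges, part))


class TestSubnetworks:
    def _parent_and_counts(self):
        net = build_network([("B1", "B2", 0.95), ("B2", "B3", 0.92),
                             ("B3", "B4", 0.97), ("B4", "B5", -0.93),
                             ("B1", "B5", 0.94)])
        counts = pd.DataFrame(
            [[5, 5, 5, 5, 5], [3, 4, 2, 0, 0], [0, 0, 0, 0, 0]],
            index=["full", "partial", "none"],
            columns=["B1", "B2", "B3", "B4", "B5"])
        t = rio.OtuTable(counts=counts, kingdom="bacteria")
        return net, t

    def test_full_presence_equals_parent(self):
        net, t = self._parent_and_counts()
        sub = nw.sample_subnetwork(net, t, "full")
        assert set(sub.graph.edges) == set(net.graph.edges)
        assert nw.topology(sub).as_series().equals(
            nw.topology(net).as_series())

    def test_absent_sample_empty_flagged(self):
        net, t = self._parent_and_counts()
        sub = nw.sample_subnetwork(net, t, "none")
        assert sub.empty_flag and sub.n_nodes == 0

    def test_partial_presence_induced_edges(self):
        net, t = self._parent_and_counts()
        sub = nw.sample_subnetwork(net, t, "partial")
        assert set(sub.graph.nodes) == {"B1", "B2", "B3"}
        assert set(map(frozenset, sub.graph.edges)) == {
            frozenset(("B1", "B2")), frozenset(("B2", "B3"))}

    def test_unknown_sample(self):
        net, t = self._parent_and_counts()
        with pytest.raises(KeyError):
            nw.sample_subnetwork(net, t, "nope")

    def test_node_removal_never_adds_edges(self):
        net, t = self._parent_and_counts()
        sub = nw.sample_subnetwork(net, t, "partial")
        assert sub.n_edges <= net.n_edges


class TestSubnetworkEnvCorrelation:
    def test_metric_equal_to_variable(self):
        metrics = pd.DataFrame({"nodes": [1, 2, 3, 4, 5, 6.0],
                                "edges": [2, 1, 4, 3, 6, 5.0]},
                               index=[f"S{i}" for i in range(6)])
        meta = rio.SampleMetadata(table=pd.DataFrame({
            "group": ["KC"] * 6, "Na": [10, 20, 30, 40, 50, 60.0],
        }, index=metrics.index))
        out = nw.subnetwork_env_correlation(metrics, meta)
        row = out[(out["metric"] == "nodes") & (out["variable"] == "Na")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)
        assert row["p"].iloc[0] == pytest.approx(2 / 720)

    def test_requires_five_samples(self):
        metrics = pd.DataFrame({"nodes": [1, 2, 3.0]},
                               index=["S0", "S1", "S2"])
        meta = rio.SampleMetadata(table=pd.DataFrame(
            {"group": ["KC"] * 3, "Na": [1, 2, 3.0]}, index=metrics.index))
        with pytest.raises(ValueError):
            nw.subnetwork_env_correlation(metrics, meta)
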