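from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from radionet import (
    ClassificationThresholds,
    SweepConfig,
    classify_nodes,
    degree_stratify,
    extract_subnetworks,
    k_sweep,
    node_metrics,
)
from radionet.network import RadiomicGraph
from radionet.topology import NodeMetrics, _randomness_score
from tests._oracles import (
    brute_betweenness,
    brute_clustering,
    brute_degree,
    dyadic_weights,
)
from tests.conftest import two_blob_table


def graph_from_weights(nodes, weights, threshold=0.0):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=float(w), length=float(1 - Fraction(w)))
    return RadiomicGraph(graph=g, edge_threshold=threshold, cluster_ids=list(nodes))


def uniform_graph(edges, w=0.5):
    nodes = sorted({n for e in edges for n in e})
    return graph_from_weights(nodes, {tuple(sorted(e)): Fraction(w) for e in edges})


class TestNodeMetrics:
    def test_triangle(self):
        g = uniform_graph([(0, 1), (1, 2), (0, 2)])
        m = node_metrics(g)
        np.testing.assert_allclose(m.cc, 1.0)
        np.testing.assert_allclose(m.betweenness_raw, 0.0)
        np.testing.assert_allclose(m.degree, 0.0)  # all equal -> min-max 0

    def test_star_center(self):
        g = uniform_graph([(0, i) for i in range(1, 5)])
        m = node_metrics(g)
        i_center = m.nodes.index(0)
        assert m.betweenness_raw[i_center] == pytest.approx(1.0)
        assert m.cc[i_center] == 0.0
        leaves = [i for i in range(5) if i != i_center]
        np.testing.assert_allclose(m.betweenness_raw[leaves], 0.0)
        assert m.degree[i_center] == 1.0

    def test_isolated_node_all_zero(self):
        g = graph_from_weights([0, 1, 2], {(0, 1): Fraction(1, 2)})
        m = node_metrics(g)
        i = m.nodes.index(2)
        assert m.degree_raw[i] == 0 and m.cc[i] == 0 and m.betweenness_raw[i] == 0

    def test_single_node_rejected(self):
        g = graph_from_weights([0], {})
        with pytest.raises(ValueError, match="2 nodes"):
            node_metrics(g)

    def test_matches_bruteforce_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            n = int(rng.integers(3, 7))
            edges = [
                (a, b)
                for a in range(n)
                for b in range(a + 1, n)
                if rng.random() < 0.5
            ]
            if not edges:
                continue
            weights = dyadic_weights(edges)
            g = graph_from_weights(list(range(n)), weights)
            m = node_metrics(g)
            lengths = {e: 1 - w for e, w in weights.items()}
            deg = brute_degree(list(range(n)), weights)
            cc = brute_clustering(list(range(n)), weights)
            bet = brute_betweenness(list(range(n)), lengths)
            for i, node in enumerate(m.nodes):
                assert m.degree_raw[i] == pytest.approx(float(deg[node]), abs=1e-9)
                assert m.cc[i] == pytest.approx(float(cc[node]), abs=1e-9)
                assert m.betweenness_raw[i] == pytest.approx(float(bet[node]), abs=1e-9)


class TestClassifyNodes:
    def _metrics(self, rows):
        """rows: list of (degree, cc, betweenness) already normalized."""
        deg = np.array([r[0] for r in rows], float)
        cc = np.array([r[1] for r in rows], float)
        bet = np.array([r[2] for r in rows], float)
        return NodeMetrics(
            nodes=list(range(len(rows))),
            degree_raw=deg,
            degree=deg,
            cc=cc,
            betweenness_raw=bet,
            betweenness=bet,
        )

    def test_bridge_rule(self):
        m = self._metrics([(0.15, 0.0, 0.85), (0.5, 0.5, 0.5)])
        roles = classify_nodes(m).role
        assert roles[0] == "bridge"

    def test_cluster_member_rule(self):
        m = self._metrics([(0.4, 0.9, 0.1), (0.5, 0.2, 0.2), (0.3, 0.1, 0.1), (0.2, 0.0, 0.0)])
        roles = classify_nodes(m).role
        assert roles[0] == "cluster_member"

    def test_isolated_node_unclassified(self):
        m = self._metrics([(0.0, 0.0, 0.0), (0.5, 0.5, 0.5), (0.6, 0.3, 0.2)])
        roles = classify_nodes(m).role
        assert roles[0] == "unclassified"

    def test_hub_beats_authority(self):
        m = self._metrics([(0.9, 0.0, 0.0), (0.1, 0.0, 0.0), (0.2, 0.0, 0.0), (0.3, 0.0, 0.0)])
        roles = classify_nodes(m).role
        assert roles[0] == "hub"

    def test_bridge_precedence_over_hub(self):
        thr = ClassificationThresholds(deg_lo=0.95, deg_hi=0.8)
        m = self._metrics([(0.9, 0.0, 0.9), (0.1, 0.0, 0.0), (0.2, 0.0, 0.0)])
        roles = classify_nodes(m, thr).role
        assert roles[0] == "bridge"

    def test_roles_total_and_exclusive(self):
        rng = np.random.default_rng(4)
        m = self._metrics([tuple(rng.uniform(0, 1, 3)) for _ in range(30)])
        cls = classify_nodes(m)
        assert sorted(cls.role) == sorted(m.nodes)
        assert all(isinstance(r, str) for r in cls.role.values())

    def test_invalid_thresholds(self):
        m = self._metrics([(0.5, 0.5, 0.5), (0.1, 0.1, 0.1)])
        with pytest.raises(ValueError, match="outside"):
            classify_nodes(m, ClassificationThresholds(bet_hi=1.2))


class TestExtractSubnetworks:
    def _classified(self, g, bridge_nodes=()):
        m = node_metrics(g)
        cls = classify_nodes(m)
        for b in bridge_nodes:
            cls.role[b] = "bridge"
        return cls

    def test_barbell_split_by_bridge(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 6), (6, 3)]
        g = uniform_graph(edges)
        cls = self._classified(g, bridge_nodes=[6])
        cls = extract_subnetworks(g, cls, min_size=3)
        assert cls.subnetwork_id[6] is None
        sids = {cls.subnetwork_id[n] for n in [0, 1, 2]}
        assert len(sids) == 1
        assert {cls.subnetwork_id[n] for n in [3, 4, 5]} != sids
        assert len(cls.major_subnetworks()) == 2

    def test_bridge_removal_increases_components(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 6), (6, 3)]
        g = uniform_graph(edges)
        before = nx.number_connected_components(g.graph)
        cls = self._classified(g, bridge_nodes=[6])
        cls = extract_subnetworks(g, cls, min_size=3)
        after = len({s for s in cls.subnetwork_id.values() if s is not None})
        assert after > before

    def test_no_bridges_components_identity(self):
        edges = [(0, 1), (1, 2), (3, 4)]
        g = uniform_graph(edges)
        cls = self._classified(g)
        assert not cls.nodes_with_role("bridge")
        cls = extract_subnetworks(g, cls, min_size=2)
        assert cls.subnetwork_id[0] == cls.subnetwork_id[1] == cls.subnetwork_id[2]
        assert cls.subnetwork_id[3] == cls.subnetwork_id[4] != cls.subnetwork_id[0]

    def test_small_components_flagged_satellite(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4)]
        g = uniform_graph(edges)
        cls = self._classified(g)
        cls = extract_subnetworks(g, cls, min_size=3)
        assert cls.satellite[3] and cls.satellite[4]
        assert not cls.satellite[0]
        assert cls.major_subnetworks() == [1]

    def test_ids_by_descending_size(self):
        from radionet.topology import NodeClassification

        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (5, 6), (3, 6)]
        g = uniform_graph(edges)
        cls = NodeClassification(
            nodes=list(range(7)), role={n: "unclassified" for n in range(7)}
        )
        cls = extract_subnetworks(g, cls, min_size=3)
        assert cls.subnetwork_id[3] == 1  # 4-node component first
        assert cls.subnetwork_id[0] == 2


class TestDegreeStratify:
    def _graph_with_degrees(self, degrees):
        """Star-like construction giving node i weighted degree degrees[i]
        via self-contained leaf edges is hard; instead use explicit weights
        on a hub-free chain: attach each node to a private anchor."""
        g = nx.Graph()
        nodes = list(range(len(degrees)))
        g.add_nodes_from(nodes)
        for i, d in enumerate(degrees):
            anchor = 100 + i
            g.add_edge(i, anchor, weight=float(d), length=1.0 - min(d, 0.99))
        return RadiomicGraph(graph=g, edge_threshold=0.0, cluster_ids=nodes + [100 + i for i in nodes])

    def _classification(self, members):
        from radionet.topology import NodeClassification

        return NodeClassification(
            nodes=members,
            role={n: "unclassified" for n in members},
            subnetwork_id={n: 1 for n in members},
            satellite={n: False for n in members},
        )

    def test_ladder_quartiles(self):
        degrees = [1, 2, 3, 4, 5, 6, 7, 8]
        g = self._graph_with_degrees([d / 10 for d in degrees])
        cls = self._classification(list(range(8)))
        groups = degree_stratify(g, cls, 1, n_groups=4)
        assert groups == {0: 1, 1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 4, 7: 4}

    def test_all_equal_single_group_warns(self):
        g = self._graph_with_degrees([0.5] * 6)
        cls = self._classification(list(range(6)))
        with pytest.warns(UserWarning, match="single stratum"):
            groups = degree_stratify(g, cls, 1, n_groups=4)
        assert set(groups.values()) == {1}

    def test_fewer_nodes_than_groups(self):
        g = self._graph_with_degrees([0.1, 0.2, 0.3])
        cls = self._classification([0, 1, 2])
        with pytest.warns(UserWarning, match="3 nodes"):
            groups = degree_stratify(g, cls, 1, n_groups=4)
        assert sorted(groups.values()) == [1, 2, 3]

    def test_empty_subnetwork_rejected(self):
        g = self._graph_with_degrees([0.1, 0.2])
        cls = self._classification([0, 1])
        with pytest.raises(ValueError, match="empty"):
            degree_stratify(g, cls, 99)

    def test_groups_ordered_by_degree(self):
        rng = np.random.default_rng(2)
        degrees = rng.uniform(0.05, 0.95, size=13)
        g = self._graph_with_degrees(degrees)
        cls = self._classification(list(range(13)))
        groups = degree_stratify(g, cls, 1, n_groups=4)
        for a in range(13):
            for b in range(13):
                if groups[a] < groups[b]:
                    assert degrees[a] <= degrees[b] + 1e-12


class TestRandomnessScore:
    def test_complete_graph_scores_one(self):
        g = uniform_graph([(a, b) for a in range(5) for b in range(a + 1, 5)])
        score, mean_cc, density = _randomness_score(g, eps=1e-9)
        assert density == 1.0 and mean_cc == 1.0 and score == 1.0

    def test_empty_graph_scores_zero(self):
        g = graph_from_weights([0, 1, 2], {})
        score, _, density = _randomness_score(g, eps=1e-9)
        assert score == 0.0 and density == 0.0


class TestKSweep:
    def test_report_shape_and_monotone_k(self, blob_table):
        cfg = SweepConfig(n_reseeds=2)
        rep = k_sweep(blob_table, [2, 4, 8, 6], seed=0, config=cfg)
        assert list(rep.frame["k"]) == [2, 4, 6, 8]
        assert set(rep.frame.columns) >= {
            "k", "randomness_score", "edge_count", "mean_cc", "stability"
        }

    def test_deterministic(self, blob_table):
        cfg = SweepConfig(n_reseeds=2)
        r1 = k_sweep(blob_table, [2, 4], seed=3, config=cfg)
        r2 = k_sweep(blob_table, [2, 4], seed=3, config=cfg)
        assert r1.frame.equals(r2.frame)
        assert r1.overfit_onset == r2.overfit_onset

    def test_needs_two_ks(self, blob_table):
        with pytest.raises(ValueError, match="at least 2"):
            k_sweep(blob_table, [4], seed=0)

    def test_k_exceeding_rows_rejected(self, blob_table):
        with pytest.raises(ValueError, match="row count"):
            k_sweep(blob_table, [2, blob_table.n_rows], seed=0)

    def test_plot_written(self, blob_table, tmp_path):
        cfg = SweepConfig(n_reseeds=1)
        rep = k_sweep(blob_table, [2, 4], seed=0, config=cfg)
        out = tmp_path / "sweep.png"
        rep.plot(out)
        assert out.stat().st_size > 0

    def test_structured_beats_shredded(self):
        table = two_blob_table(n_per_blob=150, n_features=6, separation=15.0, seed=1)
        cfg = SweepConfig(n_reseeds=3)
        rep = k_sweep(table, [2, 60], seed=0, config=cfg)
        frame = rep.frame.set_index("k")
        assert frame.loc[60, "stability"] < frame.loc[2, "stability"]
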