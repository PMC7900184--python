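import math

import networkx as nx
import numpy as np
import pytest

from immunet.communities import UNASSIGNED, Partition
from immunet.errors import ConfigurationError, PipelineError
from immunet.netstats import (
    chain_test,
    chainness,
    collapse_in_partition,
    collapse_node_group,
    common_nodes_test,
    community_overlap,
    concentration_exact_p,
    concentration_test,
    partition_similarity_test,
)

from conftest import net_of, partition_of_sizes


def planted_trio_net(d_hub, d_periph, size=6, seed=0):
    """Three communities 0,1,2 (hub=0) with given inter-community densities
    and no within-community edges."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    nodes = list(range(3 * size))
    g.add_nodes_from(nodes)
    comm = {n: n // size for n in nodes}
    for u in nodes:
        for v in nodes:
            if u >= v or comm[u] == comm[v]:
                continue
            pair = {comm[u], comm[v]}
            dens = d_periph if pair == {1, 2} else d_hub
            if rng.random() < dens:
                g.add_edge(u, v)
    return net_of(g), Partition(comm)


class TestCollapse:
    def test_identical_neighbourhoods(self):
        g = nx.Graph([(0, 2), (0, 3), (1, 2), (1, 3)])
        net = collapse_node_group(net_of(g), [0, 1], "X")
        assert set(net.graph.neighbors("X")) == {2, 3}

    def test_only_internal_edge_gives_isolated_node(self):
        g = nx.Graph([(0, 1)])
        g.add_node(2)
        net = collapse_node_group(net_of(g), [0, 1], "X")
        assert set(net.graph.neighbors("X")) == set()
        assert net.n_nodes == 2

    def test_path_collapse(self):
        g = nx.path_graph(5)  # 0-1-2-3-4
        net = collapse_node_group(net_of(g), [1, 2, 3], "X")
        assert set(net.graph.edges) == {(0, "X"), (4, "X")} or set(
            map(frozenset, net.graph.edges)
        ) == {frozenset({0, "X"}), frozenset({4, "X"})}
        assert net.n_edges == 2

    def test_node_set_collapse(self):
        marked = {"a", "b", "c"}
        out = collapse_node_group(marked, ["a", "b"], "ab")
        assert out == {"ab", "c"}

    def test_absent_node_is_error(self):
        with pytest.raises(PipelineError):
            collapse_node_group({"a", "b"}, ["a", "z"], "X")

    def test_collapse_in_partition(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1, "e": 1})
        out = collapse_in_partition(p, ["c", "d"], "cd")
        assert out.assignment["cd"] == out.assignment["e"]
        assert "c" not in out.assignment


class TestConcentration:
    def test_exact_worked_case(self):
        # two communities of 3; all marked nodes in one; m=1 -> p = 2/C(6,3)
        p = partition_of_sizes([3, 3])
        marked = p.members(0)
        exact = concentration_exact_p(p, marked, m=1)
        assert exact == pytest.approx(2 / math.comb(6, 3))
        res = concentration_test(p, marked, m=1, n_null=10_000, seed=1)
        sigma = math.sqrt(0.1 * 0.9 / 10_000)
        assert abs(res.p_value - 0.1) <= 3 * sigma + 1e-4

    def test_all_nodes_marked_gives_p_one(self):
        p = partition_of_sizes([4, 3, 2])
        res = concentration_test(p, p.assigned_nodes(), m=2, n_null=500, seed=0)
        assert res.p_value == 1.0
        assert res.observed == 7  # the two largest communities hold 4 + 3 nodes
        assert res.null_tie_count == 500  # statistic is constant under the null

    def test_m_equals_k_gives_p_one(self):
        p = partition_of_sizes([4, 4])
        res = concentration_test(p, p.members(0), m=2, n_null=500, seed=0)
        assert res.p_value == 1.0

    def test_unassigned_marked_node_rejected(self):
        p = Partition({0: 0, 1: 0, 2: 1, 3: 1, 4: UNASSIGNED})
        with pytest.raises(PipelineError, match="collapse"):
            concentration_test(p, [0, 4], m=1, n_null=10, seed=0)

    def test_m_out_of_range(self):
        p = partition_of_sizes([3, 3])
        with pytest.raises(ConfigurationError):
            concentration_test(p, p.members(0), m=3, n_null=10, seed=0)

    @pytest.mark.parametrize("sizes,n_marked,m", [([4, 3], 3, 1), ([3, 3, 2], 4, 2)])
    def test_matches_exact_enumeration(self, sizes, n_marked, m):
        rng = np.random.default_rng(0)
        p = partition_of_sizes(sizes)
        marked = list(rng.choice(p.assigned_nodes(), size=n_marked, replace=False))
        exact = concentration_exact_p(p, marked, m=m)
        res = concentration_test(p, marked, m=m, n_null=20_000, seed=3)
        sigma = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_value - exact) <= 4 * sigma + 1e-3

    def test_reproducible(self):
        p = partition_of_sizes([5, 4, 3])
        a = concentration_test(p, p.members(1), m=1, n_null=200, seed=7)
        b = concentration_test(p, p.members(1), m=1, n_null=200, seed=7)
        assert a.p_value == b.p_value and a.null_exceed_count == b.null_exceed_count


class TestChain:
    def test_perfect_chain_statistic_is_one(self):
        net, p = planted_trio_net(d_hub=1.0, d_periph=0.0, size=4)
        assert chainness(net, p, (0, 1, 2)) == pytest.approx(1.0)

    def test_fully_connected_trio_statistic_zero(self):
        net, p = planted_trio_net(d_hub=1.0, d_periph=1.0, size=4)
        assert chainness(net, p, (0, 1, 2)) == pytest.approx(0.0)

    def test_statistic_invariant_under_peripheral_swap(self):
        net, p = planted_trio_net(d_hub=0.7, d_periph=0.2, size=5, seed=3)
        assert chainness(net, p, (0, 1, 2)) == pytest.approx(
            chainness(net, p, (0, 2, 1))
        )

    def test_planted_chain_detected(self):
        net, p = planted_trio_net(d_hub=0.8, d_periph=0.05, size=4, seed=7)
        res = chain_test(net, p, (0, 1, 2), n_null=1000, seed=7)
        assert res.p_value < 0.05

    def test_too_few_inter_edges_rejected(self):
        g = nx.Graph([(0, 3)])
        g.add_nodes_from(range(9))
        p = partition_of_sizes([3, 3, 3])
        with pytest.raises(PipelineError):
            chain_test(net_of(g), p, (0, 1, 2), n_null=10, seed=0)

    def test_reproducible(self):
        net, p = planted_trio_net(d_hub=0.6, d_periph=0.2, size=5, seed=1)
        a = chain_test(net, p, (0, 1, 2), n_null=100, seed=5)
        b = chain_test(net, p, (0, 1, 2), n_null=100, seed=5)
        assert a.p_value == b.p_value


class TestCommunityOverlap:
    def test_identical_partitions_diagonal_one(self):
        p = partition_of_sizes([4, 3, 2])
        ov = community_overlap(p, p)
        jac = ov.jaccard.to_numpy()
        assert np.allclose(np.diag(jac), 1.0)

    def test_disjoint_communities_zero(self):
        a = Partition({0: 0, 1: 0, 2: 1, 3: 1})
        b = Partition({0: 1, 1: 1, 2: 0, 3: 0})
        ov = community_overlap(a, b)
        # a's community {0,1} vs b's community {2,3}: no overlap
        assert ov.common_counts.to_numpy()[0, 1] == 0
        assert ov.jaccard.to_numpy()[0, 1] == 0.0

    def test_two_common_nodes_jaccard(self):
        a_members = [f"a{i}" for i in range(12)] + ["x", "y"]  # |A| = 14
        b_members = [f"b{i}" for i in range(15)] + ["x", "y"]  # |B| = 17
        assignment_a = {n: 0 for n in a_members}
        assignment_b = {n: 0 for n in b_members}
        # complete both partitions over the union so universes match
        for n in b_members:
            assignment_a.setdefault(n, 1)
        for n in a_members:
            assignment_b.setdefault(n, 1)
        ov = community_overlap(Partition(assignment_a), Partition(assignment_b))
        counts = ov.common_counts.to_numpy()
        jac = ov.jaccard.to_numpy()
        i = ov.community_ids_a.index(1)  # |A|=14 community is the smaller one
        j = ov.community_ids_b.index(0)
        assert counts[i, j] == 2
        assert jac[i, j] == pytest.approx(2 / 29, abs=1e-12)
        assert round(jac[i, j], 2) == 0.07

    def test_counts_sum_to_shared_assigned_nodes(self):
        rng = np.random.default_rng(2)
        nodes = list(range(30))
        a = Partition({n: int(rng.integers(0, 4)) for n in nodes})
        b = Partition({n: int(rng.integers(0, 3)) for n in nodes[5:]})
        ov = community_overlap(a, b)
        assert ov.common_counts.to_numpy().sum() == 25

    def test_no_shared_nodes_is_error(self):
        a = Partition({0: 0, 1: 0})
        b = Partition({2: 0, 3: 0})
        with pytest.raises(PipelineError):
            community_overlap(a, b)


class TestCommonNodes:
    def test_degenerate_all_in_one_group(self):
        res = common_nodes_test(
            range(10), (10, 0, 0), (10, 0, 0), pair=(0, 0),
            observed_common=10, n_null=200, seed=0,
        )
        assert res.p_value == 1.0

    def test_null_mean_matches_hypergeometric(self):
        res = common_nodes_test(
            range(45), (15, 15, 15), (15, 15, 15), pair=(0, 0),
            observed_common=5, n_null=5000, seed=1,
        )
        assert res.null_mean == pytest.approx(15 * 15 / 45, abs=0.15)

    def test_observed_at_null_mean_gives_large_p(self):
        res = common_nodes_test(
            range(45), (15, 15, 15), (15, 15, 15), pair=(0, 0),
            observed_common=5, n_null=5000, seed=1,
        )
        assert res.p_value > 0.5

    def test_impossible_observation_rejected(self):
        with pytest.raises(ConfigurationError):
            common_nodes_test(
                range(20), (5, 5, 5), (5, 5, 5), pair=(0, 0),
                observed_common=6, n_null=10, seed=0,
            )

    def test_oversized_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            common_nodes_test(
                range(10), (5, 5, 5), (3, 3, 3), pair=(0, 0),
                observed_common=1, n_null=10, seed=0,
            )


class TestPartitionSimilarity:
    def test_identical_partitions(self):
        p = partition_of_sizes([5, 5, 5])
        res = partition_similarity_test(p, p, n_null=200, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_single_community_convention(self):
        a = partition_of_sizes([10])
        b = partition_of_sizes([5, 5])
        res = partition_similarity_test(a, b, n_null=100, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_permuted_labels_near_zero_ari(self):
        rng = np.random.default_rng(4)
        nodes = list(range(60))
        labels = np.repeat(np.arange(6), 10)
        a = Partition(dict(zip(nodes, labels)))
        b = Partition(dict(zip(nodes, labels[rng.permutation(60)])))
        res = partition_similarity_test(a, b, n_null=500, seed=2)
        assert abs(res.observed) < 0.15
        assert res.p_value > 0.01

    def test_unassigned_dropped(self):
        a = Partition({0: 0, 1: 0, 2: 1, 3: 1, 4: UNASSIGNED})
        b = partition_of_sizes([2, 3])
        res = partition_similarity_test(a, b, n_null=100, seed=0)
        assert res.parameters["n_shared_nodes"] == 4


class TestResultInvariants:
    def test_add_one_rule(self):
        p = partition_of_sizes([4, 4])
        res = concentration_test(p, p.members(0), m=1, n_null=333, seed=2)
        assert res.p_value == (1 + res.null_exceed_count) / (1 + 333)
        assert 0 < res.p_value <= 1

    def test_json_round_trip(self, tmp_path):
        import json

        p = partition_of_sizes([4, 4])
        res = concentration_test(p, p.members(0), m=1, n_null=100, seed=2)
        res.to_json(tmp_path / "r.json")
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["p_value"] == res.p_value
        assert payload["statistic_name"] == "marked_node_concentration"
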