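import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from immunet.communities import UNASSIGNED, Partition, description_length
from immunet.corrnet import ImmuneNetwork
from immunet.preprocess import ImmuneMatrix, MeasureAnnotation


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def make_matrix(values, missing=None, categories=None, environment="wild"):
    """ImmuneMatrix from a 2-D array; NaNs (or an explicit mask) are missing."""
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = ~np.isfinite(values)
    missing = np.asarray(missing, dtype=bool)
    n_s, n_m = values.shape
    measure_ids = [f"m{j}" for j in range(n_m)]
    if categories is None:
        cats = {m: MeasureAnnotation("X", "X") for m in measure_ids}
    else:
        cats = {
            m: MeasureAnnotation(categories[j], categories[j])
            for j, m in enumerate(measure_ids)
        }
    return ImmuneMatrix(
        subject_ids=[f"s{i}" for i in range(n_s)],
        measure_ids=measure_ids,
        categories=cats,
        values=values,
        missing_mask=missing,
        environment=environment,
    )


@pytest.fixture
def small_imputable_matrix():
    vals = np.array(
        [[1.0, 5.0, 2.0], [np.nan, np.nan, 4.0], [3.0, np.nan, 6.0], [5.0, 5.0, 8.0]]
    )
    return make_matrix(vals)


# ---------------------------------------------------------------------------
# Partition / graph helpers
# ---------------------------------------------------------------------------

def net_of(graph) -> ImmuneNetwork:
    return ImmuneNetwork(graph=graph)


def partition_of_sizes(sizes, source="external") -> Partition:
    assignment = {}
    node = 0
    for cid, size in enumerate(sizes):
        for _ in range(size):
            assignment[node] = cid
            node += 1
    return Partition(assignment, source=source)


def ari_against(partition: Partition, truth: Partition) -> float:
    nodes = [
        n for n in truth.assignment
        if partition.assignment.get(n, UNASSIGNED) != UNASSIGNED
    ]
    return adjusted_rand_score(
        [truth.assignment[n] for n in nodes],
        [partition.assignment[n] for n in nodes],
    )


# ---------------------------------------------------------------------------
# Exhaustive description-length oracle
# ---------------------------------------------------------------------------

def set_partitions(nodes):
    """All set partitions of a list (Bell-number many)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_min_dl(net: ImmuneNetwork, max_blocks=None):
    """Brute-force minimum description length over all partitions."""
    best_dl, best_assign = np.inf, None
    for part in set_partitions(list(net.nodes)):
        if max_blocks is not None and len(part) > max_blocks:
            continue
        assign = {}
        for cid, group in enumerate(part):
            for n in group:
                assign[n] = cid
        dl = description_length(net, Partition(assign))
        if dl < best_dl - 1e-12:
            best_dl, best_assign = dl, assign
    return best_dl, Partition(best_assign)


def small_graph_fixtures() -> dict[str, nx.Graph]:
    """Named graphs on <= 8 nodes used by the oracle-equivalence checks."""
    return {
        "path5": nx.path_graph(5),
        "path8": nx.path_graph(8),
        "cycle6": nx.cycle_graph(6),
        "cycle8": nx.cycle_graph(8),
        "K5": nx.complete_graph(5),
        "K8": nx.complete_graph(8),
        "star7": nx.star_graph(6),
        "two_K4": nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)),
        "barbell3_0": nx.barbell_graph(3, 0),
        "barbell3_2": nx.barbell_graph(3, 2),
        "K33": nx.complete_bipartite_graph(3, 3),
        "K24": nx.complete_bipartite_graph(2, 4),
        "gnp8a": nx.gnp_random_graph(8, 0.4, seed=1),
        "gnp8b": nx.gnp_random_graph(8, 0.5, seed=2),
        "gnp7": nx.gnp_random_graph(7, 0.45, seed=3),
        "wheel6": nx.wheel_graph(6),
    }


def brute_force_threshold(r: np.ndarray, sign: str = "positive") -> float:
    """Scan all sorted unique off-diagonal entries for the largest
    connectivity-preserving threshold (independent of the MST route)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    w = r if sign == "positive" else -r
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    for t in np.sort(np.unique(w[iu]))[::-1]:
        mask = w >= t
        np.fill_diagonal(mask, False)
        n_comp, _ = connected_components(sp.csr_matrix(mask), directed=False)
        if n_comp == 1:
            return float(t)
    raise AssertionError("graph with all edges should be connected")
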