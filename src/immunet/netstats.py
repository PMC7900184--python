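"""Randomization tests and cross-network comparison statistics.

All tests share the same reporting convention: the observed statistic, the
number of null replicates, the count of replicates at least as extreme, and
the add-one permutation p-value ``(1 + exceed) / (1 + n_null)`` (so p is
never exactly zero).  Each result also records the count of exact ties with
the observed value, which lets calibration checks form the randomized
p-value that is exactly uniform under the null even for discrete
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .communities import UNASSIGNED, Partition
from .corrnet import ImmuneNetwork, intercommunity_density
from .errors import ConfigurationError, PipelineError


@dataclass
class RandomizationTestResult:
    statistic_name: str
    observed: float
    n_null: int
    null_exceed_count: int
    p_value: float
    seed: int
    direction: str = "ge"  # ge | le | two_sided
    null_tie_count: int = 0
    null_mean: float | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (1 + self.null_exceed_count) / (1 + self.n_null)
        if abs(self.p_value - expected) > 1e-12:
            raise ValueError("p_value violates the add-one rule")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")

    def randomized_p(self, rng: np.random.Generator) -> float:
        """Tie-smoothed p-value, exactly Uniform(0,1) under the null."""
        greater = self.null_exceed_count - self.null_tie_count
        u = rng.random()
        return (greater + u * (self.null_tie_count + 1)) / (self.n_null + 1)

    def to_json(self, path) -> None:
        payload = {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "n_null": self.n_null,
            "null_exceed_count": self.null_exceed_count,
            "null_tie_count": self.null_tie_count,
            "null_mean": self.null_mean,
            "p_value": self.p_value,
            "seed": self.seed,
            "direction": self.direction,
            "parameters": self.parameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _one_sided_result(
    name: str,
    observed: float,
    null_values: np.ndarray,
    seed: int,
    parameters: dict,
    tol: float = 1e-9,
) -> RandomizationTestResult:
    null_values = np.asarray(null_values, dtype=float)
    exceed = int(np.sum(null_values >= observed - tol))
    ties = int(np.sum(np.abs(null_values - observed) <= tol))
    return RandomizationTestResult(
        statistic_name=name,
        observed=float(observed),
        n_null=len(null_values),
        null_exceed_count=exceed,
        p_value=(1 + exceed) / (1 + len(null_values)),
        seed=seed,
        direction="ge",
        null_tie_count=ties,
        null_mean=float(null_values.mean()),
        parameters=parameters,
    )


# ---------------------------------------------------------------------------
# Node collapsing
# ---------------------------------------------------------------------------

def collapse_node_group(obj, group, new_id):
    """Replace a group of nodes by a single node.

    On a network, the new node inherits the union of the group's external
    edges (internal edges vanish).  On a plain node set, the group simply
    counts as one marked node.
    """
    group = list(group)
    if len(group) < 2:
        raise ConfigurationError("collapse requires a group of >= 2 nodes")
    if isinstance(obj, ImmuneNetwork):
        g = obj.graph
        for node in group:
            if node not in g:
                raise PipelineError(f"node {node!r} not in network")
        merged = g.copy()
        neighbours = set()
        for node in group:
            neighbours.update(merged.neighbors(node))
        neighbours -= set(group)
        merged.remove_nodes_from(group)
        merged.add_node(new_id)
        merged.add_edges_from((new_id, v) for v in neighbours)
        return ImmuneNetwork(
            graph=merged, sign=obj.sign, threshold=obj.threshold
        )
    if isinstance(obj, (set, frozenset, list, tuple)):
        members = set(obj)
        missing = [n for n in group if n not in members]
        if missing:
            raise PipelineError(f"nodes {missing!r} not in set")
        return (members - set(group)) | {new_id}
    raise TypeError(f"cannot collapse nodes on {type(obj).__name__}")


def collapse_in_partition(p: Partition, group, new_id) -> Partition:
    """Collapse a group of same-community nodes inside a partition."""
    cids = {p.assignment.get(n) for n in group}
    if None in cids:
        raise PipelineError("group node absent from partition")
    if len(cids) != 1:
        raise PipelineError("cannot collapse nodes from different communities")
    assignment = {n: c for n, c in p.assignment.items() if n not in set(group)}
    assignment[new_id] = cids.pop()
    return Partition(assignment, source=p.source)


# ---------------------------------------------------------------------------
# Concentration of a marked node set
# ---------------------------------------------------------------------------

def _top_m_sum(counts: np.ndarray, m: int) -> int:
    if m >= len(counts):
        return int(counts.sum())
    return int(np.sort(counts)[::-1][:m].sum())


def concentration_test(
    p: Partition,
    marked,
    m: int,
    n_null: int = 10_000,
    seed: int = 0,
) -> RandomizationTestResult:
    """Are the marked nodes more concentrated into ``m`` communities than a
    random placement of equally many nodes would be?

    The statistic is the largest number of marked nodes containable in
    ``m`` communities (sum of the ``m`` largest per-community marked
    counts).  Null replicates redraw the marked node positions uniformly
    without replacement among all assigned nodes, holding the partition and
    community sizes fixed.
    """
    marked = list(marked)
    assigned = p.assigned_nodes()
    assigned_set = set(assigned)
    for node in marked:
        if node not in p.assignment:
            raise PipelineError(f"marked node {node!r} not in partition")
        if p.assignment[node] == UNASSIGNED:
            raise PipelineError(
                f"marked node {node!r} is unassigned; drop or collapse it first"
            )
    if not assigned_set:
        raise PipelineError("partition has no assigned nodes")
    k = p.n_communities
    if not 1 <= m <= k:
        raise ConfigurationError(f"m={m} outside 1..{k}")

    labels = np.array([p.assignment[n] for n in assigned])
    marked_idx = np.array([assigned.index(n) for n in marked])
    observed = _top_m_sum(np.bincount(labels[marked_idx], minlength=k), m)

    rng = np.random.default_rng(seed)
    null = np.empty(n_null, dtype=float)
    n_assigned, n_marked = len(assigned), len(marked)
    for rep in range(n_null):
        idx = rng.choice(n_assigned, size=n_marked, replace=False)
        null[rep] = _top_m_sum(np.bincount(labels[idx], minlength=k), m)
    return _one_sided_result(
        "marked_node_concentration",
        observed,
        null,
        seed,
        {"m": m, "n_marked": n_marked, "n_communities": k},
    )


def concentration_exact_p(p: Partition, marked, m: int) -> float:
    """Exact enumeration analogue of :func:`concentration_test` (oracle for
    small partitions; exponential in the marked-set size)."""
    from itertools import combinations

    assigned = p.assigned_nodes()
    labels = np.array([p.assignment[n] for n in assigned])
    k = p.n_communities
    marked_idx = [assigned.index(n) for n in marked]
    observed = _top_m_sum(np.bincount(labels[marked_idx], minlength=k), m)
    total = hits = 0
    for combo in combinations(range(len(assigned)), len(marked)):
        t = _top_m_sum(np.bincount(labels[list(combo)], minlength=k), m)
        total += 1
        hits += t >= observed
    return hits / total


# ---------------------------------------------------------------------------
# Chain-likeness of a community trio
# ---------------------------------------------------------------------------

def _chainness_from_densities(d_hx: float, d_hy: float, d_xy: float) -> float:
    return min(d_hx, d_hy) - d_xy


def chainness(net: ImmuneNetwork, p: Partition, trio) -> float:
    """max over hub choice of min(density(hub, X), density(hub, Y)) -
    density(X, Y); equals 1 for a perfect chain, 0 for a symmetric trio."""
    a, b, c = trio
    d_ab = intercommunity_density(net, p, a, b)
    d_ac = intercommunity_density(net, p, a, c)
    d_bc = intercommunity_density(net, p, b, c)
    return max(
        _chainness_from_densities(d_ab, d_ac, d_bc),  # hub = a
        _chainness_from_densities(d_ab, d_bc, d_ac),  # hub = b
        _chainness_from_densities(d_ac, d_bc, d_ab),  # hub = c
    )


def _double_edge_swaps(
    edges: list[tuple[int, int]], n_attempts: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Degree-preserving rewiring by repeated double-edge swap attempts."""
    edges = [tuple(e) for e in edges]
    edge_set = {frozenset(e) for e in edges}
    n_edges = len(edges)
    for _ in range(n_attempts):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed swap: (a, d), (c, b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i], edges[j] = (a, d), (c, b)
    return edges


def chain_test(
    net: ImmuneNetwork,
    p: Partition,
    trio,
    n_null: int = 10_000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> RandomizationTestResult:
    """Is the trio's connection pattern more chain-like than in
    degree-preserving rewirings of the induced subgraph?

    Community labels stay fixed; each null replicate applies
    ``swaps_per_edge * e`` double-edge-swap attempts to the subgraph
    induced by the trio's nodes.
    """
    trio = tuple(trio)
    nodes = [n for c in trio for n in p.members(c)]
    if len({p.assignment[n] for n in nodes}) != 3:
        raise PipelineError("trio must consist of three non-empty communities")
    sub = net.graph.subgraph(nodes)
    label_of = {n: p.assignment[n] for n in nodes}
    inter_edges = sum(1 for u, v in sub.edges if label_of[u] != label_of[v])
    if inter_edges < 2:
        raise PipelineError(
            "fewer than 2 inter-community edges; chain statistic uninformative"
        )
    sizes = {c: len(p.members(c)) for c in trio}

    def stat(edge_list) -> float:
        counts = {}
        for u, v in edge_list:
            cu, cv = label_of[u], label_of[v]
            if cu != cv:
                key = (min(cu, cv), max(cu, cv))
                counts[key] = counts.get(key, 0) + 1
        a, b, c = trio
        d = {}
        for x, y in ((a, b), (a, c), (b, c)):
            key = (min(x, y), max(x, y))
            d[(x, y)] = counts.get(key, 0) / (sizes[x] * sizes[y])
        return max(
            _chainness_from_densities(d[(a, b)], d[(a, c)], d[(b, c)]),
            _chainness_from_densities(d[(a, b)], d[(b, c)], d[(a, c)]),
            _chainness_from_densities(d[(a, c)], d[(b, c)], d[(a, b)]),
        )

    edges = list(sub.edges)
    observed = stat(edges)
    rng = np.random.default_rng(seed)
    n_attempts = swaps_per_edge * len(edges)
    null = np.empty(n_null, dtype=float)
    for rep in range(n_null):
        null[rep] = stat(_double_edge_swaps(edges, n_attempts, rng))
    return _one_sided_result(
        "chain_likeness",
        observed,
        null,
        seed,
        {"trio": list(trio), "swaps_per_edge": swaps_per_edge},
    )


# ---------------------------------------------------------------------------
# Cross-network community comparison
# ---------------------------------------------------------------------------

@dataclass
class CommunityOverlap:
    """Pairwise common-node counts and Jaccard indices between the
    communities of two partitions, restricted to their shared nodes."""

    community_ids_a: list
    community_ids_b: list
    common_counts: pd.DataFrame
    jaccard: pd.DataFrame

    def write(self, counts_path, jaccard_path) -> None:
        self.common_counts.to_csv(counts_path, sep="\t")
        self.jaccard.to_csv(jaccard_path, sep="\t")


def community_overlap(a: Partition, b: Partition) -> CommunityOverlap:
    shared = [n for n in a.assignment if n in b.assignment]
    shared = [
        n for n in shared
        if a.assignment[n] != UNASSIGNED and b.assignment[n] != UNASSIGNED
    ]
    if not shared:
        raise PipelineError("partitions share no assigned nodes")
    ar = a.restricted_to(shared)
    br = b.restricted_to(shared)
    ids_a = sorted(ar.community_sizes())
    ids_b = sorted(br.community_sizes())
    counts = np.zeros((len(ids_a), len(ids_b)), dtype=int)
    jac = np.zeros_like(counts, dtype=float)
    sets_a = {i: set(ar.members(i)) for i in ids_a}
    sets_b = {j: set(br.members(j)) for j in ids_b}
    for i, ca in enumerate(ids_a):
        for j, cb in enumerate(ids_b):
            inter = len(sets_a[ca] & sets_b[cb])
            union = len(sets_a[ca] | sets_b[cb])
            counts[i, j] = inter
            jac[i, j] = inter / union if union else 0.0
    index = [f"A{i}" for i in ids_a]
    columns = [f"B{j}" for j in ids_b]
    return CommunityOverlap(
        community_ids_a=ids_a,
        community_ids_b=ids_b,
        common_counts=pd.DataFrame(counts, index=index, columns=columns),
        jaccard=pd.DataFrame(jac, index=index, columns=columns),
    )


def common_nodes_test(
    node_universe,
    sizes_a,
    sizes_b,
    pair: tuple[int, int],
    observed_common: int,
    n_null: int = 10_000,
    seed: int = 0,
) -> RandomizationTestResult:
    """Is the overlap between community i of network A and community j of
    network B different from random assignment into communities of the same
    sizes?  Two-sided on the deviation from the null-mean overlap."""
    universe = list(node_universe)
    sizes_a = tuple(int(s) for s in sizes_a)
    sizes_b = tuple(int(s) for s in sizes_b)
    for name, sizes in (("sizes_a", sizes_a), ("sizes_b", sizes_b)):
        if sum(sizes) > len(universe):
            raise ConfigurationError(f"{name} sum exceeds the node universe")
    i, j = pair
    if observed_common > min(sizes_a[i], sizes_b[j]):
        raise ConfigurationError(
            f"observed_common={observed_common} impossible for community sizes"
        )
    off_a = sum(sizes_a[:i])
    off_b = sum(sizes_b[:j])
    rng = np.random.default_rng(seed)
    n = len(universe)
    null = np.empty(n_null, dtype=float)
    for rep in range(n_null):
        perm_a = rng.permutation(n)[off_a: off_a + sizes_a[i]]
        perm_b = rng.permutation(n)[off_b: off_b + sizes_b[j]]
        null[rep] = len(np.intersect1d(perm_a, perm_b, assume_unique=True))
    mean = null.mean()
    dev_obs = abs(observed_common - mean)
    dev_null = np.abs(null - mean)
    exceed = int(np.sum(dev_null >= dev_obs - 1e-9))
    ties = int(np.sum(np.abs(dev_null - dev_obs) <= 1e-9))
    return RandomizationTestResult(
        statistic_name="common_nodes",
        observed=float(observed_common),
        n_null=n_null,
        null_exceed_count=exceed,
        p_value=(1 + exceed) / (1 + n_null),
        seed=seed,
        direction="two_sided",
        null_tie_count=ties,
        null_mean=float(mean),
        parameters={
            "sizes_a": list(sizes_a),
            "sizes_b": list(sizes_b),
            "pair": list(pair),
            "universe_size": n,
        },
    )


def partition_similarity_test(
    a: Partition,
    b: Partition,
    n_null: int = 10_000,
    seed: int = 0,
) -> RandomizationTestResult:
    """Adjusted Rand index between the partitions on their shared assigned
    nodes, against a null that permutes one side's labels over nodes.

    If either partition has a single community on the shared nodes the ARI
    is 0 by convention.
    """
    shared = [
        n for n in a.assignment
        if n in b.assignment
        and a.assignment[n] != UNASSIGNED
        and b.assignment[n] != UNASSIGNED
    ]
    if len(shared) < 2:
        raise PipelineError("fewer than 2 shared assigned nodes")
    la = np.array([a.assignment[n] for n in shared])
    lb = np.array([b.assignment[n] for n in shared])

    def ari(x, y) -> float:
        if len(set(x)) < 2 or len(set(y)) < 2:
            return 0.0
        return float(adjusted_rand_score(x, y))

    observed = ari(la, lb)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null, dtype=float)
    for rep in range(n_null):
        null[rep] = ari(la, lb[rng.permutation(len(lb))])
    return _one_sided_result(
        "partition_ari",
        observed,
        null,
        seed,
        {"n_shared_nodes": len(shared)},
    )
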