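"""Community detection: repeated SBM fits combined into a consensus partition.

Single fits minimize the degree-corrected microcanonical SBM description
length (exact formula documented in :mod:`immunet._sbm`).  The consensus
step runs many seeded fits, counts how often each node pair lands in the
same community, links pairs whose co-classification frequency reaches a
stability threshold, and takes connected components of that link graph as
the consensus communities.  Nodes left in a singleton component have no
stable partner and are reported as unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._sbm import BlockState, minimize_dl
from .corrnet import ImmuneNetwork
from .errors import ConfigurationError, PipelineError

#: Distinguished assignment value for nodes outside every consensus community.
UNASSIGNED = "UNASSIGNED"


def _member_sort_key(members):
    try:
        return min(members)
    except TypeError:
        return min(str(x) for x in members)


@dataclass
class Partition:
    """Node -> community assignment permitting an explicit unassigned state.

    Community ids are canonical: contiguous integers 0..K-1 ordered by
    descending community size, ties broken by smallest member id.
    """

    assignment: dict
    source: str = "external"

    def __post_init__(self) -> None:
        self.canonicalize()

    def canonicalize(self) -> None:
        groups: dict = {}
        for node, cid in self.assignment.items():
            if cid != UNASSIGNED:
                groups.setdefault(cid, []).append(node)
        order = sorted(
            groups.values(), key=lambda ms: (-len(ms), _member_sort_key(ms))
        )
        relabel = {}
        for new_id, members in enumerate(order):
            for node in members:
                relabel[node] = new_id
        self.assignment = {
            node: relabel.get(node, UNASSIGNED) for node in self.assignment
        }

    @classmethod
    def from_labels(cls, nodes, labels, source: str = "external") -> "Partition":
        return cls({n: int(l) for n, l in zip(nodes, labels)}, source=source)

    @property
    def nodes(self) -> list:
        return list(self.assignment)

    @property
    def n_communities(self) -> int:
        return len({c for c in self.assignment.values() if c != UNASSIGNED})

    def members(self, cid) -> list:
        return [n for n, c in self.assignment.items() if c == cid]

    def community_sizes(self) -> dict:
        sizes: dict = {}
        for c in self.assignment.values():
            if c != UNASSIGNED:
                sizes[c] = sizes.get(c, 0) + 1
        return dict(sorted(sizes.items()))

    def assigned_nodes(self) -> list:
        return [n for n, c in self.assignment.items() if c != UNASSIGNED]

    def unassigned_nodes(self) -> list:
        return [n for n, c in self.assignment.items() if c == UNASSIGNED]

    def restricted_to(self, nodes) -> "Partition":
        return Partition(
            {n: self.assignment[n] for n in nodes if n in self.assignment},
            source=self.source,
        )

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"node_id": list(self.assignment), "community_id": list(self.assignment.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, source: str = "external") -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
        assignment = {}
        for _, row in df.iterrows():
            cid = row["community_id"]
            assignment[row["node_id"]] = (
                UNASSIGNED if str(cid) == UNASSIGNED else int(cid)
            )
        return cls(assignment, source=source)


@dataclass
class ConsensusSummary:
    """Co-classification frequencies and provenance of a consensus run."""

    nodes: list
    coassignment: np.ndarray
    n_runs: int
    stability_threshold: float
    per_run_description_lengths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coassignment = np.asarray(self.coassignment, dtype=float)
        if not np.allclose(self.coassignment, self.coassignment.T):
            raise ValueError("coassignment matrix must be symmetric")
        if not np.allclose(np.diag(self.coassignment), 1.0):
            raise ValueError("coassignment diagonal must be 1")

    def write(self, tsv_path, json_path) -> None:
        pd.DataFrame(
            self.coassignment, index=self.nodes, columns=self.nodes
        ).to_csv(tsv_path, sep="\t")
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "n_runs": self.n_runs,
                    "stability_threshold": self.stability_threshold,
                    "per_run_description_lengths": self.per_run_description_lengths,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------


def _adjacency(net: ImmuneNetwork, nodes: list) -> list[np.ndarray]:
    index = {u: i for i, u in enumerate(nodes)}
    return [
        np.array(sorted(index[v] for v in net.graph.neighbors(u)), dtype=np.int64)
        for u in nodes
    ]


def fit_sbm(net: ImmuneNetwork, seed: int) -> tuple[Partition, float]:
    """Single description-length-minimizing SBM fit (deterministic per seed).

    The number of blocks is selected by the objective, not fixed in advance.
    """
    if net.n_edges == 0:
        raise PipelineError("cannot fit an SBM to an edgeless network")
    nodes = net.nodes
    labels, dl = minimize_dl(_adjacency(net, nodes), seed)
    return Partition.from_labels(nodes, labels, source="single_run"), dl


def description_length(net: ImmuneNetwork, p: Partition) -> float:
    """Exact description length of ``net`` under partition ``p`` (nats)."""
    nodes = net.nodes
    labels = []
    for n in nodes:
        if n not in p.assignment:
            raise PipelineError(f"partition does not cover node {n!r}")
        cid = p.assignment[n]
        if cid == UNASSIGNED:
            raise PipelineError(f"node {n!r} is unassigned; cannot score")
        labels.append(cid)
    state = BlockState(_adjacency(net, nodes), np.asarray(labels))
    return state.full_dl()


def consensus_from_labels(
    nodes: list, label_runs: list[np.ndarray], theta: float
) -> tuple[Partition, np.ndarray]:
    """Combine per-run label vectors into a consensus partition.

    Returns the partition and the co-classification frequency matrix.
    """
    if not 0.5 < theta <= 1.0:
        raise ConfigurationError(f"stability threshold {theta} outside (0.5, 1]")
    n = len(nodes)
    runs = np.asarray(label_runs)
    co = np.zeros((n, n), dtype=float)
    for labels in runs:
        co += labels[:, None] == labels[None, :]
    co /= len(runs)

    stable = co >= theta - 1e-9
    np.fill_diagonal(stable, True)
    # connected components of the stable-pair graph (union-find)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if stable[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    assignment: dict = {}
    next_id = 0
    for members in comps.values():
        if len(members) == 1:
            assignment[nodes[members[0]]] = UNASSIGNED
        else:
            for i in members:
                assignment[nodes[i]] = next_id
            next_id += 1
    return Partition(assignment, source="consensus"), co


def consensus_partition(
    net: ImmuneNetwork,
    n_runs: int = 100,
    theta: float = 0.9,
    seed: int = 0,
) -> tuple[Partition, ConsensusSummary]:
    """Run ``n_runs`` SBM fits (seeds ``seed .. seed + n_runs - 1``) and form
    the consensus partition of stable co-classified node pairs."""
    if n_runs < 2:
        raise ConfigurationError("consensus requires n_runs >= 2")
    nodes = net.nodes
    adj = _adjacency(net, nodes)
    if net.n_edges == 0:
        raise PipelineError("cannot fit an SBM to an edgeless network")
    label_runs = []
    dls = []
    for r in range(n_runs):
        labels, dl = minimize_dl(adj, seed + r)
        label_runs.append(labels)
        dls.append(float(dl))
    partition, co = consensus_from_labels(nodes, label_runs, theta)
    summary = ConsensusSummary(
        nodes=nodes,
        coassignment=co,
        n_runs=n_runs,
        stability_threshold=theta,
        per_run_description_lengths=dls,
    )
    return partition, summary
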