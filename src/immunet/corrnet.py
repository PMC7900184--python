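"""Pearson correlation matrices and thresholded correlation networks.

A network is built by placing an edge between two measures whenever their
correlation passes a threshold ``t`` (``r >= t`` for the positive network,
``r <= -t`` for the negative one).  The working threshold is the
*bottleneck* value: the largest ``t`` at which the thresholded graph is
still a single connected component.  It equals the minimum edge weight on
the maximum spanning tree of the (sign-adjusted) correlation matrix, and is
always an actual matrix entry.

The closed rule (``>=``) is deliberate: with a strict inequality no largest
connecting threshold exists, so the bottleneck value with ``>=`` is the
unique well-defined reading.  Ties at the threshold are all included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, PipelineError
from .preprocess import ImmuneMatrix, MeasureAnnotation

POSITIVE = "positive"
NEGATIVE = "negative"

_SYM_TOL = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over measures, with the sample count used."""

    measure_ids: list[str]
    r: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.measure_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"r shape {self.r.shape} != ({n}, {n})")
        if np.max(np.abs(self.r - self.r.T)) > _SYM_TOL:
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=_SYM_TOL):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.max(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.measure_ids, columns=self.measure_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class ImmuneNetwork:
    """Unweighted graph over measures, from thresholding a correlation matrix.

    ``graph`` is a :class:`networkx.Graph` whose nodes carry ``category`` /
    ``subcategory`` attributes when known.  ``sign`` and ``threshold`` record
    how the edge set was derived (both may be None for synthetic fixtures).
    """

    graph: nx.Graph
    sign: str | None = None
    threshold: float | None = None
    correlations: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def write_edgelist_tsv(self, path) -> None:
        rows = []
        for u, v in self.graph.edges:
            key = (u, v) if (u, v) in self.correlations else (v, u)
            rows.append((u, v, self.correlations.get(key, np.nan)))
        pd.DataFrame(rows, columns=["node_a", "node_b", "r"]).to_csv(
            path, sep="\t", index=False
        )

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.sign is not None:
            g.graph["sign"] = self.sign
        if self.threshold is not None:
            g.graph["threshold"] = float(self.threshold)
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------


def pearson_matrix(m: ImmuneMatrix) -> CorrelationMatrix:
    """Pearson correlation between all measure pairs, each subject a sample.

    Requires a fully imputed matrix with at least 3 subjects and nonzero
    variance for every measure.
    """
    if not m.is_fully_imputed():
        raise PipelineError("matrix still has missing values; impute first")
    if m.n_subjects < 3:
        raise PipelineError(f"need >= 3 subjects, got {m.n_subjects}")
    stds = m.values.std(axis=0)
    for mid, s in zip(m.measure_ids, stds):
        if s == 0:
            raise PipelineError(
                f"measure {mid!r} has zero variance; correlation undefined"
            )
    r = np.corrcoef(m.values, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(list(m.measure_ids), r, m.n_subjects)


def select_threshold(c: CorrelationMatrix, sign: str = POSITIVE) -> float:
    """Largest threshold at which the thresholded network stays connected.

    Computed as the bottleneck of the maximum spanning tree of the
    sign-adjusted weight matrix (``w = r`` for positive, ``w = -r`` for
    negative networks).  The returned value is an exact matrix entry.
    """
    n = len(c.measure_ids)
    if n < 2:
        raise PipelineError("need at least 2 measures to select a threshold")
    w = c.r if sign == POSITIVE else -c.r
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    g.add_weighted_edges_from(zip(iu.tolist(), ju.tolist(), w[iu, ju].tolist()))
    mst = nx.maximum_spanning_tree(g)
    return min(d["weight"] for _, _, d in mst.edges(data=True))


def build_network(c: CorrelationMatrix, t: float, sign: str = POSITIVE) -> ImmuneNetwork:
    """Threshold the correlation matrix into an unweighted network.

    Positive sign keeps pairs with ``r >= t``; negative keeps ``r <= -t``
    (``t`` must be positive in that case).  Connectedness is not required:
    callers may use sub-bottleneck thresholds.
    """
    if sign not in (POSITIVE, NEGATIVE):
        raise ConfigurationError(f"sign must be positive|negative, got {sign!r}")
    if sign == NEGATIVE and t <= 0:
        raise ConfigurationError("negative networks require t > 0")
    n = len(c.measure_ids)
    mask = c.r >= t if sign == POSITIVE else c.r <= -t
    np.fill_diagonal(mask, False)
    g = nx.Graph()
    g.add_nodes_from(c.measure_ids)
    corr = {}
    iu, ju = np.where(np.triu(mask, k=1))
    for i, j in zip(iu, ju):
        u, v = c.measure_ids[i], c.measure_ids[j]
        g.add_edge(u, v)
        corr[(u, v)] = float(c.r[i, j])
    return ImmuneNetwork(graph=g, sign=sign, threshold=float(t), correlations=corr)


def annotate_network(net: ImmuneNetwork, categories: dict[str, MeasureAnnotation]) -> ImmuneNetwork:
    """Attach category/subcategory node attributes in place; returns net."""
    for node in net.graph.nodes:
        if node in categories:
            net.graph.nodes[node]["category"] = categories[node].category
            net.graph.nodes[node]["subcategory"] = categories[node].subcategory
    return net


def edge_density(net: ImmuneNetwork) -> float:
    """Fraction of realized node pairs, ``2e / (N (N - 1))``."""
    n = net.n_nodes
    if n < 2:
        raise PipelineError("edge density undefined for fewer than 2 nodes")
    return 2.0 * net.n_edges / (n * (n - 1))


def intercommunity_density(net: ImmuneNetwork, partition, a, b) -> float:
    """Edge density between communities ``a`` and ``b`` of ``partition``.

    For ``a != b`` this is (edges with one endpoint in each) / (|a| * |b|);
    for ``a == b`` it is the within-community density e_a / C(|a|, 2).
    """
    nodes_a = partition.members(a)
    nodes_b = partition.members(b)
    if not nodes_a or not nodes_b:
        raise PipelineError(f"empty community in pair ({a!r}, {b!r})")
    if a == b:
        if len(nodes_a) < 2:
            raise PipelineError("within-community density needs >= 2 nodes")
        sub = net.graph.subgraph(nodes_a)
        possible = len(nodes_a) * (len(nodes_a) - 1) / 2
        return sub.number_of_edges() / possible
    set_b = set(nodes_b)
    count = sum(1 for u in nodes_a for v in net.graph.neighbors(u) if v in set_b)
    return count / (len(nodes_a) * len(nodes_b))
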