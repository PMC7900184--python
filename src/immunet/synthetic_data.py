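"""Synthetic subjects x measures datasets with planted community structure.

Measures are generated from a nested Gaussian factor model so that the
target correlation matrix is positive semidefinite by construction:

    x_i = sqrt(rho_within) * F_{b(i)} + sqrt(1 - rho_within) * eps_i

where the unit-variance block factors ``F_b`` share a global factor (giving
the background inter-block correlation), a chain factor loading a hub block
and two peripheral blocks (giving the hub's strong links and the weak
peripheral-peripheral link), and a sign-flipped factor for one of a pair of
mutually negatively correlated blocks.  Between-block correlations of the
measures then equal the requested values exactly.

Missingness is MCAR: an independent per-cell process, plus a per-subject
process that wipes the entire battery of one category (e.g. every
stimulated-cytokine column) for a random subject fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from .communities import Partition
from .corrnet import ImmuneNetwork
from .errors import ConfigurationError
from .preprocess import (
    ImmuneMatrix,
    MeasureAnnotation,
    write_immune_matrix,
)

DEFAULT_CATEGORY_COUNTS = {
    "Antibody": 2,
    "SerumProteins": 3,
    "BodySpleen": 3,
    "MFI": 15,
    "FACS": 52,
    "CR": 45,
}

_CYTOKINES = ["IFNg", "IL4", "IL13", "IL1b", "IL12p70", "IL6", "IL10", "TNFa", "IL17"]
_STIMULATIONS = ["PBS", "CD3CD28", "LPS", "PWM", "PMA"]


def default_measure_table(
    category_counts: dict[str, int] | None = None,
) -> list[tuple[str, str, str]]:
    """(measure_id, category, subcategory) rows for the given category sizes."""
    counts = dict(category_counts or DEFAULT_CATEGORY_COUNTS)
    rows: list[tuple[str, str, str]] = []
    for cat, count in counts.items():
        if cat == "CR" and count == 45:
            for cyt in _CYTOKINES:
                for stim in _STIMULATIONS:
                    rows.append((f"CR_{cyt}_{stim}", "CR", cyt))
        elif cat == "MFI" and count == 15:
            for sub_i in range(3):
                for k in range(5):
                    rows.append(
                        (f"MFI_c{sub_i}_{k:02d}", "MFI", f"MFIcell{sub_i}")
                    )
        elif cat == "FACS" and count == 52:
            sizes = [8, 8, 8, 8, 8, 6, 6]
            idx = 0
            for sub_i, size in enumerate(sizes):
                for _ in range(size):
                    rows.append((f"FACS_c{sub_i}_{idx:02d}", "FACS", f"FACScell{sub_i}"))
                    idx += 1
        else:
            for k in range(count):
                rows.append((f"{cat}_{k:02d}", cat, cat))
    return rows


def default_block_assignment(
    measure_table: list[tuple[str, str, str]],
    environment: str = "wild",
    seed: int = 0,
) -> tuple[dict[str, int], tuple[int, int, int] | None, tuple[int, int] | None]:
    """Default 7-block planting for the standard 120-measure layout.

    Blocks: 0 = antibody/serum/body, 1 = MFI, 2-3 = the two FACS halves
    (the mutually negatively correlated pair), 4-6 = the three CR blocks
    (4 is the chain hub).  For the "lab" environment the measure -> block
    map is a seeded permutation of the wild one, so mesoscale structure is
    preserved while node composition differs.

    Returns (assignment, chain trio (hub first), negative pair).
    """
    by_cat: dict[str, list[str]] = {}
    for mid, cat, _sub in measure_table:
        by_cat.setdefault(cat, []).append(mid)

    ordered: list[str] = []
    block_sizes: list[int] = []
    small = [m for c in ("Antibody", "SerumProteins", "BodySpleen") for m in by_cat.get(c, [])]
    groups: list[list[str]] = []
    if small:
        groups.append(small)
    if by_cat.get("MFI"):
        groups.append(by_cat["MFI"])
    facs = by_cat.get("FACS", [])
    nk_pair = None
    if facs:
        half = len(facs) // 2
        groups.append(facs[:half])
        groups.append(facs[half:])
        nk_pair = (len(groups) - 2, len(groups) - 1)
    cr = by_cat.get("CR", [])
    chain = None
    if cr:
        third = len(cr) // 3
        first = len(groups)
        groups.append(cr[:third])
        groups.append(cr[third: 2 * third])
        groups.append(cr[2 * third:])
        chain = (first, first + 1, first + 2)
    leftovers = [
        m for m, c, _s in measure_table
        if c not in ("Antibody", "SerumProteins", "BodySpleen", "MFI", "FACS", "CR")
    ]
    if leftovers:
        groups.append(leftovers)

    for g in groups:
        ordered.extend(g)
        block_sizes.append(len(g))

    if environment == "lab":
        rng = np.random.default_rng(seed + 104729)  # fixed offset stream
        ordered = [ordered[i] for i in rng.permutation(len(ordered))]

    assignment: dict[str, int] = {}
    pos = 0
    for block_id, size in enumerate(block_sizes):
        for mid in ordered[pos: pos + size]:
            assignment[mid] = block_id
        pos += size
    return assignment, chain, nk_pair


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults mirror the standard 120-measure
    panel with seven planted blocks."""

    n_subjects: int = 500
    category_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    block_assignment: dict[str, int] | None = None
    chain_blocks: tuple[int, int, int] | None = None  # hub first
    nk_blocks: tuple[int, int] | None = None
    rho_within: float = 0.7
    rho_chain_strong: float = 0.25
    rho_chain_weak: float = 0.12
    rho_background: float = 0.05
    rho_negative: float = -0.2
    cell_missing_rate: float = 0.1
    battery_missing_rate: float = 0.4
    battery_category: str = "CR"
    environment: str = "wild"
    seed: int = 0

    def measure_table(self) -> list[tuple[str, str, str]]:
        return default_measure_table(self.category_counts)

    def resolved_blocks(
        self,
    ) -> tuple[dict[str, int], tuple[int, int, int] | None, tuple[int, int] | None]:
        if self.block_assignment is not None:
            return dict(self.block_assignment), self.chain_blocks, self.nk_blocks
        return default_block_assignment(
            self.measure_table(), self.environment, self.seed
        )

    # -- validation -------------------------------------------------------

    def _loadings(self) -> dict[str, float]:
        """Factor loadings of the block-factor construction; raises
        ConfigurationError naming the offending field when infeasible."""
        rw = self.rho_within
        if not 0.0 <= rw < 1.0:
            raise ConfigurationError(f"rho_within={rw} outside [0, 1)")
        if not -1.0 < self.rho_negative <= 0.0:
            raise ConfigurationError(
                f"rho_negative={self.rho_negative} outside (-1, 0]"
            )
        if not (self.rho_chain_strong > self.rho_chain_weak >= self.rho_background >= 0):
            raise ConfigurationError(
                "require rho_chain_strong > rho_chain_weak >= rho_background >= 0; "
                f"got {self.rho_chain_strong}, {self.rho_chain_weak}, {self.rho_background}"
            )
        if rw == 0.0:
            for name in ("rho_chain_weak", "rho_background"):
                if getattr(self, name) != 0.0:
                    raise ConfigurationError(
                        f"{name} must be 0 when rho_within is 0"
                    )
            if self.rho_negative != 0.0:
                raise ConfigurationError("rho_negative must be 0 when rho_within is 0")
            return {"a": 0.0, "alpha_h": 0.0, "alpha_p": 0.0, "beta": 0.0}
        a = self.rho_background / rw
        if a > 1:
            raise ConfigurationError("rho_background exceeds rho_within")
        alpha_p_sq = (self.rho_chain_weak - self.rho_background) / rw
        alpha_p = math.sqrt(alpha_p_sq)
        if alpha_p > 0:
            alpha_h = (self.rho_chain_strong - self.rho_background) / (rw * alpha_p)
        else:
            if self.rho_chain_strong != self.rho_background:
                raise ConfigurationError(
                    "rho_chain_strong requires rho_chain_weak > rho_background"
                )
            alpha_h = 0.0
        beta_sq = (self.rho_background - self.rho_negative) / rw
        beta = math.sqrt(beta_sq)
        for name, load in (
            ("rho_chain_weak", alpha_p),
            ("rho_chain_strong", alpha_h),
            ("rho_negative", beta),
        ):
            if a + load**2 > 1 + 1e-12:
                raise ConfigurationError(
                    f"{name} makes the block-factor construction infeasible "
                    f"(loading^2 {load**2:.3f} + background share {a:.3f} > 1)"
                )
        return {"a": a, "alpha_h": alpha_h, "alpha_p": alpha_p, "beta": beta}

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects={self.n_subjects} must be positive")
        for name in ("cell_missing_rate", "battery_missing_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"{name}={rate} outside [0, 1)")
        table = self.measure_table()
        if sum(self.category_counts.values()) != len(table):
            raise ConfigurationError("category_counts inconsistent with measure table")
        assignment, chain, nk = self.resolved_blocks()
        for mid, _c, _s in table:
            if mid not in assignment:
                raise ConfigurationError(f"block_assignment missing measure {mid!r}")
        self._loadings()

    def to_yaml(self, path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("block_assignment",)
        }
        data["chain_blocks"] = list(self.chain_blocks) if self.chain_blocks else None
        data["nk_blocks"] = list(self.nk_blocks) if self.nk_blocks else None
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticDataset:
    matrix: ImmuneMatrix
    truth_partition: Partition
    spec: SyntheticSpec


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a dataset from the factor model; deterministic given the seed."""
    spec.validate()
    loads = spec._loadings()
    table = spec.measure_table()
    assignment, chain, nk = spec.resolved_blocks()
    measure_ids = [row[0] for row in table]
    categories = {
        mid: MeasureAnnotation(cat, sub) for mid, cat, sub in table
    }
    block_ids = sorted(set(assignment.values()))
    block_index = {b: i for i, b in enumerate(block_ids)}
    n_blocks = len(block_ids)
    col_block = np.array([block_index[assignment[m]] for m in measure_ids])

    # per-block factor loadings on (global, chain, nk-signed) shared factors
    l_g = np.full(n_blocks, math.sqrt(loads["a"]))
    l_c = np.zeros(n_blocks)
    l_k = np.zeros(n_blocks)
    if chain is not None and n_blocks >= 3:
        hub, p1, p2 = (block_index[b] for b in chain)
        l_c[hub] = loads["alpha_h"]
        l_c[p1] = loads["alpha_p"]
        l_c[p2] = loads["alpha_p"]
    if nk is not None and n_blocks >= 2:
        b1, b2 = (block_index[b] for b in nk)
        l_k[b1] = loads["beta"]
        l_k[b2] = -loads["beta"]
    l_u = np.sqrt(np.clip(1.0 - l_g**2 - l_c**2 - l_k**2, 0.0, None))

    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    shared = rng.standard_normal((n, 3))  # global, chain, nk factors
    unique = rng.standard_normal((n, n_blocks))
    factors = (
        shared[:, [0]] * l_g + shared[:, [1]] * l_c + shared[:, [2]] * l_k
        + unique * l_u
    )
    eps = rng.standard_normal((n, len(measure_ids)))
    rw = spec.rho_within
    values = math.sqrt(rw) * factors[:, col_block] + math.sqrt(1.0 - rw) * eps

    missing = rng.random(values.shape) < spec.cell_missing_rate
    battery_cols = [
        j for j, mid in enumerate(measure_ids)
        if categories[mid].category == spec.battery_category
    ]
    if battery_cols and spec.battery_missing_rate > 0:
        wiped = rng.random(n) < spec.battery_missing_rate
        missing[np.ix_(wiped, battery_cols)] = True
    values = values.copy()
    values[missing] = np.nan

    matrix = ImmuneMatrix(
        subject_ids=[f"S{i:04d}" for i in range(n)],
        measure_ids=measure_ids,
        categories=categories,
        values=values,
        missing_mask=missing,
        environment=spec.environment,
    )
    truth = Partition(
        {m: block_index[assignment[m]] for m in measure_ids}, source="planted"
    )
    return SyntheticDataset(matrix=matrix, truth_partition=truth, spec=spec)


def generate_planted_network(
    n_nodes: int,
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[ImmuneNetwork, Partition]:
    """Assortative planted-partition graph: within-block edges with
    probability ``p_in``, between-block with ``p_out``."""
    if sum(block_sizes) != n_nodes:
        raise ConfigurationError(
            f"block sizes sum to {sum(block_sizes)}, expected {n_nodes}"
        )
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ConfigurationError(
            f"require 0 <= p_out <= p_in <= 1; got p_in={p_in}, p_out={p_out}"
        )
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    prob = np.where(labels[iu] == labels[ju], p_in, p_out)
    keep = rng.random(len(prob)) < prob
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    partition = Partition.from_labels(range(n_nodes), labels, source="planted")
    return ImmuneNetwork(graph=g), partition


def write_dataset(ds: SyntheticDataset, matrix_path, annotation_path, spec_path=None) -> None:
    """Matrix TSV (NA for missing), annotation TSV with the planted block,
    and optionally the spec as YAML."""
    write_immune_matrix(ds.matrix, matrix_path, annotation_path)
    import pandas as pd

    ann = pd.read_csv(annotation_path, sep="\t")
    ann["planted_block"] = [
        ds.truth_partition.assignment[m] for m in ann["measure_id"]
    ]
    ann.to_csv(annotation_path, sep="\t", index=False)
    if spec_path is not None:
        ds.spec.to_yaml(spec_path)
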