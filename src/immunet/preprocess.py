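"""Subject/measure matrix container and the pre-processing steps.

The raw input is a subjects x measures numeric matrix with missing cells,
plus an annotation table mapping each measure to a category/sub-category.
Pre-processing has three ordered steps:

1. drop measures (explicit list and/or too many missing values),
2. drop subjects that miss an entire measure battery (e.g. every
   stimulated-cytokine column),
3. fill the remaining missing cells with the per-measure mean of the
   observed values, computed within the dataset at hand.

Datasets from different environments (e.g. wild vs laboratory) must be
imputed independently; nothing in this module ever pools two matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


@dataclass
class MeasureAnnotation:
    category: str
    subcategory: str = ""


@dataclass
class ImmuneMatrix:
    """Subjects x measures matrix with missingness bookkeeping.

    ``values[i, j]`` is NaN exactly where ``missing_mask[i, j]`` is True and
    the cell has not been imputed.  ``imputed_mask`` marks cells that were
    originally missing and have since been filled; it is always a subset of
    ``missing_mask``.
    """

    subject_ids: list[str]
    measure_ids: list[str]
    categories: dict[str, MeasureAnnotation]
    values: np.ndarray
    missing_mask: np.ndarray
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    environment: str = "wild"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros_like(self.missing_mask)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_s, n_m = len(self.subject_ids), len(self.measure_ids)
        if self.values.shape != (n_s, n_m):
            raise ValueError(
                f"values shape {self.values.shape} != ({n_s}, {n_m})"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if self.imputed_mask.shape != self.values.shape:
            raise ValueError("imputed_mask shape mismatch")
        if np.any(self.imputed_mask & ~self.missing_mask):
            raise ValueError("imputed_mask must be a subset of missing_mask")
        unfilled = self.missing_mask & ~self.imputed_mask
        if not np.all(np.isfinite(self.values[~unfilled])):
            raise ValueError("non-finite value in an observed/imputed cell")
        for mid in self.measure_ids:
            if mid not in self.categories:
                raise ValueError(f"measure {mid!r} has no category annotation")

    # -- convenience ------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_measures(self) -> int:
        return len(self.measure_ids)

    @property
    def unfilled_mask(self) -> np.ndarray:
        """Cells that are missing and not yet imputed."""
        return self.missing_mask & ~self.imputed_mask

    def is_fully_imputed(self) -> bool:
        return not self.unfilled_mask.any()

    def measure_index(self, measure_id: str) -> int:
        try:
            return self.measure_ids.index(measure_id)
        except ValueError:
            raise KeyError(f"unknown measure {measure_id!r}") from None

    def copy(self) -> "ImmuneMatrix":
        return ImmuneMatrix(
            subject_ids=list(self.subject_ids),
            measure_ids=list(self.measure_ids),
            categories={m: self.categories[m] for m in self.measure_ids},
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            imputed_mask=self.imputed_mask.copy(),
            environment=self.environment,
        )

    def select_measures(self, keep: list[str]) -> "ImmuneMatrix":
        idx = [self.measure_index(m) for m in keep]
        return ImmuneMatrix(
            subject_ids=list(self.subject_ids),
            measure_ids=list(keep),
            categories={m: self.categories[m] for m in keep},
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            imputed_mask=self.imputed_mask[:, idx].copy(),
            environment=self.environment,
        )

    def select_subjects(self, keep_rows: np.ndarray) -> "ImmuneMatrix":
        keep_rows = np.asarray(keep_rows)
        return ImmuneMatrix(
            subject_ids=[s for s, k in zip(self.subject_ids, keep_rows) if k],
            measure_ids=list(self.measure_ids),
            categories={m: self.categories[m] for m in self.measure_ids},
            values=self.values[keep_rows].copy(),
            missing_mask=self.missing_mask[keep_rows].copy(),
            imputed_mask=self.imputed_mask[keep_rows].copy(),
            environment=self.environment,
        )

    def measures_in_category(self, category: str) -> list[str]:
        return [
            m for m in self.measure_ids if self.categories[m].category == category
        ]

    def measures_in_subcategory(self, subcategory: str) -> list[str]:
        return [
            m
            for m in self.measure_ids
            if self.categories[m].subcategory == subcategory
        ]


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_immune_matrix(m: ImmuneMatrix, matrix_path, annotation_path) -> None:
    """Write the matrix (subjects in rows, ``NA`` for missing cells) and the
    measure annotation table as tab-separated files."""
    vals = m.values.astype(object)
    vals[m.unfilled_mask] = np.nan
    df = pd.DataFrame(vals, index=m.subject_ids, columns=m.measure_ids)
    df.index.name = "subject_id"
    df.to_csv(matrix_path, sep="\t", na_rep=NA_TOKEN)

    ann = pd.DataFrame(
        {
            "measure_id": m.measure_ids,
            "category": [m.categories[x].category for x in m.measure_ids],
            "subcategory": [m.categories[x].subcategory for x in m.measure_ids],
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_immune_matrix(matrix_path, annotation_path, environment: str = "wild") -> ImmuneMatrix:
    df = pd.read_csv(
        matrix_path, sep="\t", index_col="subject_id", na_values=[NA_TOKEN]
    )
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
    categories = {
        row["measure_id"]: MeasureAnnotation(row["category"], row["subcategory"])
        for _, row in ann.iterrows()
    }
    values = df.to_numpy(dtype=float)
    missing = ~np.isfinite(values)
    return ImmuneMatrix(
        subject_ids=[str(s) for s in df.index],
        measure_ids=[str(c) for c in df.columns],
        categories=categories,
        values=values,
        missing_mask=missing,
        environment=environment,
    )


# ---------------------------------------------------------------------------
# Pre-processing operations
# ---------------------------------------------------------------------------

def exclude_measures(
    m: ImmuneMatrix,
    max_missing_fraction: float = 0.5,
    explicit_exclusions: list[str] | tuple[str, ...] = (),
) -> ImmuneMatrix:
    """Drop explicitly listed measures and measures with too many missing
    values (fraction strictly greater than ``max_missing_fraction``).

    Raises :class:`PipelineError` if fewer than 3 measures would remain.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ConfigurationError(
            f"max_missing_fraction={max_missing_fraction} outside [0, 1]"
        )
    for mid in explicit_exclusions:
        if mid not in m.measure_ids:
            raise ConfigurationError(f"explicit exclusion {mid!r} not in matrix")

    explicit = set(explicit_exclusions)
    frac = m.unfilled_mask.mean(axis=0)
    keep: list[str] = []
    for j, mid in enumerate(m.measure_ids):
        if mid in explicit:
            logger.info("excluding measure %s: explicit", mid)
        elif frac[j] > max_missing_fraction:
            logger.info(
                "excluding measure %s: missing fraction %.3f > %.3f",
                mid, frac[j], max_missing_fraction,
            )
        else:
            keep.append(mid)
    if len(keep) < 3:
        raise PipelineError(
            f"measure exclusion leaves {len(keep)} measures (< 3)"
        )
    return m.select_measures(keep)


def exclude_subjects_missing_battery(m: ImmuneMatrix, category: str) -> ImmuneMatrix:
    """Drop every subject for which *all* measures of ``category`` are missing."""
    cols = [m.measure_index(x) for x in m.measures_in_category(category)]
    if not cols:
        raise ConfigurationError(f"category {category!r} not present")
    all_missing = m.unfilled_mask[:, cols].all(axis=1)
    n_drop = int(all_missing.sum())
    if n_drop:
        logger.info(
            "excluding %d subjects missing the full %s battery", n_drop, category
        )
    out = m.select_subjects(~all_missing)
    if out.n_subjects < 10:
        logger.warning(
            "only %d subjects remain after battery exclusion; "
            "correlation estimates will be unstable", out.n_subjects,
        )
    return out


def impute_mean(m: ImmuneMatrix) -> ImmuneMatrix:
    """Replace each missing cell by the mean of its measure's observed values.

    Observed cells are untouched and each column mean is preserved exactly.
    A measure with no observed value has no defined mean and is an error.
    """
    out = m.copy()
    unfilled = out.unfilled_mask
    for j, mid in enumerate(out.measure_ids):
        col_missing = unfilled[:, j]
        if not col_missing.any():
            continue
        observed = out.values[~out.missing_mask[:, j], j]
        # previously imputed cells already carry the column mean
        observed = np.concatenate(
            [observed, out.values[out.imputed_mask[:, j], j]]
        )
        if observed.size == 0:
            raise PipelineError(
                f"measure {mid!r} has no observed values; mean undefined"
            )
        out.values[col_missing, j] = observed.mean()
        out.imputed_mask[col_missing, j] = True
    out.validate()
    return out


def preprocess(
    m: ImmuneMatrix,
    max_missing_fraction: float = 0.5,
    explicit_exclusions: list[str] | tuple[str, ...] = (),
    battery_category: str = "CR",
) -> tuple[ImmuneMatrix, dict]:
    """Run the three steps in order and return (matrix, JSON-able report)."""
    before_measures = list(m.measure_ids)
    before_subjects = list(m.subject_ids)
    frac = dict(zip(m.measure_ids, m.unfilled_mask.mean(axis=0)))

    m1 = exclude_measures(m, max_missing_fraction, explicit_exclusions)
    m2 = exclude_subjects_missing_battery(m1, battery_category)
    m3 = impute_mean(m2)

    removed_measures = {
        mid: (
            "explicit"
            if mid in set(explicit_exclusions)
            else f"missing fraction {frac[mid]:.4f} > {max_missing_fraction}"
        )
        for mid in before_measures
        if mid not in m1.measure_ids
    }
    report = {
        "environment": m.environment,
        "removed_measures": removed_measures,
        "removed_subjects": [
            s for s in before_subjects if s not in set(m2.subject_ids)
        ],
        "n_subjects": m3.n_subjects,
        "n_measures": m3.n_measures,
        "imputed_cells_per_measure": {
            mid: int(m3.imputed_mask[:, j].sum())
            for j, mid in enumerate(m3.measure_ids)
        },
    }
    return m3, report
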