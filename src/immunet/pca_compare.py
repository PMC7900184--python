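"""Comparative PCA with iterative outlier-measure removal.

The default scaling is the covariance matrix (no standardization): a single
measure with an enormous variance then dominates the first component, which
is the behaviour the outlier-removal loop is built to detect and undo.
Correlation scaling is available as an option.

Implemented via SVD of the centered data matrix; component signs are
canonicalized (largest-magnitude loading positive) so outputs are
bit-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PipelineError
from .preprocess import ImmuneMatrix

COVARIANCE = "covariance"
CORRELATION = "correlation"


@dataclass
class PCAResult:
    measure_ids: list[str]
    variance_shares: np.ndarray
    loadings: np.ndarray  # measures x components, orthonormal columns
    scores: np.ndarray  # subjects x components
    removed_measures: list[str] = field(default_factory=list)
    scaling: str = COVARIANCE

    def __post_init__(self) -> None:
        self.variance_shares = np.asarray(self.variance_shares, dtype=float)
        if np.any(np.diff(self.variance_shares) > 1e-9):
            raise ValueError("variance shares must be non-increasing")
        if abs(self.variance_shares.sum() - 1.0) > 1e-9:
            raise ValueError("variance shares must sum to 1")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9):
            raise ValueError("loadings columns must be orthonormal")

    def write(self, shares_path, loadings_path, scores_path, summary_path=None) -> None:
        comps = [f"PC{i + 1}" for i in range(len(self.variance_shares))]
        pd.DataFrame(
            {"component": comps, "variance_share": self.variance_shares}
        ).to_csv(shares_path, sep="\t", index=False)
        pd.DataFrame(self.loadings, index=self.measure_ids, columns=comps).to_csv(
            loadings_path, sep="\t"
        )
        pd.DataFrame(self.scores, columns=comps).to_csv(
            scores_path, sep="\t", index=False
        )
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(
                    {
                        "scaling": self.scaling,
                        "removed_measures": self.removed_measures,
                        "variance_shares": self.variance_shares.tolist(),
                    },
                    fh,
                    indent=2,
                )


def run_pca(m: ImmuneMatrix, scaling: str = COVARIANCE) -> PCAResult:
    """PCA of the (fully imputed) matrix, centered; standardized too when
    ``scaling='correlation'``.  Variance shares are eigenvalue proportions."""
    if scaling not in (COVARIANCE, CORRELATION):
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    if not m.is_fully_imputed():
        raise PipelineError("matrix still has missing values; impute first")
    if m.n_measures < 2 or m.n_subjects < 2:
        raise PipelineError("PCA needs >= 2 measures and >= 2 subjects")
    x = m.values - m.values.mean(axis=0)
    if scaling == CORRELATION:
        stds = m.values.std(axis=0, ddof=1)
        for mid, s in zip(m.measure_ids, stds):
            if s == 0:
                raise PipelineError(
                    f"measure {mid!r} has zero variance; cannot standardize"
                )
        x = x / stds
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = svals**2 / (m.n_subjects - 1)
    shares = eigvals / eigvals.sum()
    loadings = vt.T
    # sign canonicalization: largest-|loading| entry of each column positive
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = x @ loadings
    return PCAResult(
        measure_ids=list(m.measure_ids),
        variance_shares=shares,
        loadings=loadings,
        scores=scores,
        scaling=scaling,
    )


def detect_outlier_measure(
    r: PCAResult, dominance_threshold: float = 0.9
) -> str | None:
    """Measure whose squared PC1 loading exceeds the threshold while PC1
    itself dominates the variance; None when no such measure exists."""
    if r.variance_shares[0] <= dominance_threshold:
        return None
    sq = r.loadings[:, 0] ** 2
    j = int(np.argmax(sq))
    if sq[j] > dominance_threshold:
        return r.measure_ids[j]
    return None


def pca_with_outlier_removal(
    m: ImmuneMatrix,
    scaling: str = COVARIANCE,
    dominance_threshold: float = 0.9,
    max_removals: int = 1,
) -> list[PCAResult]:
    """Run PCA, drop the dominant outlier measure if one is flagged, rerun;
    repeat up to ``max_removals`` times.  Returns every run in order."""
    if max_removals < 0:
        raise ConfigurationError("max_removals must be >= 0")
    removed: list[str] = []
    current = m
    results: list[PCAResult] = []
    while True:
        res = run_pca(current, scaling)
        res.removed_measures = list(removed)
        results.append(res)
        if len(removed) >= max_removals:
            break
        outlier = detect_outlier_measure(res, dominance_threshold)
        if outlier is None:
            break
        removed.append(outlier)
        current = current.select_measures(
            [x for x in current.measure_ids if x != outlier]
        )
    return results
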