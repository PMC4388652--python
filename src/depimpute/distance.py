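"""Between-subject distances from mixed-type covariates.

Two distance matrices are built separately — Euclidean over the continuous
covariates (standardized by default so no single unit dominates) and
Manhattan over the binary covariates (a disagreement count) — then each is
min-max scaled to [0, 1] over its off-diagonal entries and the two are
combined as a weighted average into one between-subject dissimilarity
matrix that drives neighbor selection.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import CovariateTable, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "AggregatedDistance",
    "continuous_distance",
    "binary_distance",
    "aggregate",
    "covariate_distance",
]


@dataclasses.dataclass
class AggregatedDistance:
    """Symmetric N x N dissimilarity in [0, 1] with its block weights."""

    D: np.ndarray
    block_weights: tuple[float, float]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, float)


def continuous_distance(cont: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Pairwise Euclidean distances over continuous covariates.

    With ``standardize`` (default) each column is centered and scaled to
    unit variance first; zero-variance columns are dropped with a warning
    (their distance contribution is zero either way).
    """
    X = np.asarray(cont, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("continuous covariates must be a 2-D matrix with >= 1 column")
    if standardize:
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        keep = sd > 0
        if not keep.all():
            log.warning("dropping %d zero-variance continuous column(s) before "
                        "standardization", int((~keep).sum()))
        if not keep.any():
            return np.zeros((X.shape[0], X.shape[0]))
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return squareform(pdist(X, metric="euclidean"))


def binary_distance(binary: np.ndarray) -> np.ndarray:
    """Pairwise Manhattan distances over 0/1 covariates (disagreement count)."""
    X = np.asarray(binary, dtype=float)
    if X.ndim != 2:
        raise ValidationError("binary covariates must be a 2-D matrix")
    bad = ~np.isin(X, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(f"non-binary entry {X[i, j]!r} at row {i}, column {j}")
    return squareform(pdist(X, metric="cityblock"))


def _minmax_offdiag(D: np.ndarray) -> np.ndarray:
    """Scale a distance matrix to [0, 1] using its off-diagonal range.

    A constant block (no spread) maps to all zeros.
    """
    n = D.shape[0]
    if n < 2:
        return np.zeros_like(D)
    off = ~np.eye(n, dtype=bool)
    lo, hi = D[off].min(), D[off].max()
    if hi == lo:
        return np.zeros_like(D)
    out = (D - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def aggregate(
    D_cont: np.ndarray,
    D_bin: np.ndarray,
    block_weights: tuple[float, float] = (0.5, 0.5),
) -> AggregatedDistance:
    """Min-max scale each block to [0, 1] and take their weighted average."""
    D_cont = np.asarray(D_cont, float)
    D_bin = np.asarray(D_bin, float)
    if D_cont.shape != D_bin.shape or D_cont.ndim != 2 or D_cont.shape[0] != D_cont.shape[1]:
        raise ValidationError("distance blocks must be square matrices of equal size")
    for name, D in (("continuous", D_cont), ("binary", D_bin)):
        if (D < 0).any():
            raise ValidationError(f"{name} distance block has negative entries")
        if not np.allclose(D, D.T):
            raise ValidationError(f"{name} distance block is not symmetric")
    w_cont, w_bin = block_weights
    if abs(w_cont + w_bin - 1.0) > 1e-9:
        raise ValidationError(f"block weights {block_weights} must sum to 1")
    D = w_cont * _minmax_offdiag(D_cont) + w_bin * _minmax_offdiag(D_bin)
    return AggregatedDistance(D=D, block_weights=(float(w_cont), float(w_bin)))


def covariate_distance(
    cov: CovariateTable,
    standardize: bool = True,
    block_weights: tuple[float, float] = (0.5, 0.5),
) -> AggregatedDistance:
    """Build the aggregated between-subject distance from a covariate table.

    If one block is empty its weight is reassigned to the other block.
    """
    n = len(cov.subject_ids)
    has_cont = cov.continuous.shape[1] > 0
    has_bin = cov.binary.shape[1] > 0
    if not (has_cont or has_bin):
        raise ValidationError("covariate table has no columns")
    if not has_bin:
        log.warning("no binary covariates; using the continuous block alone")
        return aggregate(continuous_distance(cov.continuous, standardize),
                         np.zeros((n, n)), (1.0, 0.0))
    if not has_cont:
        log.warning("no continuous covariates; using the binary block alone")
        return aggregate(np.zeros((n, n)), binary_distance(cov.binary), (0.0, 1.0))
    return aggregate(
        continuous_distance(cov.continuous, standardize),
        binary_distance(cov.binary),
        block_weights,
    )
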