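"""Weighted KNN imputation of whole missing normal rows, with the induced
variance-covariance structure.

For each normal-missing subject i the k nearest fully observed subjects are
found in the aggregated covariate distance. With D_i1 <= ... <= D_ik the
sorted neighbor distances and D_imax the maximum distance from i over *all*
fully observed subjects, raw weights are

    w_il = 1 - D_il / D_imax

and are normalized to a_il = w_il / sum_t w_it, so the imputed row is the
convex combination

    xhat_ij = a_i1 x_{i_1 j} + ... + a_ik x_{i_k j}

equivalently XHat = A^T X with A the (N-S) x S matrix holding each missing
subject's weights at its neighbors' rows. Because imputed rows are linear
combinations of observed rows, imputed and observed data covary; at unit
feature variance and with subjects ordered observed-first the induced
covariance structure is the block matrix

    Sigma = [[ I,     A     ],
             [ A^T,   A^T A ]]

whose Gram block A^T A quantifies the imputation-induced dependence consumed
by the downstream GLS test.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .data import PairedExpressionSet, CovariateTable, ValidationError, validate_paired_set
from .distance import AggregatedDistance, covariate_distance

log = logging.getLogger(__name__)

__all__ = [
    "NeighborWeights",
    "ImputationResult",
    "choose_k",
    "neighbor_weights",
    "impute",
    "induced_sigma",
    "knn_impute_paired",
]


@dataclasses.dataclass
class NeighborWeights:
    """Neighbor sets and weights for every normal-missing subject.

    Row s of ``neighbors``/``raw_w``/``a`` describes missing subject
    ``missing_idx[s]``; neighbor entries are original subject indices in
    increasing-distance order.
    """

    missing_idx: np.ndarray  # (S,)
    observed_idx: np.ndarray  # (N-S,)
    neighbors: np.ndarray  # (S, k) int
    raw_w: np.ndarray  # (S, k)
    a: np.ndarray  # (S, k) rows sum to 1
    k: int


@dataclasses.dataclass
class ImputationResult:
    """Completed matrix plus the objects describing the induced dependence.

    ``A`` is (N-S) x S: column s holds missing subject s's a-weights at its
    neighbors' rows (zeros elsewhere). ``sigma`` is the N x N unit-variance
    covariance structure in observed-first order; ``order`` is the
    permutation mapping original subject positions to that order.
    """

    completed_normal: np.ndarray
    A: np.ndarray
    sigma: np.ndarray
    order: np.ndarray
    weights: NeighborWeights


def choose_k(n_observed: int) -> int:
    """Square root of the complete-case count, rounded to the nearest odd integer."""
    root = math.sqrt(n_observed)
    lower = int(math.floor(root))
    lower = lower if lower % 2 == 1 else lower - 1
    upper = lower + 2
    k = lower if (root - lower) <= (upper - root) else upper
    return max(1, min(k, n_observed))


def neighbor_weights(
    D: AggregatedDistance | np.ndarray,
    missing_mask: np.ndarray,
    k: int | str = 10,
) -> NeighborWeights:
    """Select k nearest fully observed neighbors and compute their weights.

    Ties at the k-boundary are broken by keeping the earliest subjects in
    stable id order. A neighbor sitting exactly at D_imax receives weight 0
    and is retained with zero contribution. If a subject is at distance 0
    from every observed subject, uniform weights are used (with a warning).
    ``k="auto"`` applies :func:`choose_k`.
    """
    Dm = D.D if isinstance(D, AggregatedDistance) else np.asarray(D, float)
    missing_mask = np.asarray(missing_mask, bool)
    obs = np.flatnonzero(~missing_mask)
    mis = np.flatnonzero(missing_mask)
    n_obs = obs.size
    if k == "auto":
        k = choose_k(n_obs)
        log.info("auto k: using k=%d from %d complete cases", k, n_obs)
    k = int(k)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n_obs:
        raise ValidationError(f"k={k} exceeds the {n_obs} fully observed subjects")

    S = mis.size
    neighbors = np.empty((S, k), dtype=int)
    raw_w = np.empty((S, k))
    a = np.empty((S, k))
    for s, i in enumerate(mis):
        d = Dm[i, obs]
        order = np.argsort(d, kind="stable")  # stable: ties keep subject-id order
        sel = order[:k]
        d_max = d.max()
        if d_max == 0.0:
            log.warning("subject %d is at distance 0 from every observed subject; "
                        "using uniform weights", i)
            w = np.ones(k)
        else:
            w = 1.0 - d[sel] / d_max
        total = w.sum()
        if total <= 0.0:
            log.warning("all selected neighbors of subject %d sit at the maximum "
                        "distance; using uniform weights", i)
            a_row = np.full(k, 1.0 / k)
        else:
            a_row = w / total
        neighbors[s] = obs[sel]
        raw_w[s] = w
        a[s] = a_row
    return NeighborWeights(mis, obs, neighbors, raw_w, a, k)


def _weight_matrix(nw: NeighborWeights) -> np.ndarray:
    """Assemble the (N-S) x S weight matrix A from per-subject weights."""
    pos = {subj: r for r, subj in enumerate(nw.observed_idx)}
    A = np.zeros((nw.observed_idx.size, nw.missing_idx.size))
    for s in range(nw.missing_idx.size):
        for neigh, weight in zip(nw.neighbors[s], nw.a[s]):
            A[pos[neigh], s] = weight
    return A


def induced_sigma(nw: NeighborWeights, n_subjects: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance induced covariance structure and its subject order.

    Returns the N x N block matrix [[I, A], [A^T, A^T A]] in observed-first
    order together with the permutation ``order`` such that
    ``x[order]`` puts a vector in that order.
    """
    if nw.observed_idx.size + nw.missing_idx.size != n_subjects:
        raise ValidationError("weights were computed on a different subject set")
    A = _weight_matrix(nw)
    n_obs = nw.observed_idx.size
    sigma = np.empty((n_subjects, n_subjects))
    sigma[:n_obs, :n_obs] = np.eye(n_obs)
    sigma[:n_obs, n_obs:] = A
    sigma[n_obs:, :n_obs] = A.T
    sigma[n_obs:, n_obs:] = A.T @ A
    order = np.concatenate([nw.observed_idx, nw.missing_idx])
    return sigma, order


def impute(pes: PairedExpressionSet, nw: NeighborWeights) -> ImputationResult:
    """Fill missing normal rows with their neighbors' weighted combination.

    Observed rows are untouched; each imputed value is a convex combination
    of its neighbors' values at that feature.
    """
    if not np.array_equal(nw.missing_idx, pes.missing_idx):
        raise ValidationError("weights were computed for a different missingness pattern")
    completed = pes.normal.copy()
    for s, i in enumerate(nw.missing_idx):
        completed[i] = nw.a[s] @ pes.normal[nw.neighbors[s]]
    sigma, order = induced_sigma(nw, pes.n_subjects)
    return ImputationResult(
        completed_normal=completed,
        A=_weight_matrix(nw),
        sigma=sigma,
        order=order,
        weights=nw,
    )


def knn_impute_paired(
    pes: PairedExpressionSet,
    cov: CovariateTable,
    k: int | str = 10,
    standardize: bool = True,
    block_weights: tuple[float, float] = (0.5, 0.5),
) -> ImputationResult:
    """End-to-end covariate-KNN imputation of a paired expression set."""
    validate_paired_set(pes, cov, k=None if k == "auto" else int(k))
    D = covariate_distance(cov, standardize=standardize, block_weights=block_weights)
    nw = neighbor_weights(D, pes.missing_mask, k=k)
    return impute(pes, nw)
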