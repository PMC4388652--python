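"""Per-feature paired differential-expression testing under imputation-induced
dependence.

The paired design reduces to a one-sample test on the per-subject
tumor - normal differences D_j for each feature j:

    D_j = 1 mu_j + eps,     Var(eps) = sigma_j^2 V,   V = I + Sigma

where Sigma is the unit-variance covariance structure induced by weighted
KNN imputation (identity top-left block for observed subjects, weight blocks
for imputed ones). The GLS estimates are

    mu_hat_j    = (1' V^-1 1)^-1 1' V^-1 D_j
    sigma2_hat  = (D_j - 1 mu_hat)' V^-1 (D_j - 1 mu_hat) / df
    Var(mu_hat) = sigma2_hat (1' V^-1 1)^-1
    t           = mu_hat / sqrt(Var(mu_hat))

with df = N - 1 (N - S - 1 under case deletion), referred to a Student t.
V does not depend on the feature, so it is Cholesky-factored once and all G
features are tested in whitened coordinates. Three analysis modes are
exposed: ``dependent`` (V = I + Sigma on the completed data), ``independent``
(V = I on the completed data, i.e. imputed values treated as fully observed)
and ``case_deletion`` (V = I on the complete pairs only). Two-sided p-values
are Benjamini-Hochberg adjusted across features.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from statsmodels.stats.multitest import multipletests

from .data import PairedExpressionSet, ValidationError
from .impute import ImputationResult

log = logging.getLogger(__name__)

__all__ = ["GLSResult", "build_v", "gls_paired_t", "run_de_analysis", "MODES"]

MODES = ("dependent", "independent", "case_deletion")


@dataclasses.dataclass
class GLSResult:
    """Vectorized GLS paired-t output, one entry per feature."""

    mu_hat: np.ndarray
    sigma2_hat: np.ndarray
    var_mu_hat: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    df: int


def build_v(sigma: np.ndarray) -> np.ndarray:
    """Form V = I + Sigma and verify positive definiteness via Cholesky.

    Returns the lower Cholesky factor of V; the factor is feature-independent
    and is reused across all features.
    """
    sigma = np.asarray(sigma, float)
    V = np.eye(sigma.shape[0]) + sigma
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "V = I + Sigma is not positive definite; reduce the number of "
            "imputed subjects or increase k"
        ) from None


def gls_paired_t(
    differences: np.ndarray,
    V: np.ndarray | None = None,
    cholesky: np.ndarray | None = None,
    df: int | None = None,
) -> GLSResult:
    """GLS one-sample t-test of the paired differences, vectorized over features.

    Parameters
    ----------
    differences
        (N,) vector or (N, G) matrix of per-subject tumor - normal
        differences, one column per feature.
    V, cholesky
        Error covariance at unit scale, or its precomputed lower Cholesky
        factor; omit both for the identity (classical one-sample t).
    df
        Degrees of freedom; defaults to N - 1.
    """
    D = np.asarray(differences, float)
    squeeze = D.ndim == 1
    if squeeze:
        D = D[:, None]
    n = D.shape[0]
    if n < 3:
        raise ValidationError("at least 3 paired differences are required")
    if df is None:
        df = n - 1
    if cholesky is None and V is not None:
        cholesky = build_v(np.asarray(V, float) - np.eye(n))
    if cholesky is None:
        z0, Z = np.ones(n), D
    else:
        z0 = solve_triangular(cholesky, np.ones(n), lower=True)
        Z = solve_triangular(cholesky, D, lower=True)
    denom = float(z0 @ z0)
    mu = (z0 @ Z) / denom
    resid = Z - np.outer(z0, mu)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    var_mu = sigma2 / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mu / np.sqrt(var_mu)
    degenerate = var_mu == 0
    if degenerate.any():
        log.warning("%d feature(s) with zero residual variance; reporting "
                    "t = +/-inf (t = 0 when the mean is also 0)", int(degenerate.sum()))
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.where(mu == 0, 0.0, np.sign(mu) * np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if squeeze:
        mu, sigma2, var_mu, t, p = (x[0] for x in (mu, sigma2, var_mu, t, p))
    return GLSResult(mu, sigma2, var_mu, t, p, df)


def run_de_analysis(
    pes: PairedExpressionSet,
    imputation: ImputationResult | None = None,
    mode: str = "dependent",
    alpha: float = 0.05,
    completed_normal: np.ndarray | None = None,
) -> pd.DataFrame:
    """Test every feature for tumor-normal differential expression.

    Differences are tumor - normal. ``dependent`` reorders subjects
    observed-first and uses V = I + Sigma from the imputation; ``independent``
    uses V = I on the completed data; ``case_deletion`` drops normal-missing
    subjects and uses V = I with df = (N - S) - 1. With no missingness all
    three modes coincide. ``completed_normal`` lets ``independent`` score a
    completed matrix from another imputation scheme (e.g. column means).

    Returns a tidy DataFrame with columns feature_id, mu_hat, sigma2_hat,
    t_stat, df, p_value, q_value (Benjamini-Hochberg), significant.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    n, s = pes.n_subjects, pes.n_missing

    if mode == "case_deletion":
        if n - s < 3:
            raise ValidationError(
                f"case deletion leaves only {n - s} complete pairs; need >= 3"
            )
        obs = pes.observed_idx
        diffs = pes.tumor[obs] - pes.normal[obs]
        res = gls_paired_t(diffs, df=(n - s) - 1)
    else:
        if completed_normal is not None:
            completed = np.asarray(completed_normal, float)
        elif imputation is not None:
            completed = imputation.completed_normal
        elif s == 0:
            completed = pes.normal
        else:
            raise ValidationError(f"mode {mode!r} needs an imputation when rows are missing")
        if np.isnan(completed).any():
            raise ValidationError("completed normal matrix still contains missing values")
        diffs = pes.tumor - completed
        if mode == "dependent" and s > 0:
            if imputation is None:
                raise ValidationError("dependent mode needs the ImputationResult "
                                      "carrying Sigma")
            L = build_v(imputation.sigma)
            res = gls_paired_t(diffs[imputation.order], cholesky=L)
        else:
            res = gls_paired_t(diffs)

    reject, q, _, _ = multipletests(res.p_value, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature_id": pes.feature_ids,
            "mu_hat": res.mu_hat,
            "sigma2_hat": res.sigma2_hat,
            "t_stat": res.t_stat,
            "df": res.df,
            "p_value": res.p_value,
            "q_value": q,
            "significant": reject.astype(int),
        }
    )
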