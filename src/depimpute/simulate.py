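"""Synthetic paired expression data, linked covariates, and missingness.

The generator emulates a paired tumor/normal miRNA expression study with
whole-sample missingness on the normal arm. Expression is Gaussian: every
normal value and every non-DE tumor value is drawn N(mu_null, sigma^2)
(defaults 2 and 1.25^2), while the DE fraction of tumor features (default
20%) is drawn N(mu_de, sigma^2) with mu_de = 2.5. Demographic/lifestyle
covariates are then derived from the tumor expression of z randomly chosen
truly-DE features so that covariate similarity tracks tumor expression
similarity:

  continuous:  C = beta0 + sum_j beta_j x_j + eps,
               beta_j ~ U[frac*min_c, frac*max_c] (frac = 2% by default),
               eps ~ N(0, 0.10 * var_c)
  binary:      logit p = beta0 + sum_j beta_j x_j, beta_j ~ U[-0.5, 0.5];
               p is min-max rescaled across subjects and thresholded at 0.5.

Missingness is MCAR: a fixed fraction of subjects (10-50%) lose their whole
normal row; true values are retained in :class:`~depimpute.data.SimulationTruth`
for RMSE scoring. :func:`run_study` drives the full factorial benchmark
(sample size x missing fraction x method x replicate) and :func:`k_sweep`
the neighbor-count sensitivity analysis.

The base characteristics of the ten covariates (means, ranges, variances,
modes) are synthetic stand-ins for a colorectal-cancer cohort's demographic
profile; nothing downstream depends on their specific values and they can
be overridden.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import PairedExpressionSet, CovariateTable, SimulationTruth, ValidationError
from .detest import run_de_analysis
from .evaluate import confusion_metrics, mean_impute, rmse
from .impute import knn_impute_paired

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "CONTINUOUS_PROFILES",
    "BINARY_PROFILES",
    "simulate_expression",
    "simulate_continuous_covariate",
    "simulate_binary_covariate",
    "simulate_covariates",
    "apply_missingness",
    "simulate_dataset",
    "run_study",
    "k_sweep",
    "STUDY_METHODS",
]

# Synthetic stand-in cohort characteristics: name -> (mean, min, max, variance).
CONTINUOUS_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "age": (65.0, 30.0, 79.0, 100.0),
    "cigarettes_per_day": (8.0, 0.0, 40.0, 60.0),
    "calories": (2100.0, 800.0, 4500.0, 360000.0),
    "bmi": (27.0, 17.0, 45.0, 22.0),
    "lutein_zeaxanthin": (1.8, 0.1, 6.0, 1.2),
}

# Synthetic stand-in modes for the binary covariates: name -> mode (0 or 1).
BINARY_PROFILES: dict[str, int] = {
    "gender": 1,
    "aspirin_nsaid_use": 0,
    "recent_smoker": 0,
    "menopause": 1,
    "hrt_use": 0,
}


@dataclasses.dataclass
class SimConfig:
    """Parameters of one simulated data set.

    Defaults reproduce the benchmark design: G = 2000 features, 20% of them
    differentially expressed in tumor with mean shift 2.0 -> 2.5 at common
    SD 1.25, covariates driven by z = 20 truly-DE tumor features with slope
    range 2% of each covariate's min/max and noise variance 10% of the
    covariate's variance, and k = 10 imputation neighbors.
    """

    N: int
    missing_fraction: float
    G: int = 2000
    de_fraction: float = 0.20
    mu_null: float = 2.0
    mu_de: float = 2.5
    sigma: float = 1.25
    z: int = 20
    cont_beta_frac: float = 0.02
    eps_var_frac: float = 0.10
    k: int = 10
    n_reps: int = 25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValidationError("N must be >= 3")
        if self.G < 1:
            raise ValidationError("G must be >= 1")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValidationError("de_fraction must be in [0, 1)")
        if not 0.0 < self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must be in (0, 1)")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.z > round(self.de_fraction * self.G):
            raise ValidationError(
                f"z={self.z} exceeds the {round(self.de_fraction * self.G)} DE features"
            )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_expression(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[PairedExpressionSet, SimulationTruth]:
    """Draw the paired normal/tumor matrices and record the DE truth."""
    n, g = cfg.N, cfg.G
    de_count = round(cfg.de_fraction * g)
    de_idx = rng.choice(g, size=de_count, replace=False)
    de_indicator = np.zeros(g, dtype=bool)
    de_indicator[de_idx] = True

    normal = rng.normal(cfg.mu_null, cfg.sigma, size=(n, g))
    tumor = rng.normal(cfg.mu_null, cfg.sigma, size=(n, g))
    tumor[:, de_indicator] = rng.normal(cfg.mu_de, cfg.sigma, size=(n, de_count))

    subject_ids = [f"s{i + 1}" for i in range(n)]
    feature_ids = [f"mir{j + 1}" for j in range(g)]
    pes = PairedExpressionSet.from_matrices(normal, tumor, subject_ids, feature_ids)
    truth = SimulationTruth(
        true_normal=normal.copy(), de_indicator=de_indicator, params=cfg.as_dict()
    )
    return pes, truth


def simulate_continuous_covariate(
    base_mean: float,
    base_min: float,
    base_max: float,
    base_var: float,
    de_expr: np.ndarray,
    frac: float,
    eps_var_frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One continuous covariate as a noisy linear function of DE tumor expression.

    Slopes are drawn once per covariate, uniform on
    [frac * base_min, frac * base_max], and shared across subjects.
    """
    de_expr = np.atleast_2d(np.asarray(de_expr, float))
    z = de_expr.shape[1]
    beta = rng.uniform(frac * base_min, frac * base_max, size=z)
    eps = rng.normal(0.0, np.sqrt(eps_var_frac * base_var), size=de_expr.shape[0])
    return base_mean + de_expr @ beta + eps


def simulate_binary_covariate(
    base_mode: float, de_expr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One 0/1 covariate via a logistic model on DE tumor expression.

    The linear predictor base_mode + sum_j beta_j x_j (beta_j ~ U[-0.5, 0.5])
    is passed through the inverse logit, min-max rescaled across subjects to
    force variability, and thresholded at 0.5. If every probability is equal
    the covariate degenerates to all zeros (with a warning).
    """
    de_expr = np.atleast_2d(np.asarray(de_expr, float))
    z = de_expr.shape[1]
    beta = rng.uniform(-0.5, 0.5, size=z)
    p = expit(base_mode + de_expr @ beta)
    lo, hi = p.min(), p.max()
    if hi == lo:
        log.warning("degenerate binary covariate: all probabilities equal; assigning 0")
        return np.zeros(de_expr.shape[0], dtype=int)
    p_scaled = (p - lo) / (hi - lo)
    return (p_scaled > 0.5).astype(int)


def simulate_covariates(
    tumor: np.ndarray,
    de_indicator: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    subject_ids: Sequence[str],
    continuous_profiles: dict | None = None,
    binary_profiles: dict | None = None,
) -> CovariateTable:
    """Simulate the covariate table from z randomly chosen DE tumor features."""
    cont_prof = continuous_profiles or CONTINUOUS_PROFILES
    bin_prof = binary_profiles or BINARY_PROFILES
    de_idx = np.flatnonzero(np.asarray(de_indicator, bool))
    drivers = rng.choice(de_idx, size=cfg.z, replace=False) if cfg.z > 0 else np.array([], int)
    de_expr = np.asarray(tumor, float)[:, drivers]

    cont = np.column_stack(
        [
            simulate_continuous_covariate(
                mean, lo, hi, var, de_expr, cfg.cont_beta_frac, cfg.eps_var_frac, rng
            )
            for mean, lo, hi, var in cont_prof.values()
        ]
    )
    binary = np.column_stack(
        [simulate_binary_covariate(mode, de_expr, rng) for mode in bin_prof.values()]
    )
    return CovariateTable(
        continuous=cont,
        binary=binary,
        continuous_names=list(cont_prof),
        binary_names=list(bin_prof),
        subject_ids=list(subject_ids),
    )


def apply_missingness(
    pes: PairedExpressionSet,
    missing_fraction: float,
    rng: np.random.Generator,
    k: int | None = None,
) -> PairedExpressionSet:
    """Mask a random fraction of whole normal rows (MCAR).

    round(missing_fraction * N) subjects are chosen uniformly; their normal
    rows become NaN while tumor rows are untouched. Keep the pre-masking
    matrix (e.g. in SimulationTruth) for RMSE scoring.
    """
    if not 0.0 < missing_fraction < 1.0:
        raise ValidationError("missing_fraction must be in (0, 1)")
    n = pes.n_subjects
    s = round(missing_fraction * n)
    if k is not None and n - s < k:
        raise ValidationError(
            f"masking {s} of {n} subjects leaves fewer than k={k} complete cases"
        )
    masked_idx = rng.choice(n, size=s, replace=False)
    normal = pes.normal.copy()
    normal[masked_idx] = np.nan
    return PairedExpressionSet.from_matrices(
        normal, pes.tumor, pes.subject_ids, pes.feature_ids
    )


def simulate_dataset(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PairedExpressionSet, CovariateTable, SimulationTruth]:
    """Full generator: expression, linked covariates, then MCAR masking."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pes, truth = simulate_expression(cfg, rng)
    cov = simulate_covariates(pes.tumor, truth.de_indicator, cfg, rng, pes.subject_ids)
    masked = apply_missingness(pes, cfg.missing_fraction, rng, k=cfg.k)
    return masked, cov, truth


STUDY_METHODS = ("knn_dependent", "knn_independent", "case_deletion", "full", "mean_imputation")


def _score(de_table: pd.DataFrame, truth: SimulationTruth) -> dict:
    truly_de = truth.de_indicator
    if truth.params.get("mu_de") == truth.params.get("mu_null"):
        truly_de = np.zeros_like(truly_de)  # global null: nothing is truly DE
    m = confusion_metrics(de_table["significant"].to_numpy(bool), truly_de)
    return {"tpr": m.tpr, "fpr": m.fpr, "fdr": m.fdr}


def run_study(
    grid: Sequence[tuple[int, float]],
    methods: Sequence[str] = ("knn_dependent", "knn_independent", "case_deletion"),
    n_reps: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    **cfg_overrides,
) -> pd.DataFrame:
    """Run the simulation benchmark over a (N, missing_fraction) grid.

    For each grid cell and replicate: simulate, mask, impute (KNN once,
    shared by the dependent and independent analyses), test, and score
    TPR/FPR/FDR against the DE truth and RMSE against the pre-masking
    normal rows. Replicate streams are spawned from ``seed`` in a fixed
    order, so the whole study is reproducible bit-for-bit.

    Returns a tidy DataFrame with columns
    N, missing_pct, method, rep, tpr, fpr, fdr, rmse.
    """
    unknown = set(methods) - set(STUDY_METHODS)
    if unknown:
        raise ValidationError(f"unknown methods {sorted(unknown)}; choose from {STUDY_METHODS}")
    children = np.random.SeedSequence(seed).spawn(len(grid) * n_reps)
    rows: list[dict] = []
    for c, (n, mf) in enumerate(grid):
        cfg = SimConfig(N=n, missing_fraction=mf, **cfg_overrides)
        for rep in range(n_reps):
            rng = np.random.default_rng(children[c * n_reps + rep])
            pes, cov, truth = simulate_dataset(cfg, rng)
            mis = pes.missing_idx
            knn = None
            if any(m.startswith("knn") for m in methods):
                knn = knn_impute_paired(pes, cov, k=cfg.k)
            for method in methods:
                cell_rmse = float("nan")
                if method == "knn_dependent":
                    de = run_de_analysis(pes, imputation=knn, mode="dependent", alpha=alpha)
                    cell_rmse = rmse(truth.true_normal[mis], knn.completed_normal[mis])
                elif method == "knn_independent":
                    de = run_de_analysis(pes, imputation=knn, mode="independent", alpha=alpha)
                    cell_rmse = rmse(truth.true_normal[mis], knn.completed_normal[mis])
                elif method == "case_deletion":
                    de = run_de_analysis(pes, mode="case_deletion", alpha=alpha)
                elif method == "full":
                    full = PairedExpressionSet.from_matrices(
                        truth.true_normal, pes.tumor, pes.subject_ids, pes.feature_ids
                    )
                    de = run_de_analysis(full, mode="independent", alpha=alpha)
                elif method == "mean_imputation":
                    completed = mean_impute(pes)
                    de = run_de_analysis(
                        pes, mode="independent", alpha=alpha, completed_normal=completed
                    )
                    cell_rmse = rmse(truth.true_normal[mis], completed[mis])
                log.info("cell (N=%d, %.0f%% missing) rep %d method %s done",
                         n, 100 * mf, rep, method)
                rows.append(
                    {
                        "N": n,
                        "missing_pct": round(100 * mf),
                        "method": method,
                        "rep": rep,
                        **_score(de, truth),
                        "rmse": cell_rmse,
                    }
                )
    return pd.DataFrame(rows)


def k_sweep(
    N: int,
    missing_fraction: float,
    ks: Sequence[int] = (1, 2, 5, 10, 15, 20, 25),
    n_reps: int = 3,
    seed: int = 0,
    **cfg_overrides,
) -> pd.DataFrame:
    """Imputation RMSE as a function of the neighbor count k.

    Each replicate data set is simulated once and imputed at every k, so the
    sweep isolates the effect of k from sampling noise.

    Returns a tidy DataFrame with columns k, rep, rmse.
    """
    cfg = SimConfig(N=N, missing_fraction=missing_fraction, k=max(ks), **cfg_overrides)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(children[rep])
        pes, cov, truth = simulate_dataset(cfg, rng)
        mis = pes.missing_idx
        for k in ks:
            res = knn_impute_paired(pes, cov, k=k)
            rows.append(
                {"k": k, "rep": rep,
                 "rmse": rmse(truth.true_normal[mis], res.completed_normal[mis])}
            )
    return pd.DataFrame(rows)
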