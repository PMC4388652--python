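"""Containers and delimited-text I/O for paired tumor--normal expression data.

The central objects are :class:`PairedExpressionSet` (a normal and a tumor
subjects x features matrix sharing subject and feature order, where some
subjects' normal rows may be *entirely* missing) and :class:`CovariateTable`
(fully observed continuous and binary per-subject covariates used only for
neighbor finding). Missingness is whole-sample by construction: a normal row
is either fully observed or fully absent — scattered missing cells are a
different problem and are rejected at validation time.

Files are plain delimited text (TSV or CSV, sniffed) with one header row and
one leading id column. The missing sentinel is the literal, case-sensitive
token ``NA``; empty cells are also accepted as missing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING_SENTINEL = "NA"

__all__ = [
    "ParseError",
    "ValidationError",
    "PairedExpressionSet",
    "CovariateTable",
    "SimulationTruth",
    "read_expression_matrix",
    "write_expression_matrix",
    "load_paired_set",
    "read_covariates",
    "validate_paired_set",
]


class ParseError(ValueError):
    """A delimited input file could not be parsed."""


class ValidationError(ValueError):
    """Inputs violate a structural invariant of the method."""


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited file as strings, sniffing the separator."""
    try:
        df = pd.read_csv(
            path,
            sep=None,
            engine="python",
            index_col=0,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from None
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row ids {dupes}")
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    """Convert a string table to float with NA/empty as NaN, naming offenders."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        s = df[col].str.strip()
        missing = (s == MISSING_SENTINEL) | (s == "")
        vals = pd.to_numeric(s.where(~missing), errors="coerce")
        bad = vals.isna() & ~missing
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ParseError(
                f"{path}: non-numeric value {s[bad].iloc[0]!r} at row "
                f"{row!r}, column {col!r} (missing sentinel is {MISSING_SENTINEL!r})"
            )
        out[:, j] = vals.to_numpy(dtype=float)
    return out


def read_expression_matrix(
    path: str | Path, orientation: str = "subjects"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an expression matrix into subjects x features orientation.

    Parameters
    ----------
    path
        Delimited text file with a header row and a leading id column.
    orientation
        ``"subjects"`` if file rows are subjects (default), ``"features"``
        if file rows are features; the returned matrix is always
        subjects x features.

    Returns
    -------
    (matrix, subject_ids, feature_ids)
        ``matrix`` is float with NaN marking missing cells; ids preserve
        file order.
    """
    if orientation not in ("subjects", "features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    values = _to_numeric(df, path)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "features":
        return values.T, col_ids, row_ids
    return values, row_ids, col_ids


def write_expression_matrix(
    path: str | Path,
    matrix: np.ndarray,
    subject_ids: Sequence[str],
    feature_ids: Sequence[str],
    orientation: str = "subjects",
    sep: str = "\t",
) -> None:
    """Write a subjects x features matrix; NaN cells become ``NA``.

    Values are printed with 12 significant digits so a write/read round
    trip is bit-identical for such representations.
    """
    df = pd.DataFrame(np.asarray(matrix, float), index=list(subject_ids), columns=list(feature_ids))
    if orientation == "features":
        df = df.T
    elif orientation != "subjects":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep, na_rep=MISSING_SENTINEL, float_format="%.12g")


@dataclasses.dataclass
class PairedExpressionSet:
    """Paired normal/tumor expression with whole-sample normal missingness.

    Attributes
    ----------
    normal
        N x G matrix; rows of normal-missing subjects are all-NaN.
    tumor
        N x G matrix, fully observed.
    subject_ids, feature_ids
        Ordered identifiers shared by both matrices.
    missing_mask
        Boolean (N,) vector, True where the normal sample is missing.
    """

    normal: np.ndarray
    tumor: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, g = self.normal.shape
        if self.tumor.shape != (n, g):
            raise ValidationError(
                f"normal is {self.normal.shape}, tumor is {self.tumor.shape}; "
                "paired matrices must share subject and feature order"
            )
        if len(self.subject_ids) != n or len(self.feature_ids) != g:
            raise ValidationError("id lengths do not match matrix shape")
        if self.missing_mask.shape != (n,):
            raise ValidationError("missing_mask must have one entry per subject")
        if np.isnan(self.tumor).any():
            raise ValidationError("tumor matrix must be fully observed")
        nan_rows = np.isnan(self.normal)
        partial = np.flatnonzero(nan_rows.any(axis=1) & ~nan_rows.all(axis=1))
        if partial.size:
            ids = [self.subject_ids[i] for i in partial]
            raise ValidationError(
                f"partial row(s) for subject(s) {ids}: a normal sample must be "
                "fully observed or fully missing (whole-sample missingness)"
            )
        if not np.array_equal(nan_rows.all(axis=1), self.missing_mask):
            raise ValidationError("missing_mask inconsistent with NaN rows of normal")
        if int(self.missing_mask.sum()) >= n:
            raise ValidationError("every normal sample is missing; nothing to impute from")

    @classmethod
    def from_matrices(
        cls,
        normal: np.ndarray,
        tumor: np.ndarray,
        subject_ids: Sequence[str],
        feature_ids: Sequence[str],
    ) -> "PairedExpressionSet":
        """Build a set deriving the missing mask from all-NaN normal rows."""
        normal = np.asarray(normal, float)
        mask = np.isnan(normal).all(axis=1) if normal.size else np.zeros(len(normal), bool)
        return cls(normal, tumor, list(subject_ids), list(feature_ids), mask)

    @property
    def n_subjects(self) -> int:
        return self.normal.shape[0]

    @property
    def n_features(self) -> int:
        return self.normal.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def observed_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.missing_mask)

    @property
    def missing_idx(self) -> np.ndarray:
        return np.flatnonzero(self.missing_mask)


@dataclasses.dataclass
class CovariateTable:
    """Fully observed per-subject covariates split into typed blocks."""

    continuous: np.ndarray
    binary: np.ndarray
    continuous_names: list[str]
    binary_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.continuous = np.asarray(self.continuous, dtype=float)
        self.binary = np.asarray(self.binary, dtype=float)
        n = len(self.subject_ids)
        if self.continuous.shape != (n, len(self.continuous_names)):
            raise ValidationError("continuous block shape mismatch")
        if self.binary.shape != (n, len(self.binary_names)):
            raise ValidationError("binary block shape mismatch")
        for name, block in (("continuous", self.continuous), ("binary", self.binary)):
            if np.isnan(block).any():
                raise ValidationError(f"{name} covariates contain missing values; "
                                      "covariates must be fully observed")
        bad = ~np.isin(self.binary, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"binary covariate {self.binary_names[j]!r} has non-binary value "
                f"{self.binary[i, j]!r} for subject {self.subject_ids[i]!r}"
            )


def read_covariates(path: str | Path, binary_cols: Sequence[str]) -> CovariateTable:
    """Read a covariate table, splitting the declared binary columns out.

    Every column not named in ``binary_cols`` is treated as continuous.
    """
    df = _read_table(path)
    values = _to_numeric(df, path)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path}: missing covariate value at row {df.index[i]!r}, column "
            f"{df.columns[j]!r}; covariates must be fully observed"
        )
    cols = [str(c) for c in df.columns]
    unknown = [c for c in binary_cols if c not in cols]
    if unknown:
        raise ValidationError(f"{path}: declared binary columns not in file: {unknown}")
    is_bin = np.array([c in set(binary_cols) for c in cols])
    return CovariateTable(
        continuous=values[:, ~is_bin],
        binary=values[:, is_bin],
        continuous_names=[c for c, b in zip(cols, is_bin) if not b],
        binary_names=[c for c, b in zip(cols, is_bin) if b],
        subject_ids=[str(i) for i in df.index],
    )


def load_paired_set(
    normal_path: str | Path,
    tumor_path: str | Path,
    orientation: str = "subjects",
) -> PairedExpressionSet:
    """Read the normal and tumor matrices and pair them.

    Subject and feature ids must agree in content and order between the two
    files; any discrepancy is an error rather than a silent reindex.
    """
    normal, n_subj, n_feat = read_expression_matrix(normal_path, orientation)
    tumor, t_subj, t_feat = read_expression_matrix(tumor_path, orientation)
    if n_subj != t_subj:
        off = sorted(set(n_subj).symmetric_difference(t_subj)) or ["(ordering differs)"]
        raise ValidationError(f"subject ids differ between normal and tumor files: {off}")
    if n_feat != t_feat:
        off = sorted(set(n_feat).symmetric_difference(t_feat)) or ["(ordering differs)"]
        raise ValidationError(f"feature ids differ between normal and tumor files: {off}")
    return PairedExpressionSet.from_matrices(normal, tumor, n_subj, n_feat)


def validate_paired_set(
    pes: PairedExpressionSet, cov: CovariateTable, k: int | None = None
) -> None:
    """Cross-check an expression set against its covariate table.

    Verifies subject id agreement (content and order) and, when ``k`` is
    given, that at least ``k`` fully observed subjects exist to impute from.
    """
    if pes.subject_ids != cov.subject_ids:
        off = sorted(set(pes.subject_ids).symmetric_difference(cov.subject_ids))
        detail = off if off else ["(same ids, different order)"]
        raise ValidationError(
            f"subject ids differ between expression and covariate tables: {detail}"
        )
    if k is not None:
        n_obs = pes.n_subjects - pes.n_missing
        if k > n_obs:
            raise ValidationError(
                f"k={k} exceeds the {n_obs} fully observed subjects available as neighbors"
            )


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth retained by the simulator for scoring.

    ``de_indicator`` marks the features drawn from the shifted tumor
    distribution; if the simulation was run with ``mu_de == mu_null`` no
    feature is truly differentially expressed regardless of the indicator.
    ``true_normal`` is the pre-masking normal matrix used for RMSE scoring.
    """

    true_normal: np.ndarray
    de_indicator: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        self.true_normal = np.asarray(self.true_normal, float)
        self.de_indicator = np.asarray(self.de_indicator, bool)
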