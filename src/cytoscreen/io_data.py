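"""Cohort table I/O, train/validation splitting and standardization.

The central container is :class:`CohortTable`: one row per patient, one
column per gated flow-cytometry population expression (continuous), plus a
binary phenotype label (1 = case, e.g. interstitial lung disease; 0 = no
case).  Patients with any missing value are excluded at load time — the
pipeline never imputes.

Standardization is always anchored to *training* statistics: validation
data are z-scored with the training mean and standard deviation, and the
screening-tool threshold ranges are the standardized training minima and
maxima.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "StandardizationParams",
    "read_cohort",
    "split_cohort",
    "fit_standardization",
    "standardize",
]


@dataclass
class CohortTable:
    """Patients x continuous biomarker variables with a binary phenotype.

    Parameters
    ----------
    patient_ids
        Unique string identifier per patient (row).
    variables
        Ordered variable (column) names; unique.
    X
        Float matrix of shape ``(n_patients, n_variables)`` with no missing
        values.
    phenotype
        Integer 0/1 label per patient; 1 is the case class.
    """

    patient_ids: list[str]
    variables: list[str]
    X: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if len(self.patient_ids) != n or len(self.phenotype) != n:
            raise ValueError("patient_ids, phenotype and X rows must align")
        if len(self.variables) != p:
            raise ValueError("variables and X columns must align")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient IDs")
        if len(set(self.variables)) != p:
            raise ValueError("duplicate variable names")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        vals = set(np.unique(self.phenotype).tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"phenotype must be coded 0/1, found {sorted(vals)}")
        self.phenotype = self.phenotype.astype(np.int64)

    # -- conveniences -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    @property
    def prevalence(self) -> float:
        """Fraction of case (phenotype 1) patients."""
        return float(self.phenotype.mean())

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.variables.index(name)]

    def subset(self, row_idx: Sequence[int]) -> "CohortTable":
        """New cohort restricted to the given row indices (order kept)."""
        row_idx = np.asarray(row_idx, dtype=int)
        return CohortTable(
            patient_ids=[self.patient_ids[i] for i in row_idx],
            variables=list(self.variables),
            X=self.X[row_idx],
            phenotype=self.phenotype[row_idx],
        )

    def to_dataframe(self, phenotype_column: str = "phenotype") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.variables)
        df.insert(0, "patient_id", self.patient_ids)
        df[phenotype_column] = self.phenotype
        return df

    def write_csv(self, path: str | Path, phenotype_column: str = "phenotype") -> None:
        self.to_dataframe(phenotype_column).to_csv(path, index=False)


@dataclass
class StandardizationParams:
    """Per-variable training statistics used to z-score any cohort.

    ``sd`` uses the n-1 denominator.  ``zmin``/``zmax`` are the standardized
    training extremes, the support of the random screening-tool thresholds.
    """

    variables: list[str]
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray

    @property
    def zmin(self) -> np.ndarray:
        return (self.min - self.mean) / self.sd

    @property
    def zmax(self) -> np.ndarray:
        return (self.max - self.mean) / self.sd


def read_cohort(
    path: str | Path,
    phenotype_column: str,
    id_column: str | None = "patient_id",
) -> tuple[CohortTable, int]:
    """Read a delimited cohort table; drop rows with any missing value.

    Parameters
    ----------
    path
        CSV file with a header row; '.' decimal separator.
    phenotype_column
        Name of the 0/1 phenotype column.
    id_column
        Column holding patient identifiers.  If absent or ``None``,
        identifiers ``p0001, p0002, ...`` are assigned from row order.

    Returns
    -------
    (cohort, n_dropped)
        The loaded table and the number of rows dropped for missingness.
    """
    df = pd.read_csv(path)
    if phenotype_column not in df.columns:
        raise ValueError(f"phenotype column {phenotype_column!r} not found")
    if id_column is not None and id_column in df.columns:
        ids_raw = df[id_column].astype(str)
        df = df.drop(columns=[id_column])
    else:
        ids_raw = pd.Series([f"p{i + 1:04d}" for i in range(len(df))])
    n_before = len(df)
    keep = df.notna().all(axis=1)
    df = df.loc[keep]
    ids_raw = ids_raw[keep.to_numpy()]
    n_dropped = n_before - len(df)
    if len(df) == 0:
        raise ValueError("no usable rows after dropping missing data")
    y = df[phenotype_column]
    y_num = pd.to_numeric(y, errors="coerce")
    if y_num.isna().any() or not set(np.unique(y_num)) <= {0.0, 1.0}:
        raise ValueError(f"phenotype column {phenotype_column!r} is not binary 0/1")
    variables = [c for c in df.columns if c != phenotype_column]
    cohort = CohortTable(
        patient_ids=ids_raw.tolist(),
        variables=variables,
        X=df[variables].to_numpy(dtype=float),
        phenotype=y_num.to_numpy(dtype=int),
    )
    return cohort, n_dropped


def split_cohort(
    cohort: CohortTable,
    n_train: int,
    seed: int,
    stratify: bool = False,
) -> tuple[CohortTable, CohortTable]:
    """Random disjoint training/validation partition.

    The default is a simple random split (119 -> 79 + 40 in the motivating
    study); ``stratify=True`` instead splits each phenotype class
    proportionally.
    """
    n = cohort.n_patients
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[int] = []
        frac = n_train / n
        classes = [1, 0]
        # round per-class counts, fixing the total to n_train exactly
        idx_by_class = {c: np.flatnonzero(cohort.phenotype == c) for c in classes}
        n_c1 = int(round(frac * len(idx_by_class[1])))
        counts = {1: n_c1, 0: n_train - n_c1}
        for c in classes:
            pool = idx_by_class[c]
            take = rng.choice(pool, size=counts[c], replace=False)
            train_idx.extend(take.tolist())
        train_idx = sorted(train_idx)
    else:
        train_idx = sorted(rng.choice(n, size=n_train, replace=False).tolist())
    valid_idx = sorted(set(range(n)) - set(train_idx))
    return cohort.subset(train_idx), cohort.subset(valid_idx)


def fit_standardization(train: CohortTable) -> StandardizationParams:
    """Per-variable mean / sd / min / max computed on training data only."""
    if train.n_patients < 2:
        raise ValueError("need at least 2 patients to fit standardization")
    sd = train.X.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        names = [train.variables[i] for i in degenerate]
        raise ValueError(f"constant variable(s), sd = 0: {names}")
    return StandardizationParams(
        variables=list(train.variables),
        mean=train.X.mean(axis=0),
        sd=sd,
        min=train.X.min(axis=0),
        max=train.X.max(axis=0),
    )


def standardize(cohort: CohortTable, params: StandardizationParams) -> CohortTable:
    """z-score every variable with the (training) ``params``.

    Validation cohorts must be standardized with the training parameters,
    never with their own statistics.
    """
    if list(cohort.variables) != list(params.variables):
        raise ValueError("variable lists of cohort and params do not match")
    Z = (cohort.X - params.mean) / params.sd
    return dataclasses.replace(cohort, X=Z, patient_ids=list(cohort.patient_ids),
                               variables=list(cohort.variables),
                               phenotype=cohort.phenotype.copy())
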