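"""Cohort data model: phenotypes, connectivity sets, SNP dosages, subgroups.

A :class:`Cohort` aligns a phenotype table with zero or more per-task
connectivity feature sets and an optional SNP dosage matrix, all sharing one
subject order.  Subgroup masks carry the query string that produced them so
any mask can be re-derived from its provenance.

Missing phenotype values are handled complete-case per analysis: a missing
value never satisfies a subgroup predicate and is dropped (pairwise) before
any correlation or regression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .edges import EdgeIndex
from .exceptions import (
    DataError,
    DegenerateDesignError,
    QueryError,
    RequestError,
)

__all__ = [
    "PhenotypeTable",
    "ConnectivitySet",
    "SNPDosageMatrix",
    "Cohort",
    "GroupMask",
    "subset",
    "filter_snps",
    "residualize",
]

COLUMN_KINDS = ("continuous", "binary", "categorical")


@dataclass
class PhenotypeTable:
    """Subject-indexed table of phenotype variables.

    Parameters
    ----------
    data
        DataFrame indexed by unique subject id (strings).  Missing values
        are NaN (continuous/binary) or pandas NA.
    kinds
        Mapping column -> ``continuous`` | ``binary`` | ``categorical``.
        Undeclared columns are inferred: numeric -> continuous, else
        categorical.
    units
        Optional mapping column -> unit string (e.g. ``age: months``).
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate subject ids: {dupes}")
        for col, kind in self.kinds.items():
            if kind not in COLUMN_KINDS:
                raise DataError(f"unknown column kind {kind!r} for {col!r}")
            if col not in self.data.columns:
                raise DataError(f"declared column {col!r} not in table")
        for col in self.data.columns:
            if col not in self.kinds:
                self.kinds[col] = (
                    "continuous"
                    if pd.api.types.is_numeric_dtype(self.data[col])
                    else "categorical"
                )
        for col, kind in self.kinds.items():
            if kind == "binary":
                levels = self.data[col].dropna().unique()
                if len(levels) > 2:
                    raise DataError(
                        f"binary column {col!r} has {len(levels)} observed levels"
                    )

    @property
    def subject_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise QueryError(f"unknown phenotype column {name!r}")
        return self.data[name]


@dataclass
class ConnectivitySet:
    """n_subjects x m edge-feature matrix for one scanner task.

    ``scale`` records whether values are raw Pearson r (bounded in [-1, 1])
    or Fisher z.  Row order matches the owning cohort's phenotype table;
    subjects lacking this modality have all-NaN rows.
    """

    task: str
    values: np.ndarray
    edge_index: EdgeIndex
    scale: str = "pearson_r"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"connectivity values must be 2-D, got {self.values.ndim}-D")
        if self.values.shape[1] != self.edge_index.m:
            raise DataError(
                f"task {self.task!r}: {self.values.shape[1]} edge columns but "
                f"p={self.edge_index.p} implies m={self.edge_index.m}"
            )
        if self.scale not in ("pearson_r", "fisher_z"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == "pearson_r":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise DataError(
                    f"task {self.task!r}: pearson_r values outside [-1, 1]"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.edge_index.m

    def observed_mask(self) -> np.ndarray:
        """Boolean vector: subjects with at least one finite edge value."""
        return np.isfinite(self.values).any(axis=1)


@dataclass
class SNPDosageMatrix:
    """n_subjects x s minor-allele dosage matrix.

    Values are in {0, 1, 2} with NaN for missing genotypes.  Missingness is
    kept explicit; zero-fill (the analysis-time policy) is applied only on
    request via :meth:`filled`, so that presence filters act on the true
    missingness mask rather than on filled values.
    """

    snp_ids: list[str]
    values: np.ndarray
    encoding: str = "dosage_012"

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.snp_ids):
            raise DataError(
                f"dosage matrix shape {self.values.shape} does not match "
                f"{len(self.snp_ids)} SNP ids"
            )
        if self.encoding not in ("dosage_012", "onehot_haplotype"):
            raise DataError(f"unknown SNP encoding {self.encoding!r}")
        if self.encoding == "dosage_012":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
                raise DataError("dosage_012 values must be in {0, 1, 2} or missing")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def filled(self) -> np.ndarray:
        """Dosages with missing genotypes zero-filled."""
        return np.nan_to_num(self.values, nan=0.0)

    def to_onehot(self) -> "SNPDosageMatrix":
        """Expand each SNP to three haplotype indicator columns.

        Order per SNP: homozygous minor (dosage 2), heterozygous (1),
        homozygous major (0).  Missing genotypes give all-zero indicators.
        """
        if self.encoding != "dosage_012":
            raise DataError("to_onehot requires dosage_012 encoding")
        n, s = self.values.shape
        out = np.zeros((n, 3 * s))
        labels = []
        for j, rs in enumerate(self.snp_ids):
            for slot, (dose, tag) in enumerate(
                [(2.0, "hom_minor"), (1.0, "het"), (0.0, "hom_major")]
            ):
                out[:, 3 * j + slot] = (self.values[:, j] == dose).astype(float)
                labels.append(f"{rs}:{tag}")
        return SNPDosageMatrix(labels, out, encoding="onehot_haplotype")


@dataclass
class GroupMask:
    """Boolean subject mask plus the query string that produced it."""

    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Cohort:
    """Aligned multi-modal cohort: phenotypes + connectivity sets + SNPs."""

    phenotypes: PhenotypeTable
    connectivity: dict[str, ConnectivitySet] = field(default_factory=dict)
    snps: SNPDosageMatrix | None = None
    name: str = "cohort"

    def __post_init__(self) -> None:
        n = self.phenotypes.n_subjects
        for task, cs in self.connectivity.items():
            if cs.n_subjects != n:
                raise DataError(
                    f"task {task!r} has {cs.n_subjects} rows; phenotypes have {n}"
                )
        if self.snps is not None and self.snps.n_subjects != n:
            raise DataError(
                f"SNP matrix has {self.snps.n_subjects} rows; phenotypes have {n}"
            )

    @property
    def n_subjects(self) -> int:
        return self.phenotypes.n_subjects

    @property
    def subject_ids(self) -> list[str]:
        return self.phenotypes.subject_ids

    def missing_modality(self, task: str) -> list[str]:
        """Subjects present in phenotypes but lacking connectivity for ``task``."""
        cs = self.connectivity[task]
        obs = cs.observed_mask()
        return [sid for sid, ok in zip(self.subject_ids, obs) if not ok]

    def apply_mask(self, mask: GroupMask) -> "Cohort":
        """Subject-consistent sub-cohort selected by ``mask``."""
        if len(mask) != self.n_subjects:
            raise DataError(
                f"mask length {len(mask)} != cohort size {self.n_subjects}"
            )
        sel = mask.values
        pheno = PhenotypeTable(
            self.phenotypes.data.loc[sel],
            kinds=dict(self.phenotypes.kinds),
            units=dict(self.phenotypes.units),
        )
        conn = {
            task: replace(cs, values=cs.values[sel])
            for task, cs in self.connectivity.items()
        }
        snps = (
            SNPDosageMatrix(self.snps.snp_ids, self.snps.values[sel], self.snps.encoding)
            if self.snps is not None
            else None
        )
        return Cohort(pheno, conn, snps, name=f"{self.name}[{mask.provenance}]")


def subset(cohort: Cohort, query: str) -> GroupMask:
    """Evaluate a phenotype predicate and return a reproducible subject mask.

    ``query`` is a pandas expression over phenotype columns, e.g.
    ``race == "EA"`` or ``mother_education <= 12``.  Missing values never
    satisfy a predicate.  An empty query selects everyone.

    >>> subset(cohort, 'mother_education <= 12')  # doctest: +SKIP
    """
    df = cohort.phenotypes.data
    if not query.strip():
        return GroupMask(np.ones(len(df), dtype=bool), provenance="")
    try:
        result = df.eval(query)
    except Exception as exc:  # pandas raises several types for bad queries
        raise QueryError(f"cannot evaluate query {query!r}: {exc}") from exc
    if not (isinstance(result, pd.Series) and result.dtype != object):
        raise QueryError(f"query {query!r} did not produce a boolean vector")
    mask = result.fillna(False).to_numpy(dtype=bool)
    # rows with any missing value among referenced columns must not qualify
    referenced = [
        c for c in df.columns if re.search(rf"\b{re.escape(c)}\b", query)
    ]
    if referenced:
        complete = df[referenced].notna().all(axis=1).to_numpy()
        mask &= complete
    return GroupMask(mask, provenance=query)


def filter_snps(snps: SNPDosageMatrix, min_subjects: int) -> SNPDosageMatrix:
    """Keep SNPs with a non-missing genotype in at least ``min_subjects`` subjects.

    Presence is decided on the missingness mask *before* any zero-fill, so a
    true dosage of 0 counts as observed.  Column order is preserved.
    """
    if min_subjects < 0:
        raise RequestError(f"min_subjects must be >= 0, got {min_subjects}")
    counts = np.isfinite(snps.values).sum(axis=0)
    keep = counts >= min_subjects
    ids = [rs for rs, k in zip(snps.snp_ids, keep) if k]
    return SNPDosageMatrix(ids, snps.values[:, keep], snps.encoding)


def residualize(
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | pd.Series | np.ndarray,
) -> pd.Series:
    """OLS residuals of ``y`` on covariates plus an intercept.

    Complete cases only; rows with any missing value get NaN residuals.
    Residuals sum to zero and are uncorrelated with each covariate.  Used
    e.g. to age-residualize an achievement score before association mapping.
    """
    y_ser = pd.Series(np.asarray(y, dtype=float)) if not isinstance(y, pd.Series) else y.astype(float)
    if isinstance(covariates, pd.Series):
        cov_df = covariates.to_frame()
    elif isinstance(covariates, pd.DataFrame):
        cov_df = covariates
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cov_df = pd.DataFrame(arr)
    if len(cov_df) != len(y_ser):
        raise DataError("y and covariates have different lengths")
    cov = cov_df.to_numpy(dtype=float)
    yv = y_ser.to_numpy(dtype=float)
    complete = np.isfinite(yv) & np.isfinite(cov).all(axis=1)
    n_complete = int(complete.sum())
    if n_complete < cov.shape[1] + 2:
        raise DegenerateDesignError(
            f"{n_complete} complete cases for {cov.shape[1]} covariates"
        )
    X = np.column_stack([np.ones(n_complete), cov[complete]])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"design matrix rank {rank} < {X.shape[1]} (collinear covariates)"
        )
    beta, *_ = np.linalg.lstsq(X, yv[complete], rcond=None)
    resid = np.full(len(yv), np.nan)
    resid[complete] = yv[complete] - X @ beta
    return pd.Series(resid, index=y_ser.index, name=getattr(y_ser, "name", None))
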