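"""Connectivity estimation from region timeseries.

Functional connectivity (FC) is the matrix of pairwise Pearson correlations
between regional BOLD timeseries.  Partial-correlation (PC) connectivity is
the conditional association between two regions given all others, read off
the inverse of a shrinkage-regularized covariance:

    sigma_lambda = (1 - lambda) * S + lambda * diag(S)
    theta = sigma_lambda^{-1}
    pc_ij = -theta_ij / sqrt(theta_ii * theta_jj)

Covariances use the maximum-likelihood denominator ``T`` throughout; partial
correlations are invariant to this choice but it must be frozen for
reproducibility.  Correlation-scale maps can be Fisher-z transformed
(``z = atanh(r)``) so that effects become approximately additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import ConnectivitySet, GroupMask
from .edges import EdgeIndex
from .exceptions import (
    DataError,
    EmptyGroupError,
    IncompatibleMapsError,
    SingularCovarianceError,
)

__all__ = [
    "TimeseriesMatrix",
    "SymmetricMap",
    "pearson_fc",
    "partial_corr",
    "fisher_z",
    "inverse_fisher",
    "mean_map",
    "map_math",
    "FISHER_CLIP",
]

FISHER_CLIP = 1e-6  # |r| clipped to 1 - FISHER_CLIP before atanh


@dataclass
class TimeseriesMatrix:
    """``p`` regions x ``T`` timepoints of BOLD-derived signal for one subject."""

    values: np.ndarray
    subject_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("timeseries must be 2-D (regions x time)")
        if self.values.shape[1] < 3:
            raise DataError(
                f"need at least 3 timepoints, got {self.values.shape[1]}"
            )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class SymmetricMap:
    """Symmetric ``p x p`` connectivity or association map with zero diagonal."""

    matrix: np.ndarray
    scale: str = "pearson_r"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise DataError(f"map must be square, got shape {self.matrix.shape}")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise DataError("map must be symmetric")
        np.fill_diagonal(self.matrix, 0.0)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    @property
    def edge_index(self) -> EdgeIndex:
        return EdgeIndex(self.p)

    def to_vector(self) -> np.ndarray:
        return self.edge_index.to_vector(self.matrix)

    @classmethod
    def from_vector(cls, vec: np.ndarray, p: int, scale: str = "pearson_r") -> "SymmetricMap":
        return cls(EdgeIndex(p).to_matrix(np.asarray(vec, dtype=float)), scale=scale)


def _constant_rows(values: np.ndarray) -> np.ndarray:
    return np.ptp(values, axis=1) == 0


def pearson_fc(ts: TimeseriesMatrix) -> SymmetricMap:
    """Pearson functional connectivity of a region x time matrix.

    Each region is demeaned over time internally.  A constant region has an
    undefined correlation; its edges are set to 0 and a warning recorded on
    the returned map.
    """
    X = ts.values - ts.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    dead = norms == 0
    notes: list[str] = []
    if dead.any():
        idx = np.flatnonzero(dead).tolist()
        msg = f"constant region(s) {idx}: correlations set to 0"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        notes.append(msg)
        norms = np.where(dead, 1.0, norms)
    Xn = X / norms[:, None]
    r = Xn @ Xn.T
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    out = SymmetricMap((r + r.T) / 2.0, scale="pearson_r")
    out.warnings = notes
    return out


def partial_corr(ts: TimeseriesMatrix, shrinkage: float = 0.1) -> SymmetricMap:
    """Partial-correlation connectivity via a shrinkage-regularized precision.

    Parameters
    ----------
    shrinkage
        lambda in [0, 1]; weight on the diagonal of the sample covariance.
        lambda > 0 guarantees positive definiteness whenever every region
        has nonzero variance, including the T < p regime.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise DataError(f"shrinkage must be in [0, 1], got {shrinkage}")
    X = ts.values - ts.values.mean(axis=1, keepdims=True)
    S = (X @ X.T) / ts.T  # maximum-likelihood covariance
    sigma = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"regularized covariance not positive definite at shrinkage="
            f"{shrinkage}; raise the shrinkage parameter"
        ) from exc
    ident = np.eye(ts.p)
    theta = np.linalg.solve(L.T, np.linalg.solve(L, ident))
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return SymmetricMap((pc + pc.T) / 2.0, scale="pearson_r")


def fisher_z(values: np.ndarray | SymmetricMap) -> np.ndarray | SymmetricMap:
    """Variance-stabilizing Fisher transform ``z = atanh(r)``.

    Values with ``|r| >= 1 - FISHER_CLIP`` are clipped first so the result
    is always finite.
    """
    if isinstance(values, SymmetricMap):
        return SymmetricMap(np.asarray(fisher_z(values.matrix)), scale="fisher_z")
    r = np.clip(np.asarray(values, dtype=float), -1 + FISHER_CLIP, 1 - FISHER_CLIP)
    return np.arctanh(r)


def inverse_fisher(values: np.ndarray | SymmetricMap) -> np.ndarray | SymmetricMap:
    """Inverse Fisher transform ``r = tanh(z)``."""
    if isinstance(values, SymmetricMap):
        return SymmetricMap(np.tanh(values.matrix), scale="pearson_r")
    return np.tanh(np.asarray(values, dtype=float))


def mean_map(conn: ConnectivitySet, mask: GroupMask | None = None) -> SymmetricMap:
    """Elementwise mean connectivity over the subjects a mask selects."""
    if mask is None:
        sel = np.ones(conn.n_subjects, dtype=bool)
    else:
        if len(mask) != conn.n_subjects:
            raise DataError("mask length does not match connectivity set")
        sel = mask.values
    if not sel.any():
        raise EmptyGroupError("mask selects no subjects")
    vec = conn.values[sel].mean(axis=0)
    return SymmetricMap.from_vector(vec, conn.edge_index.p, scale=conn.scale)


def map_math(a: SymmetricMap, b: SymmetricMap, op: str) -> SymmetricMap:
    """Elementwise arithmetic on two maps: ``add``, ``subtract`` or ``hadamard``."""
    if a.p != b.p:
        raise IncompatibleMapsError(f"parcel counts differ: {a.p} vs {b.p}")
    if a.scale != b.scale:
        raise IncompatibleMapsError(f"scales differ: {a.scale} vs {b.scale}")
    if op == "add":
        out = a.matrix + b.matrix
    elif op == "subtract":
        out = a.matrix - b.matrix
    elif op == "hadamard":
        out = a.matrix * b.matrix
    else:
        raise IncompatibleMapsError(f"unknown op {op!r}")
    return SymmetricMap(out, scale=a.scale)
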