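"""Mass-univariate association mapping with Bonferroni control.

Every feature (FC edge, SNP column, or decomposition component) is
correlated with a phenotype using the Pearson formula — for a 0/1-coded
binary phenotype this is the point-biserial correlation.  Two-sided
p-values come from the exact t reference distribution,

    t = r * sqrt((n - 2) / (1 - r^2)),  df = n - 2,

and the family-wise adjustment is Bonferroni over the m features of the
current map: ``p_adj = min(1, m * p_raw)``.

Complete cases are taken per feature, so ``n_used`` may vary across SNPs
with missing genotypes while FC edges typically share one n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PhenotypeTable
from .exceptions import (
    DegeneratePhenotypeError,
    IncompatibleMapsError,
    RequestError,
)

__all__ = [
    "AssociationMap",
    "correlate_features",
    "neglog10_display",
    "top_k",
    "overlap_count",
    "containment_fraction",
    "correlate_phenotypes",
]

DISPLAY_CLIP = 5.0  # -log10(p_adj) display ceiling


@dataclass
class AssociationMap:
    """Per-feature correlation map against one phenotype.

    Attributes
    ----------
    feature_ids
        Identifiers (edge ids as ints, or rs-style strings for SNPs).
    r, p_raw, p_adj, n_used
        Per-feature correlation, two-sided raw p, Bonferroni-adjusted p,
        and complete-case count.
    m
        Number of simultaneous tests (the Bonferroni family size).
    phenotype
        Name of the phenotype column, for provenance.
    """

    feature_ids: np.ndarray
    r: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    n_used: np.ndarray
    m: int
    phenotype: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids)
        for name in ("r", "p_raw", "p_adj"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n_used = np.asarray(self.n_used, dtype=int)

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form (one row per feature) for CSV export."""
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "r": self.r,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "n_used": self.n_used,
                "display": neglog10_display(self),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r of X against y, complete cases per column.

    Returns (r, p_raw, n_used).  Zero-variance columns and columns with
    fewer than 3 complete cases get r = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(X) & np.isfinite(y)[:, None]
    Xm = np.where(ok, X, 0.0)
    ym = np.where(ok, y[:, None], 0.0)
    n = ok.sum(axis=0).astype(float)
    n_safe = np.where(n > 0, n, 1.0)
    sx = Xm.sum(axis=0)
    sy = ym.sum(axis=0)
    sxx = (Xm * Xm).sum(axis=0)
    syy = (ym * ym).sum(axis=0)
    sxy = (Xm * ym).sum(axis=0)
    cov = sxy - sx * sy / n_safe
    vx = sxx - sx * sx / n_safe
    vy = syy - sy * sy / n_safe
    denom = np.sqrt(np.clip(vx, 0, None) * np.clip(vy, 0, None))
    valid = (n >= 3) & (denom > 0)
    r = np.zeros(X.shape[1])
    np.divide(cov, denom, out=r, where=valid)
    np.clip(r, -1.0, 1.0, out=r)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(np.where(valid, df, 1.0) / np.clip(1.0 - r * r, 1e-300, None))
    p = np.ones(X.shape[1])
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df[valid])
    p[valid & (np.abs(r) >= 1.0)] = 0.0
    r[~valid] = 0.0
    return r, p, n.astype(int)


def correlate_features(
    X: np.ndarray,
    y: np.ndarray | pd.Series,
    feature_ids: np.ndarray | list | None = None,
    phenotype: str = "",
) -> AssociationMap:
    """Correlate every column of ``X`` with phenotype ``y``.

    ``y`` may be continuous or 0/1-coded binary (point-biserial).  Missing
    values (NaN) in either ``y`` or a feature column drop that subject from
    that feature's correlation only.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise RequestError("feature matrix must be 2-D (subjects x features)")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise RequestError("y length does not match feature matrix rows")
    y_obs = y[np.isfinite(y)]
    if y_obs.size < 3 or np.ptp(y_obs) == 0:
        raise DegeneratePhenotypeError(
            f"phenotype {phenotype!r} has no variance (or < 3 complete cases)"
        )
    m = X.shape[1]
    r, p_raw, n_used = _pearson_columns(X, y)
    p_adj = np.minimum(1.0, m * p_raw)
    if feature_ids is None:
        feature_ids = np.arange(m)
    return AssociationMap(
        feature_ids=np.asarray(feature_ids),
        r=r,
        p_raw=p_raw,
        p_adj=p_adj,
        n_used=n_used,
        m=m,
        phenotype=phenotype,
    )


def neglog10_display(amap: AssociationMap, clip: float = DISPLAY_CLIP) -> np.ndarray:
    """Clipped ``-log10`` of the Bonferroni-adjusted p, for display maps.

    ``p_adj = 0`` maps to the clip level (conventionally 5).
    """
    p = np.asarray(amap.p_adj, dtype=float)
    out = np.full(p.shape, clip)
    pos = p > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.minimum(-np.log10(p[pos]), clip)
    return out


def _ranked_order(amap: AssociationMap) -> np.ndarray:
    """Indices sorted by |r| descending, ties broken by ascending feature id."""
    ids = amap.feature_ids
    order = np.arange(len(ids))
    # lexsort: last key is primary
    if ids.dtype.kind in "iuf":
        return np.lexsort((ids, -np.abs(amap.r)))
    return np.array(
        sorted(order, key=lambda i: (-abs(amap.r[i]), str(ids[i])))
    )


def top_k(amap: AssociationMap, k: int) -> list:
    """The ``k`` features with largest ``|r|`` (deterministic tie-break by id)."""
    if k > len(amap):
        raise RequestError(f"k={k} exceeds {len(amap)} features")
    order = _ranked_order(amap)
    return [amap.feature_ids[i] for i in order[:k]]


def overlap_count(list_a: list, list_b: list) -> int:
    """Number of features shared by two ranked lists."""
    return len(set(list_a) & set(list_b))


def containment_fraction(
    map_a: AssociationMap, k_a: int, map_b: AssociationMap, k_b: int
) -> float:
    """Fraction of map A's top-k_a features inside map B's top-k_b.

    Turns the visual claim "A's hotspots are a subset of B's" into a number
    in [0, 1]: 1 means full containment.
    """
    if len(map_a) != len(map_b) or not np.array_equal(
        map_a.feature_ids, map_b.feature_ids
    ):
        raise IncompatibleMapsError("maps are over different feature spaces")
    a = top_k(map_a, k_a)
    b = top_k(map_b, k_b)
    return overlap_count(a, b) / float(k_a)


def correlate_phenotypes(
    table: PhenotypeTable, a: str, b: str
) -> tuple[float, float]:
    """Single Pearson / point-biserial correlation between two phenotype columns.

    Returns ``(r, p_raw)`` on complete cases; binary columns must be 0/1
    coded (categorical strings are not auto-coded).
    """
    xa = pd.to_numeric(table.column(a), errors="coerce").to_numpy(dtype=float)
    xb = pd.to_numeric(table.column(b), errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(xa) & np.isfinite(xb)
    if ok.sum() < 3:
        raise DegeneratePhenotypeError(
            f"fewer than 3 complete cases for {a!r} vs {b!r}"
        )
    if np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
        raise DegeneratePhenotypeError(
            f"zero variance in {a!r} or {b!r} on complete cases"
        )
    r, p, n = _pearson_columns(xa[ok][:, None], xb[ok])
    return float(r[0]), float(p[0])
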