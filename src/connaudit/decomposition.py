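"""PCA decomposition of cohort connectivity and model-weight summaries.

PCA runs over subjects (observations) x edges (variables), centered but not
scaled, so component loadings keep the magnitude structure of FC.  A
deterministic sign convention (the largest-|loading| entry of each
component is made positive) makes repeated runs bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .association import AssociationMap, correlate_features
from .cohort import ConnectivitySet
from .connectivity import SymmetricMap
from .exceptions import DataError, IncompatibleMapsError, RequestError

__all__ = [
    "DecompositionResult",
    "WeightSet",
    "pca_fc",
    "correlate_components",
    "average_weights",
]


@dataclass
class DecompositionResult:
    """Loadings, subject scores and variance fractions of a decomposition."""

    components: np.ndarray  # c x m unit-norm loading vectors
    scores: np.ndarray  # n x c subject coordinates
    variance_fractions: np.ndarray
    p: int  # parcel count, for reshaping loadings to maps

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        if self.components.shape[0] != self.scores.shape[1]:
            raise DataError("component count mismatch between loadings and scores")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def component_map(self, c: int) -> SymmetricMap:
        """Loading vector ``c`` reshaped to a symmetric edge map for display."""
        return SymmetricMap.from_vector(self.components[c], self.p, scale="loading")


@dataclass
class WeightSet:
    """One or more m-vectors of model weights with provenance labels."""

    weights: np.ndarray  # k x m
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.weights.shape[0] < 1:
            raise DataError("need at least one weight vector")
        if not self.labels:
            self.labels = [f"model_{i}" for i in range(self.weights.shape[0])]
        if len(self.labels) != self.weights.shape[0]:
            raise IncompatibleMapsError("label count does not match weight vectors")


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> None:
    """Make the largest-|loading| entry of each component positive (in place)."""
    for c in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[c])))
        if components[c, j] < 0:
            components[c] *= -1.0
            scores[:, c] *= -1.0


def pca_fc(conn: ConnectivitySet, n_components: int) -> DecompositionResult:
    """Principal components of a subject x edge connectivity matrix.

    Features are centered over subjects; loadings are unit-norm; variance
    fractions are non-increasing and sum to at most 1.
    """
    X = conn.values
    ok = np.isfinite(X).all(axis=1)
    X = X[ok]
    n, m = X.shape
    limit = min(n - 1, m)
    if n_components < 1 or n_components > limit:
        raise RequestError(
            f"n_components must be in 1..{limit} for {n} subjects x {m} edges"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    _fix_signs(components, scores)
    return DecompositionResult(
        components=components,
        scores=scores,
        variance_fractions=pca.explained_variance_ratio_.copy(),
        p=conn.edge_index.p,
    )


def correlate_components(
    result: DecompositionResult, y: np.ndarray, phenotype: str = ""
) -> AssociationMap:
    """Correlate each component's subject scores with a phenotype.

    Bonferroni correction is over the number of components, not edges.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != result.scores.shape[0]:
        raise DataError("phenotype not subject-aligned with decomposition scores")
    return correlate_features(
        result.scores,
        y,
        feature_ids=np.arange(result.n_components),
        phenotype=phenotype,
    )


def average_weights(ws: WeightSet) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and standard deviation over a set of weight vectors.

    The mean is reshapeable to a :class:`SymmetricMap` for display alongside
    connectivity maps.
    """
    mean = ws.weights.mean(axis=0)
    sd = ws.weights.std(axis=0)
    return mean, sd
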