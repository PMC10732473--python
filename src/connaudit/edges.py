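"""Edge indexing for functional-connectivity feature vectors.

A parcellation with ``p`` regions defines ``m = p(p-1)/2`` unordered region
pairs (edges).  Every edge-vector in this package uses the same frozen
ordering: **0-based, row-major upper triangle, i < j, diagonal excluded** —
the order produced by ``numpy.triu_indices(p, k=1)``.  Edge ``k`` of pair
``(i, j)`` satisfies

    k = i*p - i*(i+1)/2 + (j - i - 1)

and the mapping is a bijection on ``0..m-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EdgeIndexError, InvalidParcellationError

__all__ = ["EdgeIndex", "num_edges", "pair_to_edge", "edge_to_pair"]


def num_edges(p: int) -> int:
    """Number of off-diagonal upper-triangle edges for a ``p``-region parcellation.

    >>> num_edges(264)
    34716
    """
    if p < 2:
        raise InvalidParcellationError(f"parcel count must be >= 2, got {p}")
    return p * (p - 1) // 2


def pair_to_edge(i: int, j: int, p: int) -> int:
    """Edge id of region pair ``(i, j)`` with ``i < j`` under parcellation ``p``."""
    num_edges(p)  # validates p
    if not (0 <= i < j < p):
        raise EdgeIndexError(f"require 0 <= i < j < p, got (i={i}, j={j}, p={p})")
    return i * p - i * (i + 1) // 2 + (j - i - 1)


def edge_to_pair(k: int, p: int) -> tuple[int, int]:
    """Region pair ``(i, j)`` of edge id ``k``; exact inverse of :func:`pair_to_edge`."""
    m = num_edges(p)
    if not (0 <= k < m):
        raise EdgeIndexError(f"edge id {k} outside 0..{m - 1} for p={p}")
    # closed-form row recovery, then a guard against float rounding at large p
    i = int(p - 2 - np.floor(np.sqrt(-8 * k + 4 * p * (p - 1) - 7) / 2.0 - 0.5))
    while i > 0 and k < i * p - i * (i + 1) // 2:
        i -= 1
    while k >= (i + 1) * p - (i + 1) * (i + 2) // 2 and i < p - 2:
        i += 1
    j = k - (i * p - i * (i + 1) // 2) + i + 1
    return i, j


@dataclass(frozen=True)
class EdgeIndex:
    """Frozen edge ordering for a ``p``-region parcellation."""

    p: int

    def __post_init__(self) -> None:
        num_edges(self.p)  # validates

    @property
    def m(self) -> int:
        return num_edges(self.p)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(rows, cols)`` giving pair ``(i, j)`` for each edge id in order."""
        return np.triu_indices(self.p, k=1)

    def to_matrix(self, vec: np.ndarray) -> np.ndarray:
        """Expand an m-vector into a symmetric ``p x p`` matrix with zero diagonal."""
        vec = np.asarray(vec)
        if vec.shape[-1] != self.m:
            raise EdgeIndexError(
                f"edge vector length {vec.shape[-1]} != {self.m} for p={self.p}"
            )
        mat = np.zeros(vec.shape[:-1] + (self.p, self.p), dtype=vec.dtype)
        rows, cols = self.pairs()
        mat[..., rows, cols] = vec
        mat[..., cols, rows] = vec
        return mat

    def to_vector(self, mat: np.ndarray) -> np.ndarray:
        """Extract the upper-triangle edge vector from a symmetric matrix."""
        mat = np.asarray(mat)
        if mat.shape[-2:] != (self.p, self.p):
            raise EdgeIndexError(f"matrix shape {mat.shape[-2:]} != ({self.p}, {self.p})")
        rows, cols = self.pairs()
        return mat[..., rows, cols]
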