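"""Directed k-nearest-neighbour graphs over cell coordinates.

The Potts neighbourhood is the *directed* relation ``j in Nei_k(i)``: cell j
is one of the k nearest cells to i under Euclidean distance. The relation is
deliberately not symmetrized — the Potts exponent sums over ordered pairs,
and symmetrizing would change the scale of the interaction parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeighborGraph", "build_knn_graph", "directed_agreement_count"]


@dataclass
class NeighborGraph:
    """Per-cell directed neighbour lists, ``neighbors[i] = Nei_k(i)``."""

    neighbors: np.ndarray  # (n, k) int64
    k: int
    n: int

    def __post_init__(self):
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        if self.neighbors.shape != (self.n, self.k):
            raise ValueError("neighbors must have shape (n, k)")
        if np.any(self.neighbors < 0) or np.any(self.neighbors >= self.n):
            raise ValueError("neighbour indices out of range")
        rows = np.arange(self.n)[:, None]
        if np.any(self.neighbors == rows):
            raise ValueError("a cell cannot be its own neighbour")

    def conditional_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, indices) listing, for each cell i, its
        out-neighbours followed by its in-neighbours, with multiplicity.

        The joint Potts exponent sums the indicator over every ordered pair
        (i, j in Nei_k(i)), so the full conditional of one label C_i picks up
        a beta term for each edge touching i in either direction — a
        mutual-neighbour pair contributes twice. Cached on first use.
        """
        if not hasattr(self, "_cond_adj"):
            src = np.repeat(np.arange(self.n), self.k)
            tgt = self.neighbors.ravel()
            all_src = np.concatenate([src, tgt])
            all_tgt = np.concatenate([tgt, src])
            order = np.argsort(all_src, kind="stable")
            indices = all_tgt[order]
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            np.cumsum(np.bincount(all_src, minlength=self.n), out=indptr[1:])
            self._cond_adj = (indptr, indices)
        return self._cond_adj

    def to_edge_list(self) -> np.ndarray:
        """(n*k, 2) array of directed (source, target) edges."""
        src = np.repeat(np.arange(self.n), self.k)
        return np.column_stack([src, self.neighbors.ravel()])

    @classmethod
    def from_edge_list(cls, edges: np.ndarray, n: int) -> "NeighborGraph":
        edges = np.asarray(edges, dtype=np.int64)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
        counts = np.bincount(edges[:, 0], minlength=n)
        if counts.min() != counts.max():
            raise ValueError("edge list does not define a uniform-degree graph")
        k = int(counts[0])
        return cls(edges[:, 1].reshape(n, k), k=k, n=n)


def build_knn_graph(coords, k: int) -> NeighborGraph:
    """Exact k-nearest-neighbour graph under Euclidean distance.

    Ties are broken toward the lower cell index, making the result fully
    deterministic. Duplicate coordinates (distance zero) are allowed; the
    cell itself is always excluded.
    """
    xy = np.asarray(getattr(coords, "xy", coords), dtype=float)
    if xy.ndim != 2:
        raise ValueError("coordinates must be an n x d matrix")
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    n = xy.shape[0]
    if not k >= 1:
        raise ValueError("k must be a positive integer")
    if n <= k:
        raise ValueError(f"need at least k+1 = {k + 1} cells, got {n}")

    neighbors = np.empty((n, k), dtype=np.int64)
    idx = np.arange(n)
    # Chunked exact search; stable lexsort on (distance, index) fixes ties.
    chunk = max(1, int(2e7) // max(n, 1))
    sq = np.sum(xy * xy, axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2.0 * xy[start:stop] @ xy.T + sq[None, :]
        d2[idx[start:stop] - start, idx[start:stop]] = np.inf  # exclude self
        np.maximum(d2, 0.0, out=d2)
        order = np.lexsort((np.broadcast_to(idx, d2.shape), d2), axis=1)
        neighbors[start:stop] = order[:, :k]
    return NeighborGraph(neighbors, k=k, n=n)


def directed_agreement_count(C, graph: NeighborGraph) -> int:
    """Number of ordered pairs (i, j), j in Nei_k(i), with C_i = C_j.

    This is the sufficient statistic multiplying beta in the Potts exponent;
    it is bounded by n*k and invariant under any relabelling bijection of C.
    """
    C = np.asarray(C)
    if C.shape[0] != graph.n:
        raise ValueError(f"labels have length {C.shape[0]} but graph has {graph.n} cells")
    return int(np.sum(C[graph.neighbors] == C[:, None]))
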