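"""Viewer-interaction network: thresholding, communities, modularity.

The inferred couplings J_ij are binarised at a per-video threshold J_o
chosen where the giant connected component emerges (percolation practice:
scanning from strong to weak couplings, the first level at which the
largest component spans a majority of viewers).  Communities are found by
modularity maximisation (Louvain); modularity is

    Q = 1/(2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j),

with m the edge count and k_i the degrees.  A variant that normalises by
twice the total degree (prefactor 1/(4m)) is available behind a flag.
An exhaustive set-partition oracle is provided for small graphs (n <= 12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["ViewerNetwork", "percolation_threshold", "modularity",
           "detect_communities", "exact_max_modularity", "reorder_matrix",
           "build_network"]


@dataclass
class ViewerNetwork:
    """Binary viewer network with its community partition.

    A_ij = 1 iff J_ij > J_o; labels are community ids per node; Q the
    modularity of that partition.
    """

    j_o: float
    adjacency: np.ndarray
    labels: np.ndarray
    q: float
    subject_ids: list[str]

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels).size)

    def to_edge_frame(self, J: np.ndarray | None = None) -> pd.DataFrame:
        n = self.adjacency.shape[0]
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "i": self.subject_ids[i], "j": self.subject_ids[j],
                    "J_ij": float(J[i, j]) if J is not None else np.nan,
                    "adjacent": int(self.adjacency[i, j]),
                })
        return pd.DataFrame(rows)


def _largest_component_size(adj: np.ndarray) -> int:
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if labels.size == 0:
        return 0
    return int(np.bincount(labels).max())


def percolation_threshold(J: np.ndarray,
                          majority_fraction: float = 0.5) -> float:
    """Coupling threshold J_o at which the giant component emerges.

    Scans the unique off-diagonal coupling values from strongest to
    weakest; at each level c the adjacency keeps edges with J_ij >= c.  The
    emergence level is the first at which the largest connected component
    exceeds ``majority_fraction`` of the nodes.  The returned J_o sits just
    below that level (midway to the next-lower coupling value), so that
    ``A_ij = J_ij > J_o`` includes every edge at the emergence level.

    An all-equal off-diagonal J is degenerate: that value is returned with
    a warning.
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    if n < 3:
        raise ValueError("need >= 3 nodes")
    off = ~np.eye(n, dtype=bool)
    vals = np.unique(J[off])[::-1]  # descending
    if vals.size == 1:
        warnings.warn("all off-diagonal couplings equal: "
                      "degenerate percolation threshold")
        return float(vals[0])
    target = majority_fraction * n
    for k, c in enumerate(vals):
        adj = (J >= c) & off
        if _largest_component_size(adj) > target:
            if k + 1 < vals.size:
                return float(0.5 * (c + vals[k + 1]))
            span = float(vals[0] - vals[-1])
            return float(c - 1e-9 * max(1.0, abs(span)))
    # even the full graph never spans a majority (cannot happen for n>=3
    # with all edges present, but guard anyway)
    return float(vals[-1])


def modularity(A: np.ndarray, labels: np.ndarray,
               literal_normalisation: bool = False) -> float:
    """Newman modularity of a partition of a binary undirected graph.

    Standard form: Q = 1/(2m) sum_ij (A_ij - k_i k_j/(2m)) delta(c_i,c_j)
    with 2m = sum_i k_i.  With ``literal_normalisation`` the prefactor and
    null model use twice the total degree (i.e. 1/(4m)), halving Q.
    """
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    norm = 2 * two_m if literal_normalisation else two_m
    same = labels[:, None] == labels[None, :]
    q = ((A - np.outer(k, k) / norm) * same).sum() / norm
    return float(q)


def detect_communities(A: np.ndarray, seed: int = 0) -> np.ndarray:
    """Community labels by Louvain modularity maximisation.

    Isolated nodes each form their own community.  Requires >= 1 edge.
    """
    A = np.asarray(A, dtype=float)
    if A.sum() == 0:
        raise ValueError("community detection needs >= 1 edge")
    g = nx.from_numpy_array(A)
    parts = nx.algorithms.community.louvain_communities(g, seed=seed)
    labels = np.empty(A.shape[0], dtype=int)
    for c, members in enumerate(sorted(parts, key=min)):
        for node in members:
            labels[node] = c
    return labels


def _set_partitions(items: list[int]):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exact_max_modularity(A: np.ndarray,
                         literal_normalisation: bool = False
                         ) -> tuple[np.ndarray, float]:
    """Exhaustive modularity maximisation over all set partitions.

    Oracle for small graphs only (n <= 12; Bell numbers explode beyond).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n > 12:
        raise ValueError("exhaustive search limited to n <= 12 nodes")
    best_q = -np.inf
    best = None
    for part in _set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        q = modularity(A, labels, literal_normalisation)
        if q > best_q:
            best_q, best = q, labels
    return best, float(best_q)


def reorder_matrix(M: np.ndarray, labels: np.ndarray | None = None,
                   seed: int = 0) -> np.ndarray:
    """Display permutation grouping same-community rows/columns together.

    When labels are not supplied they are derived from the matrix itself
    (percolation threshold then Louvain).  Communities are ordered by
    decreasing size; within a community the original node order is kept.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n <= 1:
        return np.arange(n)
    if labels is None:
        try:
            j_o = percolation_threshold(M)
            adj = (M > j_o) & ~np.eye(n, dtype=bool)
            labels = detect_communities(adj.astype(float), seed=seed)
        except ValueError:
            return np.arange(n)
    labels = np.asarray(labels)
    sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
    order = sorted(range(n), key=lambda i: (-sizes[labels[i]],
                                            int(labels[i]), i))
    return np.asarray(order, dtype=int)


def build_network(J: np.ndarray, subject_ids: list[str] | None = None,
                  seed: int = 0,
                  literal_normalisation: bool = False) -> ViewerNetwork:
    """Threshold J at the percolation point, detect communities, score Q."""
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    ids = subject_ids or [f"s{i:02d}" for i in range(n)]
    j_o = percolation_threshold(J)
    adj = ((J > j_o) & ~np.eye(n, dtype=bool)).astype(float)
    labels = detect_communities(adj, seed=seed)
    q = modularity(adj, labels, literal_normalisation)
    return ViewerNetwork(j_o, adj, labels, q, list(ids))
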