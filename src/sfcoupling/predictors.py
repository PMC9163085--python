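"""Structural relationship matrices used to predict functional profiles.

A node's functional (co-fluctuation) profile is modelled from three pairwise
structural relationships: Euclidean distance between node centroids,
shortest path length on the weighted connectome, and weighted
communicability. Shortest paths and communicability are computed on the
minmax-normalized connectivity matrix; path search runs on edge lengths
obtained by a negative-log transform of the normalized weights, so strong
connections are short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components, csgraph_from_dense, shortest_path
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "PredictorSet",
    "euclidean_distance",
    "minmax_normalize",
    "weight_to_length",
    "shortest_path_length",
    "weighted_communicability",
    "build_predictors",
]


@dataclass(frozen=True)
class PredictorSet:
    """The three node-by-node structural predictor matrices.

    Attributes
    ----------
    dist : ndarray
        Euclidean distance between node centroids (length units).
    spl : ndarray
        Shortest path length on -log-transformed normalized weights.
    cmc : ndarray
        Weighted communicability of the normalized connectome.
    """

    dist: np.ndarray
    spl: np.ndarray
    cmc: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.dist.shape[0]


def _check_square_symmetric(w: np.ndarray, name: str = "matrix") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{name} must be square, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=1e-12, rtol=0.0):
        raise ValueError(f"{name} must be symmetric")
    return w


def euclidean_distance(geometry) -> np.ndarray:
    """Pairwise Euclidean distance between node centroids.

    Parameters
    ----------
    geometry : NodeGeometry or (n, 3) array
        Node centroids, or an object exposing a ``centroid`` attribute.
    """
    pts = np.asarray(getattr(geometry, "centroid", geometry), dtype=float)
    if pts.ndim != 2:
        raise ValueError("centroids must be a 2-D array of coordinates")
    d = squareform(pdist(pts))
    off = d[~np.eye(len(d), dtype=bool)]
    if np.any(off == 0.0):
        i, j = np.argwhere((d == 0.0) & ~np.eye(len(d), dtype=bool))[0]
        raise ValueError(f"duplicate centroids: nodes {i} and {j} coincide")
    return d


def minmax_normalize(weights: np.ndarray) -> np.ndarray:
    """Rescale connectivity weights to [0, 1] by (w - min) / (max - min).

    For a sparse connectome the minimum over all entries is 0 (the absent
    edges and the diagonal), so this reduces to division by the maximum:
    absent edges stay 0 and the strongest edge maps to 1.
    """
    w = _check_square_symmetric(weights, "connectivity matrix")
    if np.any(w < 0):
        raise ValueError("connectivity weights must be nonnegative")
    lo, hi = w.min(), w.max()
    if hi == lo:
        raise ValueError("connectivity matrix is constant (all-zero?); cannot normalize")
    return (w - lo) / (hi - lo)


def weight_to_length(weights_norm: np.ndarray) -> np.ndarray:
    """Map normalized weights to edge lengths via -log(w).

    Absent edges (w = 0) become non-traversable (+inf); the maximum-weight
    edge (w = 1) gets length exactly 0, which the path search tolerates.
    The diagonal is set non-traversable as well (no self-loops).
    """
    w = _check_square_symmetric(weights_norm, "normalized matrix")
    if w.min() < 0 or w.max() > 1:
        raise ValueError("weights outside [0, 1]; minmax-normalize the connectome first")
    lengths = np.full_like(w, np.inf)
    mask = w > 0
    lengths[mask] = -np.log(w[mask])
    np.fill_diagonal(lengths, np.inf)
    return lengths


def shortest_path_length(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths over nonnegative edge lengths.

    Entries of +inf mark absent edges. Zero-length edges are legal and
    preserved (Dijkstra handles them; lengths are never negative).
    Raises if the graph is disconnected, listing the components.
    """
    lengths = _check_square_symmetric(np.asarray(lengths, dtype=float), "length matrix")
    finite = np.isfinite(lengths)
    if np.any(lengths[finite] < 0):
        raise ValueError("edge lengths must be nonnegative")
    adjacency = np.where(finite, lengths, np.inf)
    graph = csgraph_from_dense(adjacency, null_value=np.inf)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        groups = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(f"graph is disconnected; components: {groups}")
    spl = shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(spl, 0.0)
    return spl


def weighted_communicability(weights_norm: np.ndarray) -> np.ndarray:
    """Weighted communicability: expm of the degree-normalized adjacency.

    C = exp(D^{-1/2} A D^{-1/2}) with D = diag(sum_k a_ik). Sums walks of
    all lengths between node pairs with factorial down-weighting; entrywise
    positive on connected graphs and >= 1 on the diagonal.
    """
    a = _check_square_symmetric(weights_norm, "adjacency matrix")
    if np.any(a < 0):
        raise ValueError("adjacency weights must be nonnegative")
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        bad = np.flatnonzero(deg <= 0).tolist()
        raise ValueError(f"isolated nodes (zero generalized degree): {bad}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    normed = a * np.outer(inv_sqrt, inv_sqrt)
    cmc = expm(normed)
    return (cmc + cmc.T) / 2.0


def build_predictors(geometry, sc: np.ndarray) -> PredictorSet:
    """Compose the full predictor set from geometry and a raw connectome.

    Shortest paths and communicability are both computed from the SAME
    minmax-normalized matrix; distance comes from the centroids alone.
    """
    pts = np.asarray(getattr(geometry, "centroid", geometry), dtype=float)
    sc = _check_square_symmetric(sc, "structural connectome")
    if len(pts) != sc.shape[0]:
        raise ValueError(
            f"geometry ({len(pts)} nodes) and connectome ({sc.shape[0]} nodes) disagree"
        )
    sc_norm = minmax_normalize(sc)
    dist = euclidean_distance(pts)
    spl = shortest_path_length(weight_to_length(sc_norm))
    cmc = weighted_communicability(sc_norm)
    return PredictorSet(dist=dist, spl=spl, cmc=cmc)
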