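"""Single-cell KNN graph construction and spatio-temporal augmentation.

The expression layer is a symmetric k-nearest-neighbor graph in feature
space (exact neighbor search; edge weight = exp(-d / sigma_local) with a
locally adaptive scale).  When ordinal time labels are available, each
cell additionally links to its nearest cells in the adjacent time
groups, and edges spanning more than ``t_threshold`` ordinal groups can
be pruned.  For spatial data the expression matrix can first be smoothed
over spatial neighbors, and the graph augmented with spatial-proximity
edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import (PROV_EXPRESSION, PROV_SEQUENTIAL, PROV_SPATIAL,
                         AugmentedGraph)

__all__ = ["GraphParams", "build_knn_graph", "augment_sequential",
           "smooth_expression_spatial", "augment_spatial"]


@dataclass
class GraphParams:
    """Knobs of the graph-construction stage.

    ``k`` neighbors for the expression layer, ``k_sequential`` per
    adjacent time group, ``k_spatial`` for spatial smoothing and
    augmentation; ``t_threshold`` is the maximum ordinal-label distance
    an edge may span (None disables pruning); ``self_weight`` is the
    cell's own share in spatial expression smoothing.
    """

    k: int = 30
    k_sequential: int = 5
    t_threshold: Optional[int] = None
    k_spatial: int = 8
    self_weight: float = 0.5
    distance_to_weight: Optional[Callable[[np.ndarray, float], np.ndarray]] = None

    def __post_init__(self) -> None:
        for name in ("k", "k_sequential"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.k_spatial < 0:
            raise ValueError("k_spatial must be >= 0")
        if not (0 < self.self_weight <= 1):
            raise ValueError("self_weight must be in (0, 1]")
        if self.t_threshold is not None and self.t_threshold < 0:
            raise ValueError("t_threshold must be >= 0")

    def weight_of(self, dist: np.ndarray, sigma: float) -> np.ndarray:
        if self.distance_to_weight is not None:
            return self.distance_to_weight(dist, sigma)
        return np.exp(-dist / max(sigma, 1e-12))


def _dedup_max(u, v, w, n) -> sp.csr_matrix:
    """Symmetric CSR from directed edges, duplicates resolved by max."""
    uu = np.concatenate([u, v])
    vv = np.concatenate([v, u])
    ww = np.concatenate([w, w])
    order = np.lexsort((vv, uu))
    uu, vv, ww = uu[order], vv[order], ww[order]
    # collapse duplicates keeping the max weight
    key_change = np.ones(len(uu), dtype=bool)
    key_change[1:] = (uu[1:] != uu[:-1]) | (vv[1:] != vv[:-1])
    group = np.cumsum(key_change) - 1
    wmax = np.zeros(group[-1] + 1 if len(group) else 0)
    np.maximum.at(wmax, group, ww)
    uu, vv = uu[key_change], vv[key_change]
    return sp.csr_matrix((wmax, (uu, vv)), shape=(n, n))


def build_knn_graph(features: np.ndarray, params: GraphParams) -> AugmentedGraph:
    """Symmetric KNN graph on the feature matrix (expression layer).

    Each cell is linked to its ``k`` nearest neighbors by Euclidean
    distance; the union with reversed edges makes the graph symmetric.
    Edge weight defaults to ``exp(-d / sigma_i)`` where ``sigma_i`` is
    the mean distance of cell *i* to its k neighbors (locally adaptive).
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError("features must be 2-D")
    if not np.isfinite(features).all():
        raise ValueError("features contain non-finite values")
    n = features.shape[0]
    if params.k >= n:
        raise ValueError(f"k={params.k} must be < n_cells={n}")

    nn = NearestNeighbors(n_neighbors=params.k + 1).fit(features)
    dist, ind = nn.kneighbors(features)
    dist, ind = dist[:, 1:], ind[:, 1:]          # drop self
    sigma = np.maximum(dist.mean(axis=1), 1e-12)
    w = params.weight_of(dist, 1.0) if params.distance_to_weight else \
        np.exp(-dist / sigma[:, None])
    u = np.repeat(np.arange(n), params.k)
    W = _dedup_max(u, ind.ravel(), w.ravel(), n)
    W.setdiag(0)
    W.eliminate_zeros()
    P = sp.csr_matrix((np.full(W.nnz, PROV_EXPRESSION, dtype=np.uint8),
                       W.indices.copy(), W.indptr.copy()), shape=(n, n))
    return AugmentedGraph(weights=W, provenance=P, k=params.k)


def _add_edges(graph: AugmentedGraph, u, v, w, prov_code) -> AugmentedGraph:
    """Add symmetric edges; existing edges keep max weight and original
    provenance."""
    n = graph.n_cells
    if len(u) == 0:
        return graph
    new_W = _dedup_max(np.asarray(u), np.asarray(v), np.asarray(w), n)
    new_W.setdiag(0)
    new_W.eliminate_zeros()
    W = graph.weights.maximum(new_W)
    # provenance: keep old where old edge existed, new code elsewhere
    P_new = sp.csr_matrix((np.full(new_W.nnz, prov_code, dtype=np.uint8),
                           new_W.indices, new_W.indptr), shape=(n, n))
    old_mask = graph.weights.copy()
    old_mask.data[:] = 1
    P = (graph.provenance.astype(np.float64) + P_new.astype(np.float64)
         - P_new.astype(np.float64).multiply(old_mask))
    P = sp.csr_matrix(P).astype(np.uint8)
    P.eliminate_zeros()
    return AugmentedGraph(weights=W, provenance=P, k=graph.k)


def augment_sequential(graph: AugmentedGraph, time_label: np.ndarray,
                       features: np.ndarray,
                       params: GraphParams) -> AugmentedGraph:
    """Add feature-space KNN edges restricted to adjacent time groups.

    For each cell, its ``k_sequential`` nearest cells among cells whose
    ordinal label differs by exactly 1 are linked with provenance
    ``sequential``.  If ``t_threshold`` is set, every edge joining cells
    whose ordinal distance exceeds it is removed afterwards (pruning is
    applied last).  Cells isolated by pruning trigger a warning.
    """
    if time_label is None:
        raise ValueError("[sequential] time labels required for sequential "
                         "augmentation")
    time_label = np.asarray(time_label)
    n = graph.n_cells
    if time_label.shape != (n,):
        raise ValueError("time_label must have one entry per cell")
    features = np.asarray(features, dtype=np.float64)
    levels = np.unique(time_label)

    us, vs, ws = [], [], []
    by_level = {lv: np.flatnonzero(time_label == lv) for lv in levels}
    for lv in levels:
        adjacent = np.concatenate([by_level.get(lv - 1, np.empty(0, int)),
                                   by_level.get(lv + 1, np.empty(0, int))])
        if len(adjacent) == 0:
            continue
        cells = by_level[lv]
        kk = min(params.k_sequential, len(adjacent))
        nn = NearestNeighbors(n_neighbors=kk).fit(features[adjacent])
        dist, ind = nn.kneighbors(features[cells])
        sigma = np.maximum(dist.mean(axis=1), 1e-12)
        w = np.exp(-dist / sigma[:, None])
        us.append(np.repeat(cells, kk))
        vs.append(adjacent[ind.ravel()])
        ws.append(w.ravel())
    if us:
        graph = _add_edges(graph, np.concatenate(us), np.concatenate(vs),
                           np.concatenate(ws), PROV_SEQUENTIAL)

    if params.t_threshold is not None:
        W = graph.weights.tocoo()
        span = np.abs(time_label[W.row] - time_label[W.col])
        keep = span <= params.t_threshold
        W2 = sp.csr_matrix((W.data[keep], (W.row[keep], W.col[keep])),
                           shape=W.shape)
        P = graph.provenance.tocoo()
        spanp = np.abs(time_label[P.row] - time_label[P.col])
        keepp = spanp <= params.t_threshold
        P2 = sp.csr_matrix((P.data[keepp], (P.row[keepp], P.col[keepp])),
                           shape=P.shape)
        graph = AugmentedGraph(weights=W2, provenance=P2, k=graph.k)
        deg = np.asarray((graph.weights > 0).sum(axis=1)).ravel()
        isolated = np.flatnonzero(deg == 0)
        if len(isolated):
            warnings.warn(
                f"t_threshold pruning isolated {len(isolated)} cells: "
                f"{isolated[:20].tolist()}", stacklevel=2)
    return graph


def smooth_expression_spatial(expression: np.ndarray, spatial_xy: np.ndarray,
                              params: GraphParams) -> np.ndarray:
    """Recalibrate expression as a weighted average over spatial neighbors.

    Row *i* of the output is ``self_weight * x_i + (1 - self_weight) *
    mean(x_j : j in kNN_spatial(i))`` — a row-stochastic linear map of
    the expression rows, so constant-rows inputs are fixed points.
    """
    expression = np.asarray(expression, dtype=np.float64)
    spatial_xy = np.asarray(spatial_xy, dtype=np.float64)
    n = expression.shape[0]
    if spatial_xy.shape[0] != n:
        raise ValueError("spatial_xy must have one row per cell")
    if params.k_spatial >= n:
        raise ValueError("k_spatial must be < n_cells")
    if params.self_weight == 1.0 or params.k_spatial == 0:
        return expression.copy()
    nn = NearestNeighbors(n_neighbors=params.k_spatial + 1).fit(spatial_xy)
    _, ind = nn.kneighbors(spatial_xy)
    neigh_mean = expression[ind[:, 1:]].mean(axis=1)
    return params.self_weight * expression + (1 - params.self_weight) * neigh_mean


def augment_spatial(graph: AugmentedGraph, spatial_xy: np.ndarray,
                    params: GraphParams) -> AugmentedGraph:
    """Add spatial-proximity edges to the graph.

    Each cell is linked to its ``k_spatial`` nearest neighbors in tissue
    coordinates; spatial weights are rescaled so their median matches
    the median expression-edge weight (the two distance scales are not
    otherwise comparable).
    """
    if params.k_spatial == 0:
        return graph
    spatial_xy = np.asarray(spatial_xy, dtype=np.float64)
    n = graph.n_cells
    if spatial_xy.shape[0] != n:
        raise ValueError("spatial_xy must have one row per cell")
    if params.k_spatial >= n:
        raise ValueError("k_spatial must be < n_cells")
    nn = NearestNeighbors(n_neighbors=params.k_spatial + 1).fit(spatial_xy)
    dist, ind = nn.kneighbors(spatial_xy)
    dist, ind = dist[:, 1:], ind[:, 1:]
    sigma = np.maximum(dist.mean(axis=1), 1e-12)
    w = np.exp(-dist / sigma[:, None])
    med_expr = np.median(graph.weights.data) if graph.weights.nnz else 1.0
    med_sp = np.median(w)
    if med_sp > 0:
        w = w * (med_expr / med_sp)
    u = np.repeat(np.arange(n), params.k_spatial)
    return _add_edges(graph, u, ind.ravel(), w.ravel(), PROV_SPATIAL)
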