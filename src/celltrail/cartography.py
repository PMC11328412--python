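"""Atlas cartography: layout, embedding, milestones and edge bundling.

The cluster graph is laid out with the Fruchterman-Reingold force
model (initialized at mean spatial cluster locations when tissue
coordinates exist).  Single cells are embedded by cross-entropy
optimization (UMAP machinery) over the *augmented* single-cell graph —
the neighbor graph is supplied, not recomputed from features — with each
cell initialized at its cluster's layout position.  The embedding is
then coarsened into a few hundred kmeans milestones whose aggregated
edges are bundled by kernel-density-estimation bundling: edges are
rasterized into a density map with an Epanechnikov kernel, interior
polyline points are advected up the density gradient, Laplacian-smoothed,
and the kernel bandwidth shrinks geometrically each iteration
(h_n = lambda^n * h_max) so edges sharpen into bundles.  Endpoints never
move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.signal import fftconvolve

from .containers import AtlasLayout, AugmentedGraph, ClusterGraph

__all__ = ["BundleConfig", "layout_cluster_graph", "initial_cell_positions",
           "embed_single_cells", "kmeans_milestones", "epanechnikov",
           "bandwidth_schedule", "bundle_edges", "compose_atlas_view"]


@dataclass
class BundleConfig:
    """KDE edge-bundling parameters.

    ``h_max`` is the initial kernel bandwidth in embedding units and
    shrinks by ``lambda_decay`` each iteration; each edge is discretized
    into ``n_advect`` points; ``smoothing_passes`` Laplacian passes are
    applied after each advection step.  ``grid_size`` is the raster
    resolution of the density map.
    """

    n_iterations: int = 6
    lambda_decay: float = 0.7
    h_max: float = 0.0          # 0 -> auto: 10% of bounding-box diagonal
    n_advect: int = 30
    smoothing_passes: int = 1
    grid_size: int = 512
    advect_step: float = 0.5    # in grid cells
    weighted_kernel: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.lambda_decay < 1):
            raise ValueError("lambda_decay must be in (0, 1)")
        if self.h_max < 0:
            raise ValueError("h_max must be positive (or 0 for auto)")
        if self.n_iterations < 1 or self.n_advect < 2:
            raise ValueError("n_iterations >= 1 and n_advect >= 2 required")
        if self.smoothing_passes < 0:
            raise ValueError("smoothing_passes must be >= 0")


def layout_cluster_graph(cg: ClusterGraph, seed: int = 0,
                         spatial_init: Optional[np.ndarray] = None,
                         n_iter: int = 200) -> np.ndarray:
    """Fruchterman-Reingold layout of the cluster graph.

    Deterministic for a fixed seed.  ``spatial_init`` (one row per
    cluster, e.g. mean tissue location of each cluster's cells) is used
    as the initial configuration when provided.
    """
    import networkx as nx

    n = cg.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(cg.W, k=1))
    for i, j in zip(iu, ju):
        G.add_edge(int(i), int(j), weight=float(cg.W[i, j]))
    pos_init = None
    if spatial_init is not None:
        spatial_init = np.asarray(spatial_init, dtype=float)
        if spatial_init.shape != (n, 2):
            raise ValueError("spatial_init must be (n_nodes, 2)")
        # normalize scale so FR's unit box assumptions hold
        span = spatial_init.max(axis=0) - spatial_init.min(axis=0)
        span[span == 0] = 1.0
        norm = (spatial_init - spatial_init.mean(axis=0)) / span.max()
        pos_init = {i: norm[i] for i in range(n)}
    pos = nx.spring_layout(G, weight="weight", seed=int(seed), pos=pos_init,
                           iterations=n_iter)
    return np.array([pos[i] for i in range(n)])


def initial_cell_positions(labels: np.ndarray, cluster_layout: np.ndarray,
                           seed: int = 0, jitter: float = 0.05) -> np.ndarray:
    """Each cell at its cluster's layout position plus small jitter.

    ``jitter`` is relative to the layout's bounding-box diagonal.
    """
    labels = np.asarray(labels)
    _, coded = np.unique(labels, return_inverse=True)
    if coded.max() + 1 > cluster_layout.shape[0]:
        raise ValueError("cells reference clusters missing from the layout")
    rng = np.random.default_rng(seed)
    diag = float(np.linalg.norm(cluster_layout.max(axis=0)
                                - cluster_layout.min(axis=0)))
    scale = jitter * max(diag, 1e-12)
    return cluster_layout[coded] + rng.normal(0.0, scale, size=(len(coded), 2))


def embed_single_cells(graph: AugmentedGraph, labels: np.ndarray,
                       cluster_layout: np.ndarray, seed: int = 0,
                       n_epochs: int = 150, min_dist: float = 0.1,
                       jitter: float = 0.05) -> np.ndarray:
    """Cross-entropy 2-D embedding of the augmented single-cell graph.

    The fuzzy neighbor graph fed to the optimizer IS the augmented
    single-cell graph (it is not recomputed from features), and the
    initial coordinates place each cell at its cluster's layout position
    plus jitter, so the global arrangement of the embedding inherits the
    trajectory structure of the cluster graph.
    """
    from umap.umap_ import find_ab_params, simplicial_set_embedding

    init = initial_cell_positions(labels, cluster_layout, seed=seed,
                                  jitter=jitter)
    W = graph.weights.tocoo().astype(np.float32)
    mx = W.data.max() if W.nnz else 1.0
    W.data = W.data / mx            # fuzzy memberships expected in (0, 1]
    a, b = find_ab_params(1.0, min_dist)
    emb, _ = simplicial_set_embedding(
        data=None,
        graph=W.tocsr(),
        n_components=2,
        initial_alpha=1.0,
        a=a, b=b,
        gamma=1.0,
        negative_sample_rate=5,
        n_epochs=int(n_epochs),
        init=init,
        random_state=np.random.RandomState(seed),
        metric="euclidean",
        metric_kwds={},
        densmap=False,
        densmap_kwds={},
        output_dens=False,
    )
    return np.asarray(emb, dtype=np.float64)


def kmeans_milestones(cell_xy: np.ndarray, m: int, seed: int = 0,
                      knn: Optional[AugmentedGraph] = None):
    """Coarsen the embedding into m kmeans milestones.

    Returns ``(milestone_xy, members, edges)`` where ``edges`` aggregate
    the augmented single-cell edges between milestone member sets (empty
    when no single-cell graph is supplied).  The default milestone count
    used by the pipeline is ``min(max(150, n_cells // 100), 1000)``.
    """
    from sklearn.cluster import KMeans

    cell_xy = np.asarray(cell_xy, dtype=float)
    n = cell_xy.shape[0]
    if not (2 <= m <= n - 1):
        raise ValueError(f"m={m} must be in [2, n_cells-1]")
    km = KMeans(n_clusters=m, random_state=int(seed), n_init=4).fit(cell_xy)
    lab = km.labels_
    members = [np.flatnonzero(lab == i) for i in range(m)]
    milestone_xy = km.cluster_centers_.astype(float)
    edges = []
    if knn is not None:
        M = sp.csr_matrix((np.ones(n), (np.arange(n), lab)), shape=(n, m))
        A = (M.T @ knn.weights @ M).tocoo()
        for i, j, w in zip(A.row, A.col, A.data):
            if i < j and w > 0:
                edges.append((int(i), int(j), float(w)))
    return milestone_xy, members, edges


def epanechnikov(x: np.ndarray) -> np.ndarray:
    """Epanechnikov kernel K(x) = 1 - ||x||^2 inside the unit ball, 0 outside.

    ``x`` is a bandwidth-scaled 2-D offset (or an array of them, offsets
    on the last axis).
    """
    x = np.asarray(x, dtype=float)
    sq = (x ** 2).sum(axis=-1) if x.ndim > 0 and x.shape[-1:] == (2,) \
        else x ** 2
    return np.maximum(0.0, 1.0 - sq)


def bandwidth_schedule(config: BundleConfig, h_max: Optional[float] = None
                       ) -> np.ndarray:
    """The geometric bandwidth sequence h_n = lambda^n * h_max."""
    h0 = h_max if h_max is not None else config.h_max
    return h0 * config.lambda_decay ** np.arange(config.n_iterations)


def _kernel_footprint(h_cells: float) -> np.ndarray:
    """Epanechnikov kernel rasterized on an odd square grid of radius h."""
    r = max(int(np.ceil(h_cells)), 1)
    ax = np.arange(-r, r + 1)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    return np.maximum(0.0, 1.0 - (gx ** 2 + gy ** 2) / h_cells ** 2)


def bundle_edges(milestone_xy: np.ndarray, edges: Sequence,
                 config: Optional[BundleConfig] = None):
    """KDE edge bundling of the milestone graph.

    Each edge is discretized into ``n_advect`` points; each iteration
    (1) accumulates all polyline points into a raster density map and
    convolves it with the Epanechnikov kernel at the current bandwidth,
    (2) advects interior points along the density gradient by half a
    grid cell, and (3) applies Laplacian smoothing.  Bandwidths follow
    h_n = lambda^n * h_max exactly; endpoints are pinned to the original
    milestone coordinates throughout.

    Returns ``(polylines, density_map)`` where each polyline is a dict
    with keys u, v, weight, points.
    """
    config = config or BundleConfig()
    milestone_xy = np.asarray(milestone_xy, dtype=float)
    if len(edges) == 0:
        raise ValueError("no edges to bundle")

    lo = milestone_xy.min(axis=0)
    hi = milestone_xy.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    h_max = config.h_max if config.h_max > 0 else 0.1 * float(
        np.linalg.norm(span))
    # pad by the kernel bandwidth so no mass sits on the raster boundary
    pad = 0.05 * span.max() + h_max
    lo, hi = lo - pad, hi + pad
    G = config.grid_size
    cell = float(np.max(hi - lo) / G)
    if h_max <= cell:
        raise ValueError("h_max must exceed the grid resolution")

    polys = []
    for (u, v, w) in edges:
        pts = np.linspace(milestone_xy[int(u)], milestone_xy[int(v)],
                          config.n_advect)
        polys.append({"u": int(u), "v": int(v), "weight": float(w),
                      "points": pts})

    def _grid_coords(points):
        # fractional grid coordinates with cell centers on integers
        pos = (points - lo) / cell - 0.5
        i0 = np.clip(np.floor(pos).astype(int), 0, G - 2)
        frac = np.clip(pos - i0, 0.0, 1.0)
        return i0, frac

    def _splat(density, points, w):
        i0, f = _grid_coords(points)
        for di, dj, wt in ((0, 0, (1 - f[:, 0]) * (1 - f[:, 1])),
                           (1, 0, f[:, 0] * (1 - f[:, 1])),
                           (0, 1, (1 - f[:, 0]) * f[:, 1]),
                           (1, 1, f[:, 0] * f[:, 1])):
            np.add.at(density, (i0[:, 0] + di, i0[:, 1] + dj), w * wt)

    def _sample(field, points):
        i0, f = _grid_coords(points)
        return (field[i0[:, 0], i0[:, 1]] * (1 - f[:, 0]) * (1 - f[:, 1])
                + field[i0[:, 0] + 1, i0[:, 1]] * f[:, 0] * (1 - f[:, 1])
                + field[i0[:, 0], i0[:, 1] + 1] * (1 - f[:, 0]) * f[:, 1]
                + field[i0[:, 0] + 1, i0[:, 1] + 1] * f[:, 0] * f[:, 1])

    density = None
    for h in bandwidth_schedule(config, h_max):
        # 1) rasterize all polyline points (bilinear), optionally weighted
        density = np.zeros((G, G))
        for p in polys:
            w = p["weight"] if config.weighted_kernel else 1.0
            _splat(density, p["points"], w / config.n_advect)
        density = fftconvolve(density, _kernel_footprint(h / cell),
                              mode="same")
        gx, gy = np.gradient(density)
        # 2) advect interior points up the gradient, step bounded by grid
        for p in polys:
            pts = p["points"]
            g = np.stack([_sample(gx, pts[1:-1]), _sample(gy, pts[1:-1])],
                         axis=1)
            norm = np.linalg.norm(g, axis=1, keepdims=True)
            step = np.where(norm > 1e-12, g / np.maximum(norm, 1e-12), 0.0)
            pts[1:-1] = pts[1:-1] + config.advect_step * cell * step
            # 3) Laplacian filtering, endpoints fixed
            for _ in range(config.smoothing_passes):
                interior = pts[1:-1] + 0.5 * (pts[:-2] + pts[2:]
                                              - 2 * pts[1:-1])
                pts[1:-1] = interior
            p["points"] = pts
    # restore endpoints bit-exactly (they were never moved, but be explicit)
    for p in polys:
        p["points"][0] = milestone_xy[p["u"]]
        p["points"][-1] = milestone_xy[p["v"]]
    return polys, density


def compose_atlas_view(layout: AtlasLayout, milestone_pseudotime: np.ndarray,
                       velocity_transition: Optional[np.ndarray] = None,
                       velocity_weight: float = 0.5,
                       color: Optional[np.ndarray] = None,
                       out_path: Optional[str] = None) -> AtlasLayout:
    """Annotate bundled edges with direction and optionally render.

    Each bundled edge gets direction sign = sign of the pseudotime
    difference between its target and source milestones ("undirected"
    when equal).  When a milestone-level velocity transition is given
    and its net flow disagrees with the pseudotime sign while its
    weighted magnitude exceeds the pseudotime term, the velocity
    direction wins.  Rendering draws cells (colored by ``color``),
    bundled polylines and arrowheads.
    """
    if layout.bundled_edges is None:
        raise ValueError("bundle edges before composing the Atlas View")
    pt = np.asarray(milestone_pseudotime, dtype=float)
    pt_span = max(pt.max() - pt.min(), 1e-12)
    for e in layout.bundled_edges:
        u, v = e["u"], e["v"]
        dpt = (pt[v] - pt[u]) / pt_span
        sign = int(np.sign(dpt))
        if velocity_transition is not None:
            flow = velocity_transition[u, v] - velocity_transition[v, u]
            if (np.sign(flow) != 0 and np.sign(flow) != np.sign(dpt)
                    and velocity_weight * abs(flow)
                    > (1 - velocity_weight) * abs(dpt)):
                sign = int(np.sign(flow))
        e["direction"] = sign if sign != 0 else "undirected"
    if out_path is not None:
        _render_atlas(layout, color, out_path)
    return layout


def _render_atlas(layout: AtlasLayout, color, out_path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    xy = layout.cell_xy
    if color is not None and not np.issubdtype(np.asarray(color).dtype,
                                               np.number):
        cats, codes = np.unique(np.asarray(color), return_inverse=True)
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=codes, cmap="tab20", s=3,
                        alpha=0.6, linewidths=0)
    else:
        ax.scatter(xy[:, 0], xy[:, 1], c=color, cmap="viridis", s=3,
                   alpha=0.6, linewidths=0)
    wmax = max(e["weight"] for e in layout.bundled_edges)
    for e in layout.bundled_edges:
        pts = e["points"]
        lw = 0.3 + 2.5 * e["weight"] / wmax
        ax.plot(pts[:, 0], pts[:, 1], color="black", lw=lw, alpha=0.35)
        if e.get("direction") not in (None, "undirected"):
            k = len(pts) // 2
            p0, p1 = (pts[k], pts[k + 1]) if e["direction"] == 1 \
                else (pts[k + 1], pts[k])
            ax.annotate("", xy=p1, xytext=p0,
                        arrowprops=dict(arrowstyle="->", color="black",
                                        alpha=0.6))
    ax.set_axis_off()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
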