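"""Evaluation metrics for TI-compatible 2-D embeddings.

Five scores quantify how well a 2-D embedding supports trajectory
analysis.  Three structural metrics correlate the known ordinal time
label with (a) pseudotime inferred by re-running the trajectory engine
on the 2-D coordinates themselves, (b) geodesic distance from a root
cell on a KNN graph of the embedding, and (c) Euclidean distance from
the root.  Two cell-type metrics measure lineage/type separation: the
F1 of automatically detected cell fates against the expected fate set,
and the mean one-vs-all F1 of coarse annotations recovered by kmeans
clustering of the embedding (clusters majority-mapped to annotations
and aggregated, so splitting a type across clusters is not punished).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["MetricReport", "pearson_r", "metric_2d_pseudotime",
           "metric_geodesic", "metric_euclidean", "metric_cell_fate_f1",
           "metric_cell_type_f1", "evaluate_embedding", "radar_plot"]


@dataclass
class MetricReport:
    """The five embedding scores (correlations in [-1,1], F1 in [0,1])."""

    r_2d_pseudotime: float
    r_geodesic: float
    r_euclidean: float
    f1_cell_fate: float
    f1_cell_type: float

    def to_dict(self) -> dict:
        return asdict(self)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Standard Pearson correlation coefficient.

    ``r = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2))``.
    Zero-variance inputs are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = (xc ** 2).sum()
    sy = (yc ** 2).sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("zero-variance input")
    return float((xc * yc).sum() / np.sqrt(sx * sy))


def _run_ti_on_embedding(embedding: np.ndarray, root_cell: int, k: int,
                         seed: int, resolution: float = 1.0):
    """Run the trajectory engine with the 2-D coordinates as features.

    Returns (per-cell pseudotime, cluster graph, per-cell labels).
    """
    from .cluster import (LtrwParams, build_cluster_graph, cluster_cells,
                          detect_terminals, forward_bias, ltrw_pseudotime)
    from .graphs import GraphParams, build_knn_graph

    embedding = np.asarray(embedding, dtype=float)
    g = build_knn_graph(embedding, GraphParams(k=k))
    labels = cluster_cells(g, resolution=resolution, seed=seed)
    cg = build_cluster_graph(g, labels)
    _, coded = np.unique(labels, return_inverse=True)
    root_cluster = int(coded[root_cell])
    params = LtrwParams(seed=seed, n_mcmc=300)
    pt = ltrw_pseudotime(cg, root_cluster, params)
    cg = forward_bias(cg, pt, None, params)
    cg.root = root_cluster
    cg.terminals = detect_terminals(cg)
    return pt[coded], cg, coded


def metric_2d_pseudotime(embedding: np.ndarray, time_label: np.ndarray,
                         root_cell: int, k: int = 15, seed: int = 0) -> float:
    """Correlation of time labels with pseudotime inferred from the 2-D
    embedding itself (the embedding replaces the feature matrix)."""
    cell_pt, _, _ = _run_ti_on_embedding(embedding, root_cell, k, seed)
    return pearson_r(np.asarray(time_label, dtype=float), cell_pt)


def metric_geodesic(embedding: np.ndarray, time_label: np.ndarray,
                    root_cell: int, k: int = 15) -> float:
    """Correlation of time labels with graph-geodesic distance from the
    root cell on a Euclidean KNN graph of the embedding.

    Unreachable cells are excluded (warning when more than 5%).
    """
    from sklearn.neighbors import kneighbors_graph

    embedding = np.asarray(embedding, dtype=float)
    A = kneighbors_graph(embedding, k, mode="distance")
    A = A.maximum(A.T)
    d = sp.csgraph.dijkstra(A, directed=False, indices=root_cell)
    reach = np.isfinite(d)
    frac_un = 1.0 - reach.mean()
    if frac_un > 0:
        warnings.warn(f"{frac_un:.1%} of cells unreachable from the root; "
                      "computing on the reachable set", stacklevel=2)
    return pearson_r(np.asarray(time_label, dtype=float)[reach], d[reach])


def metric_euclidean(embedding: np.ndarray, time_label: np.ndarray,
                     root_cell: int) -> float:
    """Correlation of time labels with Euclidean distance from the root
    cell in the embedding."""
    embedding = np.asarray(embedding, dtype=float)
    d = np.linalg.norm(embedding - embedding[root_cell], axis=1)
    return pearson_r(np.asarray(time_label, dtype=float), d)


def _set_f1(detected: set, expected: set) -> float:
    if not detected or not expected:
        return 0.0
    tp = len(detected & expected)
    if tp == 0:
        return 0.0
    precision = tp / len(detected)
    recall = tp / len(expected)
    return 2 * precision * recall / (precision + recall)


def metric_cell_fate_f1(embedding: np.ndarray, time_label: np.ndarray,
                        root_cell: int, annotations: np.ndarray,
                        expected_fates: Sequence, k: int = 15,
                        seed: int = 0) -> float:
    """F1 of automatically detected cell fates on the 2-D embedding.

    The trajectory engine runs on the embedding (same root for every
    embedding under comparison); each detected terminal cluster maps to
    its majority annotation, and the detected annotation set is scored
    against ``expected_fates``.
    """
    annotations = np.asarray(annotations)
    _, cg, coded = _run_ti_on_embedding(embedding, root_cell, k, seed)
    detected = set()
    for t in cg.terminals:
        member_ann = annotations[coded == t]
        vals, counts = np.unique(member_ann, return_counts=True)
        detected.add(vals[np.argmax(counts)])
    return _set_f1(detected, set(expected_fates))


def metric_cell_type_f1(embedding: np.ndarray, annotations: np.ndarray,
                        seed: int = 0, extra_clusters: int = 5) -> float:
    """Mean one-vs-all F1 of coarse annotations under kmeans clustering.

    kmeans with k = (number of annotation levels + 5) clusters the
    embedding; each cluster is assigned its majority annotation and
    clusters of the same majority are aggregated before computing each
    annotation's one-vs-all F1.  The unweighted mean over annotations is
    returned; an annotation that is no cluster's majority scores 0.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import f1_score

    embedding = np.asarray(embedding, dtype=float)
    annotations = np.asarray(annotations)
    levels = np.unique(annotations)
    k = len(levels) + extra_clusters
    if k >= len(annotations):
        raise ValueError("k must be < n_cells")
    lab = KMeans(n_clusters=k, random_state=int(seed),
                 n_init=4).fit_predict(embedding)
    majority = {}
    for c in range(k):
        vals, counts = np.unique(annotations[lab == c], return_counts=True)
        majority[c] = vals[np.argmax(counts)]
    predicted = np.array([majority[c] for c in lab])
    scores = []
    for lv in levels:
        if lv not in majority.values():
            scores.append(0.0)
            continue
        scores.append(f1_score(annotations == lv, predicted == lv))
    return float(np.mean(scores))


def evaluate_embedding(embedding: np.ndarray, time_label: np.ndarray,
                       root_cell: int, annotations: np.ndarray,
                       expected_fates: Sequence, k: int = 15,
                       seed: int = 0) -> MetricReport:
    """Compute all five embedding metrics."""
    return MetricReport(
        r_2d_pseudotime=metric_2d_pseudotime(embedding, time_label,
                                             root_cell, k=k, seed=seed),
        r_geodesic=metric_geodesic(embedding, time_label, root_cell, k=k),
        r_euclidean=metric_euclidean(embedding, time_label, root_cell),
        f1_cell_fate=metric_cell_fate_f1(embedding, time_label, root_cell,
                                         annotations, expected_fates, k=k,
                                         seed=seed),
        f1_cell_type=metric_cell_type_f1(embedding, annotations, seed=seed),
    )


def radar_plot(report: MetricReport, out_path: str, title: str = "") -> None:
    """Radar chart of the five metrics (correlations clipped at 0)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    d = report.to_dict()
    names = list(d)
    vals = [max(0.0, d[n]) for n in names]
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    vals_c = vals + vals[:1]
    ang_c = np.concatenate([angles, angles[:1]])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(5, 5))
    ax.plot(ang_c, vals_c, "o-")
    ax.fill(ang_c, vals_c, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=8)
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
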