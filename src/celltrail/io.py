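"""Readers and writers for cell tables, graphs and results.

Cell tables round-trip through two dialects: an h5ad single-cell
container (expression in X, time/annotation as per-cell columns,
spatial coordinates in ``obsm["spatial"]``, velocity as a layer) and a
plain CSV directory (``expression.csv``, ``obs.csv`` and optionally
``velocity.csv``).  Graphs serialize to edge-list CSV (with provenance)
or MTX; cluster graphs to JSON.
"""

from __future__ import annotations

import json
import os
from typing import Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (PROV_NAMES, AugmentedGraph, CellTable, ClusterGraph)

__all__ = ["read_cell_table", "write_cell_table", "write_graph_csv",
           "read_graph_csv", "write_graph_mtx", "write_cluster_graph_json",
           "read_cluster_graph_json"]

_PROV_CODES = {v: k for k, v in PROV_NAMES.items()}


def _to_anndata(table: CellTable):
    import anndata as ad

    obs = pd.DataFrame(index=[f"cell_{i}" for i in range(table.n_cells)])
    if table.time_label is not None:
        obs["time_label"] = pd.Categorical(table.time_label)
    if table.annotation is not None:
        obs["annotation"] = pd.Categorical(table.annotation)
    if table.truth_branch is not None:
        obs["truth_branch"] = pd.Categorical(table.truth_branch)
    if table.truth_time is not None:
        obs["truth_time"] = table.truth_time
    adata = ad.AnnData(X=table.expression.copy(), obs=obs)
    if table.spatial_xy is not None:
        adata.obsm["spatial"] = table.spatial_xy.copy()
    if table.velocity is not None:
        adata.layers["velocity"] = table.velocity.copy()
    return adata


def _from_anndata(adata) -> CellTable:
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    def _col(name, as_int=False):
        if name not in adata.obs:
            return None
        v = np.asarray(adata.obs[name])
        return v.astype(np.int64) if as_int else v
    vel = None
    if "velocity" in adata.layers:
        vel = np.asarray(adata.layers["velocity"])
        if vel.shape != X.shape:
            raise ValueError("velocity layer shape does not match X")
    return CellTable(
        expression=X.astype(np.float64),
        time_label=_col("time_label", as_int=True),
        annotation=_col("annotation"),
        truth_branch=_col("truth_branch"),
        truth_time=(np.asarray(adata.obs["truth_time"], dtype=float)
                    if "truth_time" in adata.obs else None),
        spatial_xy=(np.asarray(adata.obsm["spatial"], dtype=float)
                    if "spatial" in adata.obsm else None),
        velocity=vel,
    )


def write_cell_table(table: CellTable, path: Union[str, os.PathLike]) -> None:
    """Write a CellTable to ``.h5ad`` or a CSV directory (by extension)."""
    path = str(path)
    if path.endswith(".h5ad"):
        _to_anndata(table).write_h5ad(path)
        return
    os.makedirs(path, exist_ok=True)
    np.savetxt(os.path.join(path, "expression.csv"), table.expression,
               delimiter=",")
    obs = pd.DataFrame(index=range(table.n_cells))
    for name in ("time_label", "annotation", "truth_branch", "truth_time"):
        v = getattr(table, name)
        if v is not None:
            obs[name] = v
    if table.spatial_xy is not None:
        obs["spatial_x"] = table.spatial_xy[:, 0]
        obs["spatial_y"] = table.spatial_xy[:, 1]
    obs.to_csv(os.path.join(path, "obs.csv"), index=False)
    if table.velocity is not None:
        np.savetxt(os.path.join(path, "velocity.csv"), table.velocity,
                   delimiter=",")


def read_cell_table(path: Union[str, os.PathLike]) -> CellTable:
    """Read a CellTable from ``.h5ad`` or a CSV directory."""
    path = str(path)
    if path.endswith(".h5ad"):
        import anndata as ad
        return _from_anndata(ad.read_h5ad(path))
    if not os.path.isdir(path):
        raise FileNotFoundError(f"no such container: {path}")
    X = np.loadtxt(os.path.join(path, "expression.csv"), delimiter=",",
                   ndmin=2)
    obs_path = os.path.join(path, "obs.csv")
    kw = {}
    if os.path.exists(obs_path):
        obs = pd.read_csv(obs_path)
        if "time_label" in obs:
            kw["time_label"] = obs["time_label"].to_numpy(dtype=np.int64)
        if "annotation" in obs:
            kw["annotation"] = obs["annotation"].to_numpy()
        if "truth_branch" in obs:
            kw["truth_branch"] = obs["truth_branch"].to_numpy()
        if "truth_time" in obs:
            kw["truth_time"] = obs["truth_time"].to_numpy(dtype=float)
        if "spatial_x" in obs:
            kw["spatial_xy"] = obs[["spatial_x", "spatial_y"]].to_numpy()
    vel_path = os.path.join(path, "velocity.csv")
    if os.path.exists(vel_path):
        vel = np.loadtxt(vel_path, delimiter=",", ndmin=2)
        if vel.shape != X.shape:
            raise ValueError("velocity.csv shape does not match "
                             "expression.csv")
        kw["velocity"] = vel
    return CellTable(expression=X, **kw)


def write_graph_csv(graph: AugmentedGraph, path: str) -> None:
    graph.edge_dataframe().to_csv(path, index=False)


def read_graph_csv(path: str, n_cells: int, k: int = 0) -> AugmentedGraph:
    df = pd.read_csv(path)
    u = df["u"].to_numpy()
    v = df["v"].to_numpy()
    w = df["weight"].to_numpy(dtype=float)
    p = np.array([_PROV_CODES[s] for s in df["provenance"]], dtype=np.uint8)
    W = sp.csr_matrix((np.r_[w, w], (np.r_[u, v], np.r_[v, u])),
                      shape=(n_cells, n_cells))
    P = sp.csr_matrix((np.r_[p, p], (np.r_[u, v], np.r_[v, u])),
                      shape=(n_cells, n_cells))
    return AugmentedGraph(weights=W, provenance=P, k=k)


def write_graph_mtx(graph: AugmentedGraph, path: str) -> None:
    from scipy.io import mmwrite
    mmwrite(path, graph.weights)


def write_cluster_graph_json(cg: ClusterGraph, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(cg.to_json_dict(), fh, indent=1)


def read_cluster_graph_json(path: str) -> ClusterGraph:
    with open(path) as fh:
        return ClusterGraph.from_json_dict(json.load(fh))
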