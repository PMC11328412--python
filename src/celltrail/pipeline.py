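"""End-to-end orchestration: graph -> clusters -> pseudotime -> walks ->
atlas -> metrics, with every stage's outputs written to a run directory."""

from __future__ import annotations

import json
import logging
import os
from datetime import datetime, timezone
from typing import Optional

import numpy as np
import pandas as pd

from . import cartography, cluster, graphs, io, metrics, walks
from .config import RunConfig
from .containers import AtlasLayout, CellTable

__all__ = ["run_pipeline"]

logger = logging.getLogger("celltrail")


def _log(log_lines, stage: str, msg: str) -> None:
    line = f"{datetime.now(timezone.utc).isoformat()} [{stage}] {msg}"
    log_lines.append(line)
    logger.info(line)


def run_pipeline(table: CellTable, config: RunConfig, out_dir: str,
                 make_figure: bool = True) -> dict:
    """Run the full trajectory-and-cartography pipeline.

    Writes ``cluster_graph.json``, ``pseudotime.csv``, ``lineages.csv``,
    ``atlas.png``, ``report.json`` and ``run.log`` into ``out_dir`` and
    returns the in-memory results.  Deterministic for a fixed config
    seed.  Preconditions are checked fail-fast with the stage name in
    the error.
    """
    os.makedirs(out_dir, exist_ok=True)
    log_lines: list = []
    res: dict = {}

    # --- stage 1: single-cell graph ------------------------------------
    stage = "graph"
    feats = table.expression
    if table.spatial_xy is not None:
        feats = graphs.smooth_expression_spatial(feats, table.spatial_xy,
                                                 config.graph)
        _log(log_lines, stage, "spatially smoothed expression "
             f"(self_weight={config.graph.self_weight})")
    g = graphs.build_knn_graph(feats, config.graph)
    _log(log_lines, stage, f"scKNN graph: {g.n_cells} cells, "
         f"{g.n_edges} edges (k={config.graph.k})")
    if table.time_label is not None and \
            len(np.unique(table.time_label)) > 1:
        g = graphs.augment_sequential(g, table.time_label, feats,
                                      config.graph)
        _log(log_lines, stage, f"sequential augmentation -> {g.n_edges} edges")
    if table.spatial_xy is not None:
        g = graphs.augment_spatial(g, table.spatial_xy, config.graph)
        _log(log_lines, stage, f"spatial augmentation -> {g.n_edges} edges")
    res["graph"] = g

    # --- stage 2: clusters, pseudotime, forward bias --------------------
    stage = "cluster_ti"
    labels = cluster.cluster_cells(g, resolution=config.resolution,
                                   seed=config.seed)
    _, coded = np.unique(labels, return_inverse=True)
    cg = cluster.build_cluster_graph(g, labels)
    _log(log_lines, stage, f"{cg.n_nodes} clusters")
    vt = None
    if table.velocity is not None:
        vt = cluster.velocity_transition_matrix(cg, table.expression,
                                                table.velocity, labels)
    root = config.root
    if root is None:
        if vt is not None:
            root = cluster.detect_root(cg, vt)
            _log(log_lines, stage, f"root detected from velocity: {root}")
        elif table.time_label is not None:
            means = [table.time_label[coded == i].mean()
                     for i in range(cg.n_nodes)]
            root = int(np.argmin(means))
            _log(log_lines, stage, f"root from earliest time labels: {root}")
        else:
            raise ValueError("[cluster_ti] no root: supply config.root or "
                             "velocity/time information")
    pt_nodes = cluster.ltrw_pseudotime(cg, root, config.ltrw)
    cg = cluster.forward_bias(cg, pt_nodes, vt, config.ltrw)
    cg.root = root
    cg.terminals = cluster.detect_terminals(cg)
    _log(log_lines, stage, f"terminals: {cg.terminals}")
    res.update(labels=labels, cluster_graph=cg, root=root)
    cell_pt = pt_nodes[coded]
    res["pseudotime"] = cell_pt

    # --- stage 3: lineage walks -----------------------------------------
    stage = "memory_walks"
    ens = walks.simulate_walks(cg, root, config.walk)
    field = walks.lineage_probabilities(ens, cg, labels=labels, knn=g)
    _log(log_lines, stage, f"{config.walk.n_walks} walks (memory="
         f"{config.walk.memory}); hit rate "
         f"{float(np.mean(ens.terminal_hit >= 0)):.2f}")
    res.update(ensemble=ens, lineage_field=field)

    # --- stage 4-6: cartography -----------------------------------------
    stage = "cartography"
    spatial_init = None
    if table.spatial_xy is not None:
        spatial_init = np.stack([table.spatial_xy[coded == i].mean(axis=0)
                                 for i in range(cg.n_nodes)])
    cl_layout = cartography.layout_cluster_graph(cg, seed=config.seed,
                                                 spatial_init=spatial_init)
    emb = cartography.embed_single_cells(g, labels, cl_layout,
                                         seed=config.seed,
                                         n_epochs=config.embed_epochs)
    m = config.milestones_for(table.n_cells)
    mil_xy, mil_members, mil_edges = cartography.kmeans_milestones(
        emb, m, seed=config.seed, knn=g)
    _log(log_lines, stage, f"{m} milestones, {len(mil_edges)} edges")
    polys, density = cartography.bundle_edges(mil_xy, mil_edges,
                                              config.bundle)
    layout = AtlasLayout(cell_xy=emb, milestone_xy=mil_xy,
                         milestone_members=mil_members,
                         milestone_edges=mil_edges, bundled_edges=polys,
                         density_map=density)
    mil_pt = np.array([cell_pt[mm].mean() if len(mm) else 0.0
                       for mm in mil_members])
    fig_path = os.path.join(out_dir, "atlas.png") if make_figure else None
    layout = cartography.compose_atlas_view(layout, mil_pt,
                                            color=cell_pt,
                                            out_path=fig_path)
    res["atlas"] = layout

    # --- metrics ---------------------------------------------------------
    report = None
    if table.time_label is not None and table.annotation is not None:
        stage = "metrics"
        root_cell = int(np.flatnonzero(coded == root)[0])
        tips = _expected_fates(table, cg, coded)
        report = metrics.evaluate_embedding(
            emb, table.time_label, root_cell, table.annotation, tips,
            k=config.graph.k, seed=config.seed)
        _log(log_lines, stage, f"metrics: {report.to_dict()}")
        res["report"] = report

    # --- outputs ---------------------------------------------------------
    io.write_cluster_graph_json(cg, os.path.join(out_dir,
                                                 "cluster_graph.json"))
    pd.DataFrame({"cell": np.arange(table.n_cells), "cluster": coded,
                  "pseudotime": cell_pt}).to_csv(
        os.path.join(out_dir, "pseudotime.csv"), index=False)
    lin = pd.DataFrame({"cell": np.arange(table.n_cells)})
    for t in field.fates:
        lin[f"fate_{t}"] = field.cell_probs.get(
            t, field.cluster_probs[t][coded])
    lin.to_csv(os.path.join(out_dir, "lineages.csv"), index=False)
    if report is not None:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return res


def _expected_fates(table: CellTable, cg, coded) -> list:
    """Majority annotations of the detected terminal clusters (used as the
    expected-fate reference when the caller does not supply one)."""
    ann = np.asarray(table.annotation)
    fates = []
    for t in cg.terminals:
        vals, counts = np.unique(ann[coded == t], return_counts=True)
        fates.append(vals[np.argmax(counts)])
    return sorted(set(fates))
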