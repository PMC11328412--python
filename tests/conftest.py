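"""Shared fixtures: small synthetic atlases and toy cluster graphs."""

import numpy as np
import pytest

import celltrail as ct
from celltrail import cluster as cl


@pytest.fixture(scope="session")
def y_atlas_small():
    """A 900-cell Y atlas (trunk + two arms) with velocity, fixed seed."""
    topo = ct.TrajectoryTopology.y()
    table = ct.generate_branching_atlas(topo, n_cells=900, n_timepoints=5,
                                        seed=11, with_velocity=True)
    return topo, table


@pytest.fixture(scope="session")
def tri_atlas_ti():
    """Frozen trifurcation atlas with the full TI pipeline applied.

    3000 cells, 5 time points, defaults; returns a dict with the graph,
    labels, forward-biased cluster graph, root and per-cluster
    branch-majority map.
    """
    topo = ct.TrajectoryTopology.trifurcation()
    table = ct.generate_branching_atlas(topo, n_cells=3000, n_timepoints=5,
                                        seed=7, with_velocity=True)
    gp = ct.GraphParams()
    g = ct.build_knn_graph(table.expression, gp)
    g = ct.augment_sequential(g, table.time_label, table.expression, gp)
    labels = ct.cluster_cells(g, resolution=1.0, seed=7)
    cg = ct.build_cluster_graph(g, labels)
    _, coded = np.unique(labels, return_inverse=True)
    vt = cl.velocity_transition_matrix(cg, table.expression, table.velocity,
                                       labels)
    root = cl.detect_root(cg, vt)
    params = cl.LtrwParams(seed=7)
    pt = cl.ltrw_pseudotime(cg, root, params)
    cg = cl.forward_bias(cg, pt, vt, params)
    cg.root = root
    cg.terminals = cl.detect_terminals(cg)
    majority = {}
    for i in range(cg.n_nodes):
        vals, counts = np.unique(table.truth_branch[coded == i],
                                 return_counts=True)
        majority[i] = vals[np.argmax(counts)]
    return {"topology": topo, "table": table, "graph": g, "labels": labels,
            "coded": coded, "cg": cg, "root": root, "majority": majority}


@pytest.fixture
def chain_graph():
    """Toy chain a - b - c with unit weights."""
    return ct.generate_toy_cluster_graph(
        ["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)], root="a")


@pytest.fixture
def directed_chain(chain_graph):
    """Chain forward-biased hard left-to-right; terminal = c."""
    cg = chain_graph
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 2] = 1.0
    cg.directed_W = D
    cg.pseudotime = np.array([0.0, 0.5, 1.0])
    cg.root = 0
    cg.terminals = [2]
    return cg


def random_toy_graph(rng, n_nodes, extra_edges=2):
    """Random connected weighted toy graph built from a spanning tree."""
    nodes = list(range(n_nodes))
    edges = []
    seen = set()
    for v in range(1, n_nodes):
        u = int(rng.integers(0, v))
        edges.append((u, v, float(rng.uniform(0.5, 3.0))))
        seen.add((u, v))
    for _ in range(extra_edges):
        u, v = sorted(rng.choice(n_nodes, size=2, replace=False).tolist())
        if (u, v) not in seen:
            seen.add((u, v))
            edges.append((u, v, float(rng.uniform(0.5, 3.0))))
    return ct.generate_toy_cluster_graph(nodes, edges, root=0)


def bias_toy_graph(cg, rng=None, seed=0):
    """Give a toy graph pseudotime (graph distance from root) and a
    forward bias; terminals detected by the standard rule."""
    import scipy.sparse as sp

    rng = rng or np.random.default_rng(seed)
    d = sp.csgraph.dijkstra(sp.csr_matrix((cg.W > 0).astype(float)),
                            indices=cg.root, unweighted=True)
    pt = d / max(d.max(), 1.0)
    params = cl.LtrwParams(velocity_weight=0.0)
    cg = cl.forward_bias(cg, pt, None, params)
    cg.root = 0
    cg.terminals = cl.detect_terminals(cg)
    return cg
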