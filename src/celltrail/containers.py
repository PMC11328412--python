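"""Core in-memory containers shared across the pipeline.

The pipeline moves through three representations of the data:

``CellTable``
    the per-cell input — an expression (or feature) matrix plus optional
    time labels, spatial coordinates, annotations, velocity vectors and,
    for simulated data, the generating ground truth.
``AugmentedGraph``
    the weighted single-cell KNN graph, possibly augmented with
    sequential (temporal) and spatial edges; every edge remembers which
    layer created it.
``ClusterGraph``
    the coarse graph over cell clusters on which pseudotime, forward
    biasing and the memory-biased walks operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

# provenance codes for AugmentedGraph edges
PROV_EXPRESSION = 1
PROV_SEQUENTIAL = 2
PROV_SPATIAL = 3

PROV_NAMES = {PROV_EXPRESSION: "expression",
              PROV_SEQUENTIAL: "sequential",
              PROV_SPATIAL: "spatial"}


@dataclass
class CellTable:
    """Per-cell data bundle.

    Parameters
    ----------
    expression
        ``(n_cells, n_features)`` dense float matrix; no missing values.
    time_label
        Optional ordinal integer per cell (experimental time point).
        Levels must form a contiguous integer sequence.
    spatial_xy
        Optional ``(n_cells, 2)`` tissue coordinates.
    annotation
        Optional categorical label per cell (e.g. cell type).
    velocity
        Optional matrix of per-cell velocity vectors, same shape as
        ``expression``.
    truth_branch, truth_time
        Generating ground truth for synthetic data: branch membership and
        latent pseudotime in [0, 1].
    """

    expression: np.ndarray
    time_label: Optional[np.ndarray] = None
    spatial_xy: Optional[np.ndarray] = None
    annotation: Optional[np.ndarray] = None
    velocity: Optional[np.ndarray] = None
    truth_branch: Optional[np.ndarray] = None
    truth_time: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=np.float64)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D matrix")
        if not np.isfinite(self.expression).all():
            raise ValueError("expression contains missing/non-finite values")
        n = self.n_cells
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=np.float64)
            if self.velocity.shape != self.expression.shape:
                raise ValueError(
                    f"velocity shape {self.velocity.shape} does not match "
                    f"expression shape {self.expression.shape}")
        if self.time_label is not None:
            self.time_label = np.asarray(self.time_label, dtype=np.int64)
            if self.time_label.shape != (n,):
                raise ValueError("time_label must have one entry per cell")
            levels = np.unique(self.time_label)
            if not np.array_equal(levels, np.arange(levels.min(),
                                                    levels.max() + 1)):
                raise ValueError("time_label levels must be contiguous")
        if self.spatial_xy is not None:
            self.spatial_xy = np.asarray(self.spatial_xy, dtype=np.float64)
            if self.spatial_xy.shape[0] != n:
                raise ValueError("spatial_xy must have one row per cell")
        for attr in ("annotation", "truth_branch", "truth_time"):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ValueError(f"{attr} must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_features(self) -> int:
        return self.expression.shape[1]


@dataclass
class AugmentedGraph:
    """Symmetric weighted single-cell graph with per-edge provenance.

    ``weights`` is a symmetric CSR matrix with zero diagonal;
    ``provenance`` stores on the same sparsity pattern which layer
    (expression / sequential / spatial) first created each edge. When an
    edge is re-created by a later layer the maximum weight is kept and
    the original provenance retained.
    """

    weights: sp.csr_matrix
    provenance: sp.csr_matrix
    k: int

    def __post_init__(self) -> None:
        self.weights = sp.csr_matrix(self.weights)
        self.provenance = sp.csr_matrix(self.provenance)
        if self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be square")
        if (self.weights.diagonal() != 0).any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return self.weights.nnz // 2

    def is_symmetric(self, tol: float = 0.0) -> bool:
        diff = self.weights - self.weights.T
        return abs(diff).max() <= tol if diff.nnz else True

    def edge_dataframe(self):
        """Edges as a (u, v, weight, provenance) DataFrame, u < v."""
        import pandas as pd
        coo = sp.triu(self.weights, k=1).tocoo()
        prov = self.provenance.tocsr()
        names = [PROV_NAMES[int(prov[u, v])] for u, v in zip(coo.row, coo.col)]
        return pd.DataFrame({"u": coo.row, "v": coo.col,
                             "weight": coo.data, "provenance": names})


@dataclass
class ClusterGraph:
    """Weighted graph over cell clusters.

    ``W`` is the symmetric non-negative weight matrix aggregated from
    single-cell edges.  After trajectory inference the graph also
    carries ``directed_W`` (forward-biased directed weights),
    per-node ``pseudotime``, a ``root`` node and a ``terminals`` set.
    Node ids are integers ``0..n_nodes-1``; ``names`` keeps the original
    labels for toy graphs built from named nodes.
    """

    W: np.ndarray
    members: Optional[list] = None          # per-node array of cell indices
    names: Optional[list] = None            # original node labels
    directed_W: Optional[np.ndarray] = None
    pseudotime: Optional[np.ndarray] = None
    root: Optional[int] = None
    terminals: Optional[list] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if (self.W < 0).any():
            raise ValueError("W must be non-negative")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if (np.diag(self.W) != 0).any():
            raise ValueError("W must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Undirected neighborhood N_v of node i (nodes with w_ij > 0)."""
        return np.flatnonzero(self.W[i] > 0)

    def out_neighbors(self, i: int) -> np.ndarray:
        if self.directed_W is None:
            raise ValueError("directed_W not computed; run forward_bias first")
        return np.flatnonzero(self.directed_W[i] > 0)

    def index_of(self, name) -> int:
        if self.names is None:
            return int(name)
        return self.names.index(name)

    def to_json_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "W": self.W.tolist(),
            "names": ([n.item() if isinstance(n, np.generic) else n
                       for n in self.names]
                      if self.names is not None else None),
            "member_counts": ([len(m) for m in self.members]
                              if self.members is not None else None),
            "directed_W": (self.directed_W.tolist()
                           if self.directed_W is not None else None),
            "pseudotime": (self.pseudotime.tolist()
                           if self.pseudotime is not None else None),
            "root": None if self.root is None else int(self.root),
            "terminals": (None if self.terminals is None
                          else [int(t) for t in self.terminals]),
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "ClusterGraph":
        cg = cls(W=np.asarray(d["W"], dtype=float), names=d.get("names"))
        if d.get("directed_W") is not None:
            cg.directed_W = np.asarray(d["directed_W"], dtype=float)
        if d.get("pseudotime") is not None:
            cg.pseudotime = np.asarray(d["pseudotime"], dtype=float)
        cg.root = d.get("root")
        cg.terminals = d.get("terminals")
        return cg


@dataclass
class WalkEnsemble:
    """A collection of simulated walks from the root of a cluster graph.

    ``walks`` are node-id sequences all starting at the root;
    ``terminal_hit[w]`` is the terminal the w-th walk was absorbed at
    (or -1 if it timed out); ``visitation[t][v]`` is the fraction of
    walks absorbed at terminal t that visited node v at least once.
    """

    walks: list
    terminal_hit: np.ndarray
    visitation: dict        # terminal id -> np.ndarray over nodes
    root: int

    @property
    def n_walks(self) -> int:
        return len(self.walks)

    def hit_fraction(self, terminal: int) -> float:
        return float(np.mean(self.terminal_hit == terminal))


@dataclass
class AtlasLayout:
    """2-D cartography bundle: cells, milestones and bundled edges."""

    cell_xy: np.ndarray
    milestone_xy: Optional[np.ndarray] = None
    milestone_members: Optional[list] = None
    milestone_edges: Optional[list] = None   # (u, v, weight)
    bundled_edges: Optional[list] = None     # dicts: u, v, weight, points, direction
    density_map: Optional[np.ndarray] = None
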