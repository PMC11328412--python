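"""Synthetic branching atlases with known ground truth.

The generator emulates the structure of time-resolved developmental
atlases: cells lie along a rooted tree of branches in feature space,
sampled with Gaussian noise, carry ordinal time-point labels derived
from their latent pseudotime, and can optionally carry velocity vectors
tangent to the latent trajectory and branch-correlated spatial zones.
Because branch membership and latent time are known exactly, every
downstream stage (clustering, pseudotime, fate detection, lineage
walks, metrics) can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import CellTable, ClusterGraph

__all__ = [
    "TrajectoryTopology",
    "generate_branching_atlas",
    "generate_toy_cluster_graph",
    "centroid_path_point",
    "centroid_path_tangent",
]


@dataclass
class TrajectoryTopology:
    """A rooted tree of branches defining the latent trajectory.

    ``parent`` maps each branch id to its parent branch (the root maps
    to ``None``).  ``branch_lengths`` are in latent-time units;
    ``n_features`` is the total feature dimension, of which the last
    ``markers_per_branch * n_branches`` columns are reserved for
    branch-specific marker features that ramp up linearly along their
    branch only.
    """

    parent: Dict[str, Optional[str]]
    branch_lengths: Dict[str, float]
    n_features: int = 20
    markers_per_branch: int = 1

    def __post_init__(self) -> None:
        if not self.parent:
            raise ValueError("topology has no branches")
        roots = [b for b, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("topology must have exactly one root branch")
        for b, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"parent {p!r} of branch {b!r} unknown")
        # check acyclicity / connectivity by walking up from every branch
        for b in self.parent:
            seen = set()
            cur: Optional[str] = b
            while cur is not None:
                if cur in seen:
                    raise ValueError("branch tree contains a cycle")
                seen.add(cur)
                cur = self.parent[cur]
        for b, L in self.branch_lengths.items():
            if L <= 0:
                raise ValueError(f"branch length of {b!r} must be > 0")
        if set(self.branch_lengths) != set(self.parent):
            raise ValueError("branch_lengths keys must match branches")
        if self.markers_per_branch < 0:
            raise ValueError("markers_per_branch must be >= 0")
        n_marker_cols = self.markers_per_branch * self.n_branches
        if self.n_features <= n_marker_cols:
            raise ValueError("n_features must exceed total marker columns")

    @property
    def branches(self) -> List[str]:
        """Branches in a stable depth-first order starting at the root."""
        children: Dict[Optional[str], List[str]] = {}
        for b, p in sorted(self.parent.items()):
            children.setdefault(p, []).append(b)
        order: List[str] = []
        stack = list(reversed(children.get(None, [])))
        while stack:
            b = stack.pop()
            order.append(b)
            stack.extend(reversed(children.get(b, [])))
        return order

    @property
    def root_branch(self) -> str:
        return next(b for b, p in self.parent.items() if p is None)

    @property
    def n_branches(self) -> int:
        return len(self.parent)

    def depth_offset(self, branch: str) -> float:
        """Latent-time distance from the root to the start of ``branch``."""
        d = 0.0
        p = self.parent[branch]
        while p is not None:
            d += self.branch_lengths[p]
            p = self.parent[p]
        return d

    def tips(self) -> List[str]:
        parents = {p for p in self.parent.values() if p is not None}
        return [b for b in self.branches if b not in parents]

    def marker_columns(self, branch: str) -> np.ndarray:
        """Feature columns reserved as markers of ``branch``."""
        i = self.branches.index(branch)
        m = self.markers_per_branch
        start = self.n_features - m * self.n_branches + i * m
        return np.arange(start, start + m)

    # -- common topologies ------------------------------------------------

    @classmethod
    def linear(cls, length: float = 1.0, **kw) -> "TrajectoryTopology":
        return cls(parent={"root": None}, branch_lengths={"root": length}, **kw)

    @classmethod
    def y(cls, trunk: float = 1.0, arm: float = 1.0, **kw) -> "TrajectoryTopology":
        """Three-branch 'Y': a trunk splitting into two arms."""
        return cls(parent={"trunk": None, "arm1": "trunk", "arm2": "trunk"},
                   branch_lengths={"trunk": trunk, "arm1": arm, "arm2": arm},
                   **kw)

    @classmethod
    def trifurcation(cls, trunk: float = 0.6, arm: float = 1.0,
                     **kw) -> "TrajectoryTopology":
        """A trunk splitting into three arms (three terminal fates)."""
        return cls(parent={"trunk": None, "arm1": "trunk", "arm2": "trunk",
                           "arm3": "trunk"},
                   branch_lengths={"trunk": trunk, "arm1": arm, "arm2": arm,
                                   "arm3": arm}, **kw)


def _branch_geometry(topology: TrajectoryTopology, rng: np.random.Generator,
                     marker_amplitude: float):
    """Start point and unit direction per branch in the geometry subspace.

    Directions are Gram-Schmidt orthogonalized Gaussian draws so sibling
    branches separate cleanly as noise shrinks.  Marker columns are held
    at zero in the geometry; the marker ramp is added on top.
    """
    n_feat = topology.n_features
    n_geom = n_feat - topology.markers_per_branch * topology.n_branches
    starts: Dict[str, np.ndarray] = {}
    dirs: Dict[str, np.ndarray] = {}
    used: List[np.ndarray] = []
    for b in topology.branches:
        g = rng.standard_normal(n_geom)
        for u in used:
            g -= (g @ u) * u
        norm = np.linalg.norm(g)
        if norm < 1e-9:            # dimension exhausted; fall back to raw draw
            g = rng.standard_normal(n_geom)
            norm = np.linalg.norm(g)
        g /= norm
        used.append(g)
        d = np.zeros(n_feat)
        d[:n_geom] = g
        p = topology.parent[b]
        if p is None:
            starts[b] = np.zeros(n_feat)
        else:
            starts[b] = starts[p] + dirs[p] * topology.branch_lengths[p]
        dirs[b] = d
    return starts, dirs


def centroid_path_point(topology: TrajectoryTopology, starts, dirs, branch: str,
                        s: float, marker_amplitude: float) -> np.ndarray:
    """Noise-free centroid position at arclength ``s`` along ``branch``.

    The marker of the current branch ramps linearly from 0 to the full
    amplitude along the branch; ancestor markers stay at full amplitude
    so the centroid path is continuous across branch points.
    """
    x = (starts[branch] + dirs[branch] * s).copy()
    L = topology.branch_lengths[branch]
    x[topology.marker_columns(branch)] = marker_amplitude * (s / L)
    p = topology.parent[branch]
    while p is not None:
        x[topology.marker_columns(p)] = marker_amplitude
        p = topology.parent[p]
    return x


def centroid_path_tangent(topology: TrajectoryTopology, starts, dirs,
                          branch: str, s: float,
                          marker_amplitude: float) -> np.ndarray:
    """Unit tangent of the centroid path (geometry drift + marker ramp)."""
    t = dirs[branch].copy()
    L = topology.branch_lengths[branch]
    t[topology.marker_columns(branch)] = marker_amplitude / L
    return t / np.linalg.norm(t)


def generate_branching_atlas(topology: TrajectoryTopology,
                             n_cells: int = 3000,
                             n_timepoints: int = 5,
                             noise_sd: float = 0.1,
                             with_velocity: bool = False,
                             with_spatial: bool = False,
                             seed: int = 0,
                             marker_amplitude: float = 1.5,
                             velocity_jitter: float = 0.0) -> CellTable:
    """Sample a branching single-cell atlas with known ground truth.

    Cells are placed uniformly along the latent tree (per-branch counts
    proportional to branch length), observed as the branch centroid plus
    iid Gaussian noise of ``noise_sd``.  ``time_label`` bins the latent
    pseudotime into ``n_timepoints`` contiguous quantile bins.  With
    ``with_velocity`` each cell carries the unit tangent of its branch
    centroid path (optionally angular-jittered); with ``with_spatial``
    each branch occupies a disc-shaped zone on a ring laid out so only
    tree-adjacent branches overlap.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if not np.isfinite(noise_sd) or noise_sd < 0:
        raise ValueError("noise_sd must be finite and >= 0")
    if n_cells < 10 * topology.n_branches:
        raise ValueError("need at least 10 cells per branch")

    rng = np.random.default_rng(seed)
    starts, dirs = _branch_geometry(topology, rng, marker_amplitude)
    branches = topology.branches
    lengths = np.array([topology.branch_lengths[b] for b in branches])
    total_depth = max(topology.depth_offset(b) + topology.branch_lengths[b]
                      for b in branches)

    # allocate cells proportional to branch length (largest remainder)
    frac = lengths / lengths.sum()
    counts = np.floor(frac * n_cells).astype(int)
    for i in np.argsort(-(frac * n_cells - counts))[: n_cells - counts.sum()]:
        counts[i] += 1

    X = np.empty((n_cells, topology.n_features))
    V = np.empty_like(X) if with_velocity else None
    branch_of = np.empty(n_cells, dtype=object)
    latent = np.empty(n_cells)
    row = 0
    for b, c in zip(branches, counts):
        L = topology.branch_lengths[b]
        s = rng.uniform(0.0, L, size=c)
        s.sort()
        for j in range(c):
            X[row] = centroid_path_point(topology, starts, dirs, b, s[j],
                                         marker_amplitude)
            if with_velocity:
                V[row] = centroid_path_tangent(topology, starts, dirs, b, s[j],
                                               marker_amplitude)
            branch_of[row] = b
            latent[row] = (topology.depth_offset(b) + s[j]) / total_depth
            row += 1
    X += rng.normal(0.0, noise_sd, size=X.shape)
    if with_velocity and velocity_jitter > 0:
        noise = rng.normal(0.0, velocity_jitter, size=V.shape)
        V = V + noise
        V /= np.linalg.norm(V, axis=1, keepdims=True)

    # contiguous quantile bins of latent pseudotime
    if n_timepoints == 1:
        time_label = np.zeros(n_cells, dtype=np.int64)
    else:
        qs = np.quantile(latent, np.linspace(0, 1, n_timepoints + 1)[1:-1])
        time_label = np.searchsorted(qs, latent, side="right").astype(np.int64)

    spatial = None
    if with_spatial:
        spatial = _spatial_zones(topology, branch_of, latent, rng)

    return CellTable(expression=X, time_label=time_label, spatial_xy=spatial,
                     annotation=branch_of.astype(str), velocity=V,
                     truth_branch=branch_of.astype(str), truth_time=latent)


def _spatial_zones(topology: TrajectoryTopology, branch_of, latent, rng):
    """Disc-shaped branch zones on a ring; only tree-adjacent zones overlap.

    Zone centers sit on a ring in depth-first order (so parent/child
    zones are ring-adjacent); the disc radius is 60% of the adjacent
    chord, which makes neighboring discs overlap while non-adjacent ones
    stay disjoint.
    """
    branches = topology.branches
    nb = len(branches)
    if nb == 1:
        centers = {branches[0]: np.zeros(2)}
        radius = 1.0
    else:
        ring_r = 10.0
        angles = 2 * np.pi * np.arange(nb) / nb
        centers = {b: ring_r * np.array([np.cos(a), np.sin(a)])
                   for b, a in zip(branches, angles)}
        chord = 2 * ring_r * np.sin(np.pi / nb)
        radius = 0.6 * chord
    n = len(branch_of)
    xy = np.empty((n, 2))
    for i in range(n):
        r = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        xy[i] = centers[branch_of[i]] + r * np.array([np.cos(a), np.sin(a)])
    return xy


def generate_toy_cluster_graph(nodes: Sequence,
                               weighted_edges: Sequence[Tuple],
                               root=None) -> ClusterGraph:
    """Build a small hand-specified undirected cluster graph.

    ``weighted_edges`` is a list of ``(u, v, weight)`` with positive
    weights; duplicate edges, self-loops and disconnected graphs are
    rejected.  Intended as an exact fixture for the walk oracles.
    """
    nodes = list(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    if len(idx) != len(nodes):
        raise ValueError("duplicate node ids")
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, w in weighted_edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        if w <= 0:
            raise ValueError("edge weights must be > 0")
        i, j = idx[u], idx[v]
        if W[i, j] != 0:
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        W[i, j] = W[j, i] = w
    # connectivity check by BFS
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(W[i] > 0):
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    if len(seen) != n:
        raise ValueError("graph is not connected")
    cg = ClusterGraph(W=W, names=nodes)
    if root is not None:
        cg.root = idx[root]
    return cg
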