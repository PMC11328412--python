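"""Cluster graph, lazy-teleporting random-walk pseudotime and forward bias.

The single-cell graph is coarsened into a cluster graph (community
detection or user labels; edge weight = summed single-cell edge weight
between clusters).  Pseudotime on the cluster graph is the expected
hitting time from the root under a lazy-teleporting random walk (LTRW):
at each step the walker stays put with probability ``laziness``, jumps
to a uniformly random node with probability ``teleport``, and otherwise
moves along edges proportionally to their weight.  The analytic hitting
times (linear solve) are refined by averaging with Monte-Carlo first-hit
times, then shifted/normalized so the root is at 0 and the latest node
at 1.  Undirected edge weights are then redistributed into directed
weights along increasing pseudotime (and, when velocity is available,
blended 50/50 by default with a velocity-derived transition), after
which root and terminal states can be detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .containers import AugmentedGraph, ClusterGraph

__all__ = ["LtrwParams", "cluster_cells", "build_cluster_graph",
           "ltrw_transition_matrix", "ltrw_pseudotime", "forward_bias",
           "velocity_transition_matrix", "detect_root", "detect_terminals"]


@dataclass
class LtrwParams:
    """Parameters of the lazy-teleporting walk and forward biasing.

    ``laziness`` + ``teleport`` must be < 1.  ``velocity_weight`` is the
    share of the directed edge weight taken from the velocity transition
    (0.5 = equal weight to velocity and pseudotime).  ``n_mcmc`` walks of
    at most ``max_steps`` steps refine the analytic hitting times.
    """

    laziness: float = 0.0
    teleport: float = 0.05
    n_mcmc: int = 1000
    max_steps: int = 2000
    velocity_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.laziness < 1 and 0 <= self.teleport < 1):
            raise ValueError("laziness and teleport must be in [0, 1)")
        if self.laziness + self.teleport >= 1:
            raise ValueError("laziness + teleport must be < 1")
        if not (0 <= self.velocity_weight <= 1):
            raise ValueError("velocity_weight must be in [0, 1]")
        if self.n_mcmc < 1 or self.max_steps < 1:
            raise ValueError("n_mcmc and max_steps must be >= 1")


def cluster_cells(graph: AugmentedGraph, resolution: float = 1.0,
                  seed: int = 0,
                  labels: Optional[np.ndarray] = None) -> np.ndarray:
    """Partition cells into clusters on the single-cell graph.

    Runs Leiden community detection on the weighted graph (deterministic
    for a fixed seed).  User-supplied ``labels`` bypass clustering
    entirely and are returned re-coded to consecutive integers.
    """
    n = graph.n_cells
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != (n,):
            raise ValueError(f"labels length {len(labels)} != n_cells {n}")
        _, coded = np.unique(labels, return_inverse=True)
        return coded.astype(np.int64)

    import igraph as ig
    import leidenalg

    n_comp, _ = sp.csgraph.connected_components(graph.weights, directed=False)
    if n_comp > 1:
        warnings.warn(f"single-cell graph has {n_comp} connected components",
                      stacklevel=2)
    coo = sp.triu(graph.weights, k=1).tocoo()
    g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                 edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed))
    return np.asarray(part.membership, dtype=np.int64)


def build_cluster_graph(graph: AugmentedGraph,
                        labels: np.ndarray) -> ClusterGraph:
    """Aggregate the single-cell graph into a cluster graph.

    ``w_ij`` sums the weights of all single-cell edges joining members
    of cluster i to members of cluster j (i != j); the result is
    symmetric because the cell graph is.  Clusters with no inter-cluster
    edge are reported with a warning.
    """
    labels = np.asarray(labels)
    n = graph.n_cells
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per cell")
    uniq, coded = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    M = sp.csr_matrix((np.ones(n), (np.arange(n), coded)), shape=(n, k))
    W = np.asarray((M.T @ graph.weights @ M).todense())
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0  # exact symmetry against float noise
    members = [np.flatnonzero(coded == i) for i in range(k)]
    if any(len(m) == 0 for m in members):
        raise ValueError("empty cluster")
    isolated = np.flatnonzero(W.sum(axis=1) == 0)
    if len(isolated):
        warnings.warn(f"clusters with no inter-cluster edges: "
                      f"{isolated.tolist()}", stacklevel=2)
    return ClusterGraph(W=W, members=members, names=list(uniq))


def ltrw_transition_matrix(cg: ClusterGraph, params: LtrwParams) -> np.ndarray:
    """Row-stochastic LTRW transition matrix on the cluster graph.

    ``P = (1 - laziness - teleport) * D^-1 W + laziness * I +
    teleport * U`` where U is the uniform matrix.
    """
    n = cg.n_nodes
    deg = cg.W.sum(axis=1)
    if (deg == 0).any() and params.teleport == 0:
        raise ValueError("isolated node with teleport=0: chain is reducible")
    Dinv_W = np.divide(cg.W, deg[:, None], out=np.zeros_like(cg.W),
                       where=deg[:, None] > 0)
    move = 1.0 - params.laziness - params.teleport
    P = move * Dinv_W + params.laziness * np.eye(n) + params.teleport / n
    # rows of isolated nodes: dump the move mass into laziness
    zero = deg == 0
    if zero.any():
        P[zero] += move * np.eye(n)[zero]
    return P


def _analytic_hitting_times(P: np.ndarray, root: int) -> np.ndarray:
    """Expected steps from ``root`` to each node (h[root] = 0).

    For target j, h_j solves ``(I - P_{-j}) h = 1`` over the non-target
    rows/columns (standard first-passage linear system).
    """
    n = P.shape[0]
    h = np.zeros(n)
    for j in range(n):
        if j == root:
            continue
        keep = np.arange(n) != j
        A = np.eye(n - 1) - P[np.ix_(keep, keep)]
        sol = np.linalg.solve(A, np.ones(n - 1))
        h[j] = sol[root - (root > j)]
    return h


def _mcmc_hitting_times(P: np.ndarray, root: int, params: LtrwParams):
    """Mean first-hit step per node over simulated LTRW walks from root.

    Returns ``(mean, standard_error)`` per node; nodes never hit within
    ``max_steps`` in any walk are NaN (the caller falls back to the
    analytic estimate).
    """
    rng = np.random.default_rng(params.seed)
    n = P.shape[0]
    cum = np.cumsum(P, axis=1)
    total = np.zeros(n)
    total_sq = np.zeros(n)
    count = np.zeros(n)
    for _ in range(params.n_mcmc):
        first = np.full(n, -1, dtype=np.int64)
        cur = root
        first[root] = 0
        unseen = n - 1
        for step in range(1, params.max_steps + 1):
            cur = int(np.searchsorted(cum[cur], rng.random(), side="right"))
            if first[cur] < 0:
                first[cur] = step
                unseen -= 1
                if unseen == 0:
                    break
        hit = first >= 0
        total[hit] += first[hit]
        total_sq[hit] += first[hit] ** 2
        count[hit] += 1
    mean = np.full(n, np.nan)
    se = np.full(n, np.nan)
    ok = count > 0
    mean[ok] = total[ok] / count[ok]
    var = np.maximum(total_sq[ok] / count[ok] - mean[ok] ** 2, 0.0)
    se[ok] = np.sqrt(var / count[ok])
    return mean, se


def ltrw_pseudotime(cg: ClusterGraph, root: int, params: LtrwParams,
                    return_raw: bool = False) -> np.ndarray:
    """LTRW pseudotime per cluster: analytic hitting times refined by MCMC.

    The analytic stage solves the linear first-passage system of the
    lazy-teleporting chain; the refinement stage averages in Monte-Carlo
    first-hit times (walks capped at ``max_steps``).  The combined
    estimate is min-shifted so the root sits at 0 and max-normalized to
    [0, 1].  With ``return_raw`` the unnormalized analytic hitting times
    are returned instead (used by scale-invariance checks).
    """
    n = cg.n_nodes
    if not (0 <= root < n):
        raise ValueError("root not in graph")
    if params.teleport == 0:
        n_comp, _ = sp.csgraph.connected_components(sp.csr_matrix(cg.W),
                                                    directed=False)
        if n_comp > 1:
            raise ValueError("graph disconnected and teleport=0: "
                             "some nodes are unreachable")
    P = ltrw_transition_matrix(cg, params)
    analytic = _analytic_hitting_times(P, root)
    if return_raw:
        return analytic
    mcmc, _ = _mcmc_hitting_times(P, root, params)
    combined = np.where(np.isnan(mcmc), analytic, (analytic + mcmc) / 2.0)
    combined = combined - combined[root]
    combined = np.maximum(combined, 0.0)
    mx = combined.max()
    return combined / mx if mx > 0 else combined


def velocity_transition_matrix(cg: ClusterGraph, expression: np.ndarray,
                               velocity: np.ndarray,
                               labels: np.ndarray) -> np.ndarray:
    """Row-stochastic cluster transition matrix from velocity vectors.

    Each cluster's mean velocity vector is compared (cosine similarity)
    with the displacement from its centroid to each neighbor's centroid;
    rectified similarities are normalized over the neighborhood, so flow
    goes only to neighbors the velocity actually points toward.  A
    cluster whose velocity points toward no neighbor (a sink of the
    flow) gets a self-absorbing row.
    """
    labels = np.asarray(labels)
    uniq, coded = np.unique(labels, return_inverse=True)
    n = cg.n_nodes
    if len(uniq) != n:
        raise ValueError("labels do not match cluster graph")
    cent = np.stack([expression[coded == i].mean(axis=0) for i in range(n)])
    vel = np.stack([velocity[coded == i].mean(axis=0) for i in range(n)])
    T = np.zeros((n, n))
    for i in range(n):
        nbrs = cg.neighbors(i)
        if len(nbrs) == 0:
            continue
        disp = cent[nbrs] - cent[i]
        dn = np.linalg.norm(disp, axis=1)
        vn = np.linalg.norm(vel[i])
        if vn < 1e-12:
            cos = np.zeros(len(nbrs))
        else:
            cos = (disp @ vel[i]) / (np.maximum(dn, 1e-12) * vn)
        pos = np.maximum(cos, 0.0)
        if pos.sum() > 0:
            T[i, nbrs] = pos / pos.sum()
        else:
            T[i, i] = 1.0                 # flow sink: self-absorbing
    return T


def forward_bias(cg: ClusterGraph, pseudotime: np.ndarray,
                 velocity_transition: Optional[np.ndarray],
                 params: LtrwParams) -> ClusterGraph:
    """Redistribute undirected edge weight into directed weights.

    For each undirected edge (i, j) the pseudotime component sends
    ``w_ij * s(dt)`` forward (toward increasing pseudotime) and
    ``w_ij * (1 - s(dt))`` backward, where ``s`` is a logistic squash of
    the pseudotime difference standardized by its standard deviation
    over edges.  With velocity, each row blends
    ``(1 - velocity_weight) * pt_component + velocity_weight * w_ij *
    velocity_transition[i, j]`` and is rescaled to keep the pseudotime
    component's row sum; rows that end up all-zero fall back to the
    pseudotime component.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    n = cg.n_nodes
    iu, ju = np.nonzero(np.triu(cg.W, k=1))
    dts = pseudotime[ju] - pseudotime[iu]
    scale = np.std(np.abs(dts))
    if scale < 1e-12:
        scale = 1.0
    D_pt = np.zeros((n, n))
    for i, j, dt in zip(iu, ju, dts):
        s = 1.0 / (1.0 + np.exp(-dt / scale))
        D_pt[i, j] = cg.W[i, j] * s          # i -> j follows increasing pt
        D_pt[j, i] = cg.W[i, j] * (1.0 - s)

    if velocity_transition is None or params.velocity_weight == 0:
        D = D_pt
    else:
        vw = params.velocity_weight
        D_vel = cg.W * velocity_transition
        D = (1 - vw) * D_pt + vw * D_vel
        # rescale rows to the pseudotime component's row sum
        for i in range(n):
            rs, target = D[i].sum(), D_pt[i].sum()
            if rs > 0 and target > 0:
                D[i] *= target / rs
            elif rs == 0:
                D[i] = D_pt[i]
    out = ClusterGraph(W=cg.W, members=cg.members, names=cg.names)
    out.directed_W = D
    out.pseudotime = pseudotime
    out.root = cg.root
    out.terminals = cg.terminals
    return out


def detect_root(cg: ClusterGraph,
                velocity_transition: Optional[np.ndarray]) -> int:
    """Predict the start state from velocity flow.

    The root is the node with maximal stationary mass under the
    time-reversed velocity chain — the state everything flows *out* of
    forward in time.  Ties break to the smallest node id.
    """
    if velocity_transition is None:
        raise ValueError("velocity_transition required for root detection; "
                         "otherwise supply the root explicitly")
    T = np.asarray(velocity_transition, dtype=float)
    n = T.shape[0]
    R = T.T.copy()
    np.fill_diagonal(R, 0.0)              # forward self-loops are sinks,
    rs = R.sum(axis=1)                    # not reverse flow
    zero = rs == 0
    R[zero, zero] = 1.0                   # sources absorb the reversed walk
    R = R / R.sum(axis=1, keepdims=True)
    R = 0.99 * R + 0.01 / n                 # teleport for ergodicity
    pi = np.full(n, 1.0 / n)
    for _ in range(10000):
        nxt = pi @ R
        if np.abs(nxt - pi).max() < 1e-12:
            pi = nxt
            break
        pi = nxt
    best = float(pi.max())
    cands = np.flatnonzero(pi >= best - 1e-10)
    if len(cands) > 1:
        warnings.warn("root tie broken to smallest node id", stacklevel=2)
    return int(cands.min())


def detect_terminals(cg: ClusterGraph, theta_out: float = 0.35,
                     q_deg: float = 0.5, q_pt: float = 0.7) -> list:
    """Detect terminal (cell-fate) clusters on the forward-biased graph.

    A node is terminal when (a) its fraction of outgoing directed mass,
    out/(out+in), is below ``theta_out``; (b) its neighborhood size is
    at or below the ``q_deg`` quantile of neighborhood sizes; and (c)
    its pseudotime is at or above the ``q_pt`` quantile.  If no node
    passes, the latest-pseudotime node is returned with a warning.
    """
    if cg.directed_W is None or cg.pseudotime is None:
        raise ValueError("directed_W and pseudotime must be computed first")
    D, pt = cg.directed_W, cg.pseudotime
    out_mass = D.sum(axis=1)
    in_mass = D.sum(axis=0)
    tot = out_mass + in_mass
    out_frac = np.divide(out_mass, tot, out=np.ones_like(out_mass),
                         where=tot > 0)
    nbr_size = (cg.W > 0).sum(axis=1)
    deg_cut = np.quantile(nbr_size, q_deg)
    pt_cut = np.quantile(pt, q_pt)
    mask = (out_frac < theta_out) & (nbr_size <= deg_cut) & (pt >= pt_cut)
    terminals = np.flatnonzero(mask)
    if len(terminals) == 0:
        warnings.warn("no node met the terminal criteria; falling back to "
                      "the max-pseudotime node", stacklevel=2)
        terminals = np.array([int(np.argmax(pt))])
    return [int(t) for t in terminals]
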