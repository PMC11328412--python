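"""Second-order (memory-biased) random walks on the cluster graph.

A first-order walk moves from ``v_cur`` to neighbor ``v_o`` with
probability proportional to the edge weight ``w(v_cur, v_o)``.  The
second-order walk additionally conditions on the previous node: a bias
factor ``alpha`` multiplies the weight of each candidate next node,

    alpha(v_cur, v_next) = 1        if (v_next, v_prev) is an edge
                                    (including the return move),
    alpha(v_cur, v_next) = 1/Memory otherwise,

so candidates outside the previous node's neighborhood are down-weighted
by the Memory parameter (Memory = 1 recovers the memoryless walk).  No
extra return-edge penalty is applied: the walks run on the
forward-biased directed graph, whose weights already suppress moves
against the pseudotime.  Ensembles of such walks from the root to the
terminal states give visitation frequencies per fate, which become
lineage probability fields and lineage-specific gene trends.

``enumerate_walk_distribution`` computes the same absorption and
visitation quantities exactly by dynamic programming over the
(previous, current) state chain and serves as the oracle for the
stochastic simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .containers import AugmentedGraph, ClusterGraph, WalkEnsemble

__all__ = ["MemoryConfig", "LineageProbabilityField", "first_order_probs",
           "second_order_probs", "simulate_walks",
           "enumerate_walk_distribution", "walk_pseudotime",
           "lineage_probabilities", "memory_scan",
           "gene_trend_along_lineage"]


@dataclass
class MemoryConfig:
    """Walk-stage parameters.

    ``memory`` >= 1 controls how strongly steps leaving the previous
    node's neighborhood are penalized (1 = no memory).  The walks are
    lazy-teleporting: per step the walker stays with probability
    ``laziness`` and jumps to a uniformly random node with probability
    ``teleport`` — and the memory bias also applies to those jumps,
    which is precisely how memory sharpens pathways (a teleport to a
    node unseen from the previous state is down-weighted by 1/memory).
    ``max_steps`` defaults to 4x the node count when left at 0.
    """

    memory: float = 10.0
    n_walks: int = 2000
    max_steps: int = 0
    laziness: float = 0.0
    teleport: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.memory < 1:
            raise ValueError("memory must be >= 1")
        if self.n_walks < 1:
            raise ValueError("n_walks must be >= 1")
        if not (0 <= self.laziness < 1 and 0 <= self.teleport < 1
                and self.laziness + self.teleport < 1):
            raise ValueError("need laziness, teleport >= 0 and "
                             "laziness + teleport < 1")

    def steps_for(self, cg: ClusterGraph) -> int:
        return self.max_steps if self.max_steps > 0 else 4 * cg.n_nodes


@dataclass
class LineageProbabilityField:
    """Per-cluster and per-cell probability of contributing to each fate."""

    cluster_probs: Dict[int, np.ndarray]
    cell_probs: Dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def fates(self):
        return sorted(self.cluster_probs)


def _walk_weights(cg: ClusterGraph) -> np.ndarray:
    """Edge weights the walk runs on: directed if forward-biased."""
    return cg.directed_W if cg.directed_W is not None else cg.W


def first_order_probs(cg: ClusterGraph, v_cur: int) -> np.ndarray:
    """Memoryless transition distribution out of ``v_cur``.

    ``p(v_o | v_cur) = w(v_cur, v_o) / sum_u w(v_cur, u)`` over the
    (out-)neighborhood; zero elsewhere.  Sink nodes are rejected — the
    caller is responsible for absorption.
    """
    w = _walk_weights(cg)[v_cur]
    total = w.sum()
    if total <= 0:
        raise ValueError(f"node {v_cur} has no out-neighbors")
    return w / total


def second_order_probs(cg: ClusterGraph, v_prev: int, v_cur: int,
                       config: MemoryConfig) -> np.ndarray:
    """Memory-biased transition distribution at (previous, current).

    Candidates adjacent to ``v_prev`` in the undirected graph (or the
    return move itself) keep bias 1; all others are down-weighted by
    ``1/memory``.  With ``memory = 1`` this is exactly the first-order
    distribution.
    """
    if config.memory < 1:
        raise ValueError("memory must be >= 1")
    if cg.W[v_prev, v_cur] <= 0 and _walk_weights(cg)[v_prev, v_cur] <= 0:
        raise ValueError(f"({v_prev}, {v_cur}) is not an edge")
    w = _walk_weights(cg)[v_cur].copy()
    if w.sum() <= 0:
        raise ValueError(f"node {v_cur} has no out-neighbors")
    alpha = _alpha(cg, v_prev, config.memory)
    biased = alpha * w
    return biased / biased.sum()


def _alpha(cg: ClusterGraph, v_prev: int, memory: float) -> np.ndarray:
    """Memory bias over candidate next nodes given the previous node."""
    in_prev_nbhd = cg.W[v_prev] > 0
    in_prev_nbhd[v_prev] = True            # return move keeps bias 1
    return np.where(in_prev_nbhd, 1.0, 1.0 / memory)


def step_distribution(cg: ClusterGraph, v_prev: int, v_cur: int,
                      config: MemoryConfig) -> np.ndarray:
    """One-step distribution of the second-order lazy-teleporting walk.

    The memoryless kernel mixes the (directed) edge-weight move with
    staying in place (``laziness``) and a uniform jump (``teleport``);
    the memory bias alpha then reweights every candidate — including
    teleport targets — by whether it is adjacent to the previous node.
    With ``laziness = teleport = 0`` this reduces exactly to
    ``second_order_probs`` (or ``first_order_probs`` when ``v_prev`` is
    negative, i.e. at the first step of a walk).
    """
    n = cg.n_nodes
    w = _walk_weights(cg)[v_cur]
    total = w.sum()
    move = 1.0 - config.laziness - config.teleport
    base = np.full(n, config.teleport / n)
    if total > 0:
        base += move * w / total
        base[v_cur] += config.laziness
    else:
        base[v_cur] += config.laziness + move   # sink: move mass stays put
    if v_prev >= 0 and config.memory > 1:
        base = _alpha(cg, v_prev, config.memory) * base
    s = base.sum()
    if s <= 0:
        raise ValueError(f"no admissible move from node {v_cur}")
    return base / s


def simulate_walks(cg: ClusterGraph, root: int,
                   config: MemoryConfig) -> WalkEnsemble:
    """Simulate an ensemble of second-order walks from the root.

    The first step is first-order (no previous node exists); subsequent
    steps are memory-biased.  A walk stops when it reaches any terminal
    (recorded in ``terminal_hit``) or after ``max_steps``.  Visitation
    frequencies are tabulated per terminal over the walks absorbed
    there.  Fixed seed => identical ensemble.
    """
    if cg.terminals is None:
        raise ValueError("terminals must be computed before simulating walks")
    terminals = set(int(t) for t in cg.terminals)
    max_steps = config.steps_for(cg)
    rng = np.random.default_rng(config.seed)
    n = cg.n_nodes
    W = _walk_weights(cg)

    cum_cache: Dict[tuple, np.ndarray] = {}
    walks = []
    hits = np.full(config.n_walks, -1, dtype=np.int64)
    for wi in range(config.n_walks):
        seq = [root]
        prev = -1
        cur = root
        for _ in range(max_steps):
            if W[cur].sum() <= 0 and config.teleport == 0:
                break                        # stuck at a non-terminal sink
            key = (prev, cur)
            if key not in cum_cache:
                cum_cache[key] = np.cumsum(
                    step_distribution(cg, prev, cur, config))
            cum = cum_cache[key]
            nxt = int(np.searchsorted(cum, rng.random() * cum[-1],
                                      side="right"))
            prev, cur = cur, nxt
            seq.append(cur)
            if cur in terminals:
                hits[wi] = cur
                break
        walks.append(seq)

    visitation: Dict[int, np.ndarray] = {}
    for t in sorted(terminals):
        idx = np.flatnonzero(hits == t)
        vis = np.zeros(n)
        for wi in idx:
            vis[np.unique(walks[wi])] += 1
        visitation[t] = vis / len(idx) if len(idx) else vis
    frac_hit = float(np.mean(hits >= 0))
    if frac_hit < 0.5:
        warnings.warn(
            f"only {frac_hit:.0%} of walks reached a terminal; consider "
            "raising max_steps or strengthening the forward bias",
            stacklevel=2)
    return WalkEnsemble(walks=walks, terminal_hit=hits,
                        visitation=visitation, root=root)


def enumerate_walk_distribution(cg: ClusterGraph, root: int,
                                config: MemoryConfig,
                                horizon: int = 0):
    """Exact absorption and visitation probabilities by dynamic programming.

    The second-order walk is a first-order Markov chain on (previous,
    current) states; terminals absorb.  Iterating the chain ``horizon``
    steps yields exact per-terminal absorption probabilities, and — by
    augmenting each state with a visited-flag per queried node — the
    exact probability that a walk absorbed at terminal t visited node v.
    Exponential in nothing, but quadratic state space: limited to 25
    nodes.

    Returns a dict with keys ``absorption`` (terminal -> probability)
    and ``visitation`` (terminal -> array over nodes of
    P(visited v | absorbed at t)).
    """
    n = cg.n_nodes
    if n > 25:
        raise ValueError("exact enumeration limited to graphs of <= 25 nodes")
    if cg.terminals is None:
        raise ValueError("terminals must be set")
    terminals = sorted(int(t) for t in cg.terminals)
    horizon = horizon if horizon > 0 else config.steps_for(cg)
    W = _walk_weights(cg)

    # enumerate non-absorbed states (prev, cur): prev=-1 start state
    states = [(-1, root)] + [(p, c) for p in range(n) for c in range(n)
                             if c not in terminals]
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    T = np.zeros((m, m))                       # state -> state
    A = np.zeros((m, len(terminals)))          # state -> absorbed at t
    term_index = {t: i for i, t in enumerate(terminals)}
    for si, (prev, cur) in enumerate(states):
        if W[cur].sum() <= 0 and config.teleport == 0 \
                and config.laziness == 0:
            continue                            # stuck sink: never absorbed
        q = step_distribution(cg, prev, cur, config)
        for nxt in np.flatnonzero(q > 0):
            if int(nxt) in term_index:
                A[si, term_index[int(nxt)]] += q[nxt]
            else:
                T[si, index[(cur, int(nxt))]] += q[nxt]

    cur_of_state = np.array([c for _, c in states])
    absorption = np.zeros(len(terminals))
    # visitation: lift with a visited flag per queried node
    visit_joint = np.zeros((n, len(terminals)))  # P(visited v & absorbed at t)
    for v in range(n):
        p_unvis = np.zeros(m)
        p_vis = np.zeros(m)
        if root == v:
            p_vis[0] = 1.0
        else:
            p_unvis[0] = 1.0
        acc = np.zeros(len(terminals))
        for _ in range(horizon):
            # absorption this step
            a_un = p_unvis @ A
            a_vi = p_vis @ A
            if v in terminals:
                ti = terminals.index(v)
                # entering terminal v itself counts as visiting it
                acc[ti] += a_un[ti]
                a_vi_total = a_vi.copy()
                acc += a_vi_total
            else:
                acc += a_vi
            nxt_un = p_unvis @ T
            nxt_vi = p_vis @ T
            # states whose current node is v flip the flag
            at_v = cur_of_state == v
            nxt_vi[at_v] += nxt_un[at_v]
            nxt_un[at_v] = 0.0
            p_unvis, p_vis = nxt_un, nxt_vi
            if p_unvis.sum() + p_vis.sum() < 1e-15:
                break
        visit_joint[v] = acc

    # absorption probabilities (flag-free pass)
    p = np.zeros(m)
    p[0] = 1.0
    for _ in range(horizon):
        absorption += p @ A
        p = p @ T
        if p.sum() < 1e-15:
            break
    vis = {}
    for ti, t in enumerate(terminals):
        if absorption[ti] > 0:
            vis[t] = visit_joint[:, ti] / absorption[ti]
        else:
            vis[t] = np.zeros(n)
    return {"absorption": {t: float(absorption[i])
                           for i, t in enumerate(terminals)},
            "visitation": vis}


def walk_pseudotime(cg: ClusterGraph, root: int,
                    config: MemoryConfig) -> np.ndarray:
    """Per-cluster pseudotime from the second-order walk ensemble.

    The mean first-visit step of each node over the ensemble, min-shifted
    and max-normalized to [0, 1]; nodes never visited are assigned the
    latest time.
    """
    ens = simulate_walks(cg, root, config)
    n = cg.n_nodes
    total = np.zeros(n)
    count = np.zeros(n)
    for seq in ens.walks:
        seen = {}
        for step, node in enumerate(seq):
            if node not in seen:
                seen[node] = step
        for node, step in seen.items():
            total[node] += step
            count[node] += 1
    pt = np.full(n, np.nan)
    ok = count > 0
    pt[ok] = total[ok] / count[ok]
    worst = np.nanmax(pt)
    pt[~ok] = worst
    pt -= pt[root]
    pt = np.maximum(pt, 0)
    mx = pt.max()
    return pt / mx if mx > 0 else pt


def lineage_probabilities(ensemble: WalkEnsemble, cg: ClusterGraph,
                          labels: Optional[np.ndarray] = None,
                          knn: Optional[AugmentedGraph] = None
                          ) -> LineageProbabilityField:
    """Lineage probability field per terminal fate.

    Cluster level: the fate-t value of a cluster is its visit frequency
    among walks absorbed at t, max-normalized to [0, 1].  Cell level
    (when labels and the single-cell graph are given): each cell takes
    its cluster's value, then one step of neighbor averaging on the
    single-cell graph (half own value, half weighted neighbor mean).
    """
    if ensemble.n_walks == 0:
        raise ValueError("empty walk ensemble")
    cluster_probs: Dict[int, np.ndarray] = {}
    for t, vis in ensemble.visitation.items():
        if vis.max() <= 0:
            warnings.warn(f"no walk reached terminal {t}; its lineage field "
                          "is all-zero", stacklevel=2)
            cluster_probs[t] = np.zeros_like(vis)
        else:
            cluster_probs[t] = vis / vis.max()
    out = LineageProbabilityField(cluster_probs=cluster_probs)
    if labels is not None and knn is not None:
        labels = np.asarray(labels)
        uniq, coded = np.unique(labels, return_inverse=True)
        W = knn.weights
        deg = np.asarray(W.sum(axis=1)).ravel()
        for t, cp in cluster_probs.items():
            cell_vals = cp[coded]
            neigh = np.asarray(W @ cell_vals).ravel()
            smooth = np.where(deg > 0, neigh / np.maximum(deg, 1e-12),
                              cell_vals)
            out.cell_probs[t] = 0.5 * cell_vals + 0.5 * smooth
    return out


def memory_scan(cell_table, memories: Sequence[float] = (1, 5, 10, 50, 100),
                graph_params=None, ltrw_params=None, walk_config=None,
                root: Optional[int] = None, resolution: float = 1.0):
    """Correlate experimental time with pseudotime across memory values.

    Graph construction, clustering, LTRW pseudotime, forward biasing and
    terminal detection are run once and shared; only the walk stage is
    re-run per memory value.  For each memory the per-cell pseudotime is
    the walk-based pseudotime of the cell's cluster, and the reported
    value is its Pearson correlation with the ordinal time label.  The
    default grid is {1, 5, 10, 50, 100} (memory 1 = no memory).
    """
    import pandas as pd

    from . import cluster as _cluster
    from . import graphs as _graphs
    from .metrics import pearson_r

    memories = list(memories)
    if any(m < 1 for m in memories):
        raise ValueError("memory values must be >= 1")
    if cell_table.time_label is None:
        raise ValueError("memory_scan requires time labels")
    gp = graph_params or _graphs.GraphParams()
    lp = ltrw_params or _cluster.LtrwParams()
    wc = walk_config or MemoryConfig()

    g = _graphs.build_knn_graph(cell_table.expression, gp)
    if cell_table.time_label is not None and \
            len(np.unique(cell_table.time_label)) > 1:
        g = _graphs.augment_sequential(g, cell_table.time_label,
                                       cell_table.expression, gp)
    labels = _cluster.cluster_cells(g, resolution=resolution, seed=lp.seed)
    cg = _cluster.build_cluster_graph(g, labels)
    vt = None
    if cell_table.velocity is not None:
        vt = _cluster.velocity_transition_matrix(
            cg, cell_table.expression, cell_table.velocity, labels)
    if root is None:
        if vt is not None:
            root = _cluster.detect_root(cg, vt)
        else:
            # earliest mean time label
            _, coded = np.unique(labels, return_inverse=True)
            means = [cell_table.time_label[coded == i].mean()
                     for i in range(cg.n_nodes)]
            root = int(np.argmin(means))
    pt = _cluster.ltrw_pseudotime(cg, root, lp)
    cg = _cluster.forward_bias(cg, pt, vt, lp)
    cg.root = root
    cg.terminals = _cluster.detect_terminals(cg)

    _, coded = np.unique(labels, return_inverse=True)
    rows = []
    for mem in memories:
        cfg = MemoryConfig(memory=float(mem), n_walks=wc.n_walks,
                           max_steps=wc.max_steps, seed=wc.seed)
        node_pt = walk_pseudotime(cg, root, cfg)
        cell_pt = node_pt[coded]
        r = pearson_r(cell_table.time_label.astype(float), cell_pt)
        rows.append({"memory": mem, "pearson_r": r})
    return pd.DataFrame(rows)


def gene_trend_along_lineage(expression: np.ndarray, pseudotime: np.ndarray,
                             field: LineageProbabilityField, fate: int,
                             n_grid: int = 50,
                             bandwidth: Optional[float] = None) -> np.ndarray:
    """Lineage-weighted smoothed expression trend along pseudotime.

    At each of ``n_grid`` uniform pseudotime grid points tau, the trend
    is the weighted average of expression with weights = lineage
    probability for ``fate`` x Gaussian kernel in pseudotime centered at
    tau.  Returns an ``(n_grid, n_genes)`` array (``(n_grid,)`` for a
    single gene vector).  Windows with fewer than 10 effective cells
    trigger a warning.
    """
    expression = np.asarray(expression, dtype=float)
    single = expression.ndim == 1
    X = expression[:, None] if single else expression
    pt = np.asarray(pseudotime, dtype=float)
    if fate in field.cell_probs:
        w_fate = np.asarray(field.cell_probs[fate], dtype=float)
    else:
        raise ValueError(f"no cell-level lineage field for fate {fate}")
    if len(w_fate) != len(pt) or X.shape[0] != len(pt):
        raise ValueError("expression, pseudotime and field sizes differ")
    lo, hi = pt.min(), pt.max()
    grid = np.linspace(lo, hi, n_grid)
    if bandwidth is None:
        bandwidth = 0.08 * max(hi - lo, 1e-12)
    trend = np.empty((n_grid, X.shape[1]))
    few = 0
    for gi, tau in enumerate(grid):
        kern = np.exp(-0.5 * ((pt - tau) / bandwidth) ** 2)
        w = w_fate * kern
        total = w.sum()
        if total <= 0:
            trend[gi] = np.nan
            few += 1
            continue
        ess = total ** 2 / np.maximum((w ** 2).sum(), 1e-300)
        if ess < 10:
            few += 1
        trend[gi] = (w[:, None] * X).sum(axis=0) / total
    if few:
        warnings.warn(f"{few}/{n_grid} trend windows have fewer than 10 "
                      "effective cells", stacklevel=2)
    return trend.ravel() if single else trend
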