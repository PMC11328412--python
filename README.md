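# celltrail

Trajectory inference and cartographic visualization for single-cell
atlases, built around **second-order (memory-biased) lazy-teleporting
random walks** on a forward-biased cluster graph. `celltrail` is aimed
at analysts working with large time-resolved or spatially resolved
single-cell datasets who want (1) a pseudotime and per-fate lineage
probabilities that stay specific to each differentiation pathway, and
(2) an "atlas view": an edge-bundled, direction-annotated map of the
whole dataset.

## The model

Cells are represented as a KNN graph in feature space, optionally
augmented with edges between cells of adjacent experimental time points
(and with spatial-proximity edges for tissue data, after spatially
smoothing expression). The graph is coarsened into a cluster graph
G(V, E, W) by community detection. On that graph:

- **Pseudotime** is the expected hitting time from a root cluster under
  a *lazy-teleporting random walk* (LTRW): with probability `laziness`
  the walker stays, with `teleport` it jumps uniformly, otherwise it
  moves along edges in proportion to `w_ij`. The analytic hitting times
  (a linear solve) are refined by averaging with Monte-Carlo first-hit
  times, then normalized to [0, 1].
- **Forward biasing** redistributes each undirected edge weight into
  directed weights along increasing pseudotime (logistic squashing of
  the standardized pseudotime difference), optionally blended 50/50
  with an RNA-velocity-derived transition matrix. Roots are detected
  from velocity flow, terminal states (cell fates) from low forward
  out-flow, low connectivity and late pseudotime.
- **Lineage pathways** are ensembles of *second-order* walks from the
  root: the step from `v_cur` given the previous node `v_prev` weights
  each candidate `v_next` by

      alpha = 1         if (v_next, v_prev) is an edge (incl. the return move)
      alpha = 1/Memory  otherwise,

  times the directed edge weight, normalized over the neighborhood.
  `Memory = 1` is exactly the memoryless walk; larger values penalize
  moves that leave the previous node's neighborhood, including teleport
  jumps. Visitation frequencies of walks absorbed at each terminal give
  per-fate lineage probability fields and lineage-specific gene trends.
  An exact dynamic program over (previous, current) states provides the
  oracle for all walk statistics on small graphs.
- **Cartography**: the cluster graph is laid out by Fruchterman-
  Reingold; single cells are embedded by UMAP-style cross-entropy
  optimization *of the augmented graph itself*, initialized at their
  cluster's layout position; the embedding is coarsened into kmeans
  milestones whose edges are bundled by kernel-density-estimation
  bundling (Epanechnikov kernel, bandwidth h_n = lambda^n * h_max) and
  annotated with pseudotime/velocity direction arrows.
- **Metrics**: five scores rate any 2-D embedding for TI use — Pearson
  correlation of experimental time with (i) pseudotime recomputed from
  the embedding, (ii) graph-geodesic and (iii) Euclidean distance from
  the root, plus (iv) cell-fate-detection F1 and (v) mean one-vs-all
  cell-type F1 under kmeans clustering.

A seeded synthetic-atlas generator (branching trajectories with known
branch membership, latent pseudotime, markers, tangent velocities and
spatial zones) provides ground truth for every stage.

## Worked example

```python
import numpy as np
import celltrail as ct
from celltrail import cluster as cl

topo = ct.TrajectoryTopology.trifurcation()      # trunk + three fates
table = ct.generate_branching_atlas(topo, n_cells=3000, n_timepoints=5,
                                    with_velocity=True, seed=7)

gp = ct.GraphParams()
g = ct.build_knn_graph(table.expression, gp)
g = ct.augment_sequential(g, table.time_label, table.expression, gp)
labels = ct.cluster_cells(g, resolution=1.0, seed=7)
cg = ct.build_cluster_graph(g, labels)
vt = cl.velocity_transition_matrix(cg, table.expression, table.velocity, labels)
root = cl.detect_root(cg, vt)
pt = cl.ltrw_pseudotime(cg, root, cl.LtrwParams(seed=7))
cg = cl.forward_bias(cg, pt, vt, cl.LtrwParams())
cg.root, cg.terminals = root, cl.detect_terminals(cg)
print(cg.n_nodes, root, cg.terminals)
```

prints

```
8 4 [1, 2, 6]
```

— 8 clusters, root cluster 4 (the earliest cluster: mean latent time
0.15) and three terminal clusters whose majority branches are the three
true arm tips (pseudotime 0.94–1.00). Correlating the per-cell
pseudotime with the experimental time label gives `r = 0.911`. The
`examples/` directory walks through each capability (simulation, TI,
memory walks and gene trends, the Atlas View figure, and the embedding
metric suite); `celltrail --help` exposes the same stages as CLI
subcommands (`simulate`, `run`, `graph`, `ti`, `lineage`, `atlas`,
`metrics`).

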