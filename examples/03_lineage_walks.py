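"""Second-order (memory-biased) walks, lineage fields and gene trends.

Shows the memory bias on a hand-built square graph (the exact worked
example: with memory=2 at (prev=a, cur=b) the return move keeps bias 1
while the unseen node c is halved, giving p = (2/3, 1/3)), then runs a
walk ensemble on a simulated atlas to derive per-fate lineage
probabilities and a marker gene trend along one lineage.
"""

import numpy as np

import celltrail as ct
from celltrail import cluster as cl
from celltrail.walks import MemoryConfig, second_order_probs, simulate_walks

square = ct.generate_toy_cluster_graph(
    "abcd", [("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "a", 1)])
p = second_order_probs(square, 0, 1, MemoryConfig(memory=2.0))
print(f"square graph, memory=2, at (prev=a, cur=b): "
      f"p(a)={p[0]:.4f}, p(c)={p[2]:.4f}  (exactly 2/3 and 1/3)")

topo = ct.TrajectoryTopology.trifurcation()
table = ct.generate_branching_atlas(topo, n_cells=3000, n_timepoints=5,
                                    with_velocity=True, seed=7)
gp = ct.GraphParams()
g = ct.build_knn_graph(table.expression, gp)
g = ct.augment_sequential(g, table.time_label, table.expression, gp)
labels = ct.cluster_cells(g, resolution=1.0, seed=7)
cg = ct.build_cluster_graph(g, labels)
vt = cl.velocity_transition_matrix(cg, table.expression, table.velocity,
                                   labels)
root = cl.detect_root(cg, vt)
pt = cl.ltrw_pseudotime(cg, root, cl.LtrwParams(seed=7))
cg = cl.forward_bias(cg, pt, vt, cl.LtrwParams())
cg.root, cg.terminals = root, cl.detect_terminals(cg)

ens = simulate_walks(cg, root, MemoryConfig(memory=10, n_walks=5000, seed=7))
print(f"walks reaching a fate: {np.mean(ens.terminal_hit >= 0):.0%}; "
      f"hits per fate: "
      f"{ {t: int((ens.terminal_hit == t).sum()) for t in cg.terminals} }")

field = ct.lineage_probabilities(ens, cg, labels=labels, knn=g)
_, coded = np.unique(labels, return_inverse=True)
fate = cg.terminals[0]
arm = max(set(table.truth_branch[coded == fate]),
          key=lambda a: (table.truth_branch[coded == fate] == a).sum())
marker = table.expression[:, topo.marker_columns(arm)[0]]
trend = ct.gene_trend_along_lineage(marker, pt[coded], field, fate,
                                    n_grid=20)
print(f"fate {fate} ({arm}) marker trend along pseudotime "
      "(rises only along its own lineage):")
print(np.round(trend, 2))
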