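"""Finite-sample-corrected mutual information and the long-range network.

Plants a correlated residue pair that is distant both in sequence and
in space, computes the corrected Calpha-fluctuation MI matrix over the
study-scale 7500 pooled frames, and builds the MI >= 0.25 /
distance >= 6 A / separation > 6 network with its centralities.
"""

import numpy as np

from mdinfonet import (
    NetworkConfig,
    Selection,
    betweenness_centrality,
    build_graph,
    degree_centrality,
    distance_matrix,
    mi_matrix_calpha,
)
from mdinfonet import synthetic as syn
from mdinfonet.infotheory import aggregate_mi
from mdinfonet.minet import edge_table

spec = syn.GaussianTrajSpec(
    n_res=24, n_frames=7500, sigma=0.35, seed=5,
    blocks=[syn.CorrelationBlock(residues=[2, 20], rho=0.95)])
traj, _ = syn.gen_gaussian_traj(spec)
sel = Selection.calpha(traj)

mat = mi_matrix_calpha([traj], sel)
off = mat.matrix[~np.eye(24, dtype=bool)]
print(f"corrected MI: planted pair {mat.matrix[2, 20]:.3f} bits vs "
      f"background mean {off.mean():.4f} bits")
print("  (independent residues carry ~0 corrected bits; the rho=0.95 "
      "pair shares real information)")

mean_tab = aggregate_mi(mat, "residue_mean")
top = mean_tab.sort_values("mean_mi_bits", ascending=False).head(2)
print("top residues by mean distant-pair MI:")
print(top.to_string(index=False))

g = build_graph(mat, distance_matrix([traj], sel), NetworkConfig())
print(f"\nnetwork: {g.number_of_nodes()} nodes, {g.number_of_edges()} "
      "edge(s) passing MI >= 0.25, D >= 6 A, |i-j| > 6")
print(edge_table(g).to_string(index=False))
cd = degree_centrality(g)
cb = betweenness_centrality(g)
hubs = cd[cd.degree_centrality > 0]
print("non-zero degree centrality nodes (the planted pair):")
print(hubs.to_string(index=False))
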