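# mdinfonet

Trajectory-analysis toolkit for protein MD ensembles, built for studies
that compare per-condition replicate simulations of a receptor (e.g. a
class A GPCR simulated at several pH values) and ask where the protein
fluctuates, which interactions persist, whether the conformational
state is preserved, and **which residues exchange dynamic information**.

It provides, as a plain Python library over multi-model PDB
trajectories:

- **Fluctuation analysis** — per-frame RMSD (align on one selection,
  measure on another), pooled per-residue RMSF about the iterated mean
  structure, windowed-RMSF stationarity QC, and condition-difference
  ΔRMSF with per-region maxima.
- **Principal component analysis** — Cα covariance PCA with cumulative
  variance ratios PCA_c = Σ_{i≤c} λ_i / Σ_i λ_i, per-frame projections
  P_t = X·U_k, the fluctuation amplitude along a mode
  RMSF = √( (1/T) Σ_t (P_t − ⟨P⟩)² ), and RMSIP subspace overlap
  between replicates.
- **Hydrogen bonds and contacts** — geometric detection
  (H···acceptor ≤ 2.5 Å, donor–H–acceptor angle ≥ 120°), occupancy
  pooled across a condition's replicates with a 0.001 frequency floor,
  per-residue persistence and unique-partner accounting; persistent
  heavy-atom contact maps (6.0 Å cutoff, 75% persistence).
- **GPCR microswitch panel** — ionic lock, Tyr–Tyr gate, NPxxY, PIF and
  toggle-switch metrics with inactive-state threshold verdicts,
  configurable per receptor.
- **Finite-sample-corrected mutual information** — adaptive equal-width
  binning of scalar Cα fluctuations (bin count chosen by an entropy
  convergence scan), Shannon entropy with the
  H + (N_b − 1)/N_c correction, pairwise MI with the
  MI − (N_b(i,j) − N_b(i) − N_b(j) + 1)/(2 N_c) correction, dihedral
  rotamer-state MI (3-state backbone sectors, g+/t/g− side chains,
  2-state terminal sp2 dihedrals), and aggregation by residue, residue
  type, chemical class and rotatable-bond count.
- **Residue interaction networks** — edges between residue pairs that
  are distant in sequence (|i−j| > 6), non-contacting in space
  (D_ij ≥ 6 Å) and informationally coupled (MI_ij ≥ 0.25), with
  MI-normalized weights, degree centrality deg(i)/(N−1) and
  unnormalized betweenness centrality.
- **Synthetic data** — seeded generators with analytically known ground
  truth (block-correlated Gaussian ensembles, planted rotamer joint
  tables, scheduled hydrogen-bond scenes, two-state microswitch
  scenes), so the whole pipeline is verifiable without simulation data.

## Worked example

```python
import numpy as np
from mdinfonet import (Selection, NetworkConfig, mi_matrix_calpha,
                       distance_matrix, build_graph, degree_centrality)
from mdinfonet import synthetic as syn

spec = syn.GaussianTrajSpec(
    n_res=24, n_frames=7500, sigma=0.35, seed=5,
    blocks=[syn.CorrelationBlock(residues=[2, 20], rho=0.95)])
traj, _ = syn.gen_gaussian_traj(spec)
sel = Selection.calpha(traj)

mat = mi_matrix_calpha([traj], sel)
print(mat.matrix[2, 20], mat.matrix[~np.eye(24, dtype=bool)].mean())

g = build_graph(mat, distance_matrix([traj], sel), NetworkConfig())
print(g.number_of_edges(), list(g.edges))
```

prints

```
0.613936519231012 0.01666452517897648
1 [(('A', 3), ('A', 21))]
```

The planted ρ = 0.95 residue pair carries 0.61 bits of corrected mutual
information against a ~0.017-bit independent background, and it is the
only pair passing all three network conditions (far in sequence, not in
contact, MI above 0.25 bits) — the network isolates genuine long-range
coupling. The `examples/` directory has one narrative script per
capability (fluctuation/PCA, H-bonds/contacts, microswitches, MI
networks, and the one-config pipeline).

Real trajectories enter the same way: `read_pdb_trajectory(path)` per
replicate, one list of trajectories per condition, or a YAML config via
`python -m mdinfonet.pipeline config.yaml`, which writes every table
plus a manifest of content digests.

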