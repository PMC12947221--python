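# Methods

This note documents the models and procedures mdinfonet implements,
the defaults it ships, the numerical choices it makes, and what its
synthetic generators do and do not emulate.

## Trajectory model and superposition

A trajectory is an ordered stack of frames over one immutable atom
table; residue identity is the (chain, author residue number) pair,
coordinates are Å everywhere. Multi-model PDB is the only on-disk
format (MODEL/ENDMDL blocks of fixed-column ATOM records; a bare ATOM
block reads as one frame). Elements come from columns 77–78 with a
fallback to the leading letter of the atom name — safe because the
package is protein-only (CA is always Cα carbon, metals are out of
scope). Alternate locations other than ' '/'A' are dropped, the
simplest deterministic rule. Hydrogens are required only by the
hydrogen-bond stage; their availability is reported at load time and
every other stage ignores their absence.

Rigid superposition is the least-squares Kabsch fit (via scipy's
rotation machinery; the batched alignment path uses an SVD Kabsch with
a determinant sign correction). Fits require ≥ 3 non-collinear atoms.
The test suite cross-checks against an independently written Horn
quaternion implementation at 1e-8 Å.

## Fluctuations

- **RMSD series** superpose each frame on a reference frame (default:
  frame 0 of the replicate, the common reporting convention) over an
  alignment selection and measure over a possibly different selection,
  so loop deviations can be isolated after aligning on the stable core.
- **RMSF** is referenced to the *iterated pooled mean*: frames of all
  replicates are pooled, fitted to the running mean structure until the
  mean moves < 1e-6 Å, then RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩. The same
  aligned, mean-referenced displacements feed the mutual-information
  stage, so both views of flexibility share one reference.
- **Windowed RMSF** cuts non-overlapping windows (default use: 25 ns
  windows over a 100 ns production run at 0.04 ns/frame → 4 × 625
  frames), dropping a trailing partial window — a stationarity check.
- **ΔRMSF** is the per-residue difference of two profiles with
  per-region |Δ| maxima; region ranges (e.g. the ICL3 core 241–260 and
  its edges 230–240/261–266 for the β2 adrenergic receptor) are
  configuration, never hard-coded, because loop boundary conventions
  vary between authors.

A caveat the tests make explicit: the rigid fit absorbs 6 degrees of
freedom, so for an N-residue selection a fraction ≈ 6/(3N) of isotropic
variance is removed. Closed-form RMSF checks therefore use N = 100,
where the effect is within the 3% test band.

## PCA

The covariance of the 3N-dimensional Cα coordinate vector of the
aligned ensemble is eigendecomposed with divisor T, so Σλ_i equals the
total mean-squared fluctuation exactly (checked at 1e-8 relative).
Eigenvector signs are fixed by making the largest-magnitude component
positive — plots reproduce bit-exactly and RMSIP is sign-invariant
anyway. The cumulative contribution PCA_c = Σ_{i≤c}λ_i / Σλ_i is
non-decreasing and reaches 1 at c = N.

Projections mean-center with the *model's* mean and dot with one
eigenvector per frame. The fluctuation amplitude along a mode is the
RMSF of the projection series, √((1/T)Σ(P_t − ⟨P⟩)²), which equals
√λ on the fitting ensemble (1e-6 relative); the per-residue curve is
the RMSF of the rank-1 reconstruction P_t·U — i.e. the scalar times the
per-residue norm of the mode. Both the scalar and the profile are
returned because the per-residue convention is not standardized.

RMSIP over the first k modes (default k = 5) is
√((1/k) Σ_{i≤k} Σ_{j≤k} (u_i·v_j)²); it is computed per replicate for
replicate comparisons and on pooled conditions for projection figures.

## Hydrogen bonds and contacts

Donors are N/O atoms with a covalently bonded hydrogen, inferred
geometrically (H within 1.2 Å in the same residue) because the inputs
are bare PDB frames with no topology file; acceptors are protein N/O
atoms; water is excluded. A triple counts when H···A ≤ 2.5 Å and the
D–H–A angle ≥ 120°. Occupancy is pooled over the condition's
replicates and records below 0.001 frequency are dropped as stochastic
contacts. Distinct hydrogens of one donor (the three Lys NZ protons)
are distinct records. Per-residue "persistence" is the mean occupancy
of the residue's surviving bonds; "unique acceptors" counts distinct
acceptor residues over surviving records with the residue as donor.
Because the raw record count and the occupancy-weighted count are both
defensible readings of "number of hydrogen bonds", both aggregates are
emitted; the record count is the default.

Contacts: residues are in contact in a frame when any heavy-atom
(C/N/O/S) pair is within 6.0 Å (heavy atoms rather than Cα to avoid
underestimating side-chain contacts); a contact is persistent at ≥ 75%
of frames. Both thresholds are parameters.

## Microswitch panel

Shipped definitions for the β2 adrenergic receptor (all residue IDs
come from a config table keyed by Ballesteros–Weinstein labels, so the
panel ports to other receptors):

| switch | metric | inactive rule |
|---|---|---|
| ionic lock | Arg131(NH1)–Glu268(OE2) distance | < 10.5 Å |
| Y–Y gate | Tyr219(CZ)–Tyr326(CZ) distance | > 14.6 Å |
| NPxxY | motif RMSD, residues 322–327 | < 2.0 Å |
| PIF | motif RMSD, Ile121 + Phe282 | < 2.2 Å |
| toggle | motif RMSD, Trp286 + Phe290 | reported only |
| Cys bridge | Cys106–Cys191 Cα distance | reported only |

Motif RMSD superposes each frame on the inactive reference structure
over the motif's heavy atoms and measures over the same atoms — the
minimal reading of "RMSD after alignment" for a local motif, and heavy
atoms because side-chain rearrangement is the signal for PIF/toggle.
Distances use no alignment (they are rigid-motion invariant). The panel
reports per-trajectory median/IQR and pooled inactive fractions.

## Entropy, mutual information and the finite-sampling correction

The fluctuation variable of residue i is the scalar norm
ΔR_i(t) = |r_i(t) − ⟨r_i⟩| of its Cα displacement after alignment
(scalar, matching the 1-D binning of the entropy scan). Each series is
binned on equal-width bins over its own range; the bin count is the
smallest N in an ascending scan with relative entropy increment
(H(N+1) − H(N))/H(N) ≤ 0.02, hard-capped at √N_c so the scan cannot
chase noise on small samples. Constant series are flagged (H = 0, one
bin) rather than binned.

Corrections are applied exactly in the printed forms

    H_true  ≈ H_obs  + (N_b − 1)/N_c
    MI_true ≈ MI_obs − (N_b(i,j) − N_b(i) − N_b(j) + 1)/(2 N_c)

with N_b the occupied-bin (or occupied-state) counts and N_c the sample
count. The entropy correction is deliberately *not* the textbook
Miller–Madow (N_b − 1)/(2 N_c ln 2): the additive form above is the
package's defined estimator and the MI correction is its exact
consequence through MI = H_i + H_j − H_ij. Negative corrected MI values
are finite-sample artifacts; they are floored at zero and the flooring
is flagged. The corrected-MI independence null (50 seeds at N_c = 7500,
the pooled frame count of three 2500-frame replicates) stays below
0.02 bits for binned continuous pairs and 0.01 bits for 3-state
categorical pairs.

A subtlety the estimator does not remove: for small selections the
shared rigid-body fit itself couples residues weakly (the 6 absorbed
degrees of freedom are common to all residues), so matrix-level nulls
are checked at 30 residues where this residual sits within the null
band. Binned MI is also bounded above by the continuous MI of the
generator; oracle comparisons therefore integrate the generating
density over the estimator's actual bins rather than using the
continuous closed form.

### Dihedral rotamer states

Backbone ϕ/ψ and side-chain χ1–χ4 are computed by the standard atan2
torsion construction, degrees in (−180, 180]; a dihedral whose defining
atoms are missing is marked absent, never zero-filled. Discretization:

- backbone: three equal 120° sectors anchored at −180° (the −180°
  boundary belongs to the first sector). Anchored sectors were chosen
  over Ramachandran-basin boundaries for determinism; this is a
  sensitivity-analysis candidate.
- side-chain sp3: g+ (0°, 120°], t (|θ| > 120°), g− (−120°, 0°].
- terminal sp2 dihedrals (Asp χ2, Glu χ3, Phe/Tyr/His/Trp χ2, Asn χ2,
  Gln χ3): two symmetry states, |θ| ≤ 90° vs > 90°. The table is
  overridable.

Residue-pair dihedral MI computes the corrected categorical MI for
every (dihedral of i, dihedral of j) pair and reduces by **sum**
(default; max and mean selectable — the residue-level reduction is a
convention, not a derivation). Distant-pair summaries use |i−j| > 5;
the Cα network uses |i−j| > 6. The two defaults intentionally differ
and are both configurable. Aggregations: per-residue mean over distant
partners, condition-difference ΔMI, per-residue-type mean, residue-
type-pair matrix, per-rotatable-bond-count mean, chemical-class mean
and class-pair matrix, with the class table
basic {K,R,H} / acidic {D,E} / amide {N,Q} / polar {S,T,Y,C} /
hydrophobic {A,V,L,I,M,F,W,P,G}.

## Residue network

Edges require all three of: sequence separation |i−j| > 6, trajectory-
mean Cα distance D_ij **≥** τ (default 6.0 Å — at-or-above, keeping
only spatially distant, non-contacting pairs so the network reports
long-range information transfer rather than packing; 6.0 Å mirrors the
contact cutoff the MI maps are overlaid on), and MI_ij ≥ 0.25 bits.
Distance reduction over frames is the mean by default (min and
per-frame stack selectable). Weights are MI normalized by the largest
included MI, so a non-empty edge set always has max weight 1. Degree
centrality is deg(i)/(N−1) with N = |V|; betweenness is the
unnormalized Brandes sum over unordered pairs on hop-count shortest
paths (a weighted variant uses 1/w lengths). Both are verified against
exhaustive path-enumeration oracles on ≤ 12-node graphs.

## Synthetic generators

All generators are seeded through numpy Generators (no time-based
state) and return machine-readable ground truth:

- **Gaussian ensembles**: isotropic per-coordinate jitter σ (default
  0.5 Å, a typical equilibrated-residue fluctuation) about an ideal
  helical Cα trace; planted blocks displace their residues along one
  shared random unit vector with equicorrelated scalar amplitudes
  (s_i = √ρ z₀ + √(1−ρ) z_i), the simplest construction with exact
  scalar correlation ρ, scaled σ√3 so magnitudes match the isotropic
  residues. Default ensembles mirror the study layout: three replicates
  × 2500 frames at 0.04 ns/frame per condition, pooled to 7500.
- **Single-mode ensembles** plant one internal deformation mode
  (rigid-body components projected out, since alignment would remove
  them) for PCA recovery tests.
- **Rotamer series** are i.i.d. draws from explicit joint tables whose
  exact MI is computed analytically.
- **Hydrogen-bond scenes** pose each scheduled triple satisfying both
  criteria with margin (2.0 Å, 180°) in Bernoulli-scheduled frames and
  violating exactly one criterion with margin (2.9 Å, or 110° at
  1.9 Å) otherwise, on residues spaced 25 Å apart.
- **Switch scenes** toggle an atom-pair distance between 9.0 and
  12.0 Å across the 10.5 Å ionic-lock rule on a planted schedule.

What they do **not** emulate: real backbone connectivity and sterics,
anharmonic or multi-basin dynamics, time correlation (frames are
i.i.d.), protonation effects, solvent and membrane. Passing tests
demonstrate the estimators and bookkeeping are correct under known
ground truth — not that any biological conclusion follows from them.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen to make each statistical
check sharp at desk scale: 7500-sample MI nulls (the pooled per-
condition frame count), 10⁵-sample table-recovery and closed-form
checks, ≤ 200-frame fixtures for nested-loop oracle equivalence,
≤ 12-node graphs for path enumeration. The pipeline writes a manifest
of SHA-256 content digests; identical configs reproduce identical
bytes for all deterministic stages.

## Known limitations

- PDB-only I/O (no DCD/XTC/PSF); protein atoms only.
- The bin-count scan and corrections assume i.i.d. samples; correlated
  MD frames make N_c an overcount and the corrections undercorrect.
- Donor typing by H proximity fails on structures without hydrogens
  (reported as an explicit error) and would mistype exotic chemistry.
- The microswitch defaults encode one receptor's residue numbering;
  porting requires a config table.
- Betweenness on hop counts ignores edge weights unless the weighted
  variant is chosen.
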