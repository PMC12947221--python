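"""Adaptive-histogram entropy and finite-sample-corrected mutual
information on Calpha fluctuations and dihedral rotamer states.

The fluctuation of residue i at frame t is the scalar norm of its
Calpha displacement from the ensemble-mean position after alignment,
dR_i(t). Each residue's series is discretized on equal-width bins whose
count is chosen by an ascending scan stopped at relative entropy
convergence,

    (H(N+1) - H(N)) / H(N) <= 0.02,

capped at sqrt(N_c) bins so the scan cannot chase sampling noise.
Histogram entropy and MI carry additive finite-sampling corrections in
terms of the occupied-bin counts N_b and the sample count N_c:

    H_true  ~= H_obs  + (N_b - 1) / N_c
    MI_true ~= MI_obs - (N_b(i,j) - N_b(i) - N_b(j) + 1) / (2 N_c)

(implemented exactly in this form; negative corrected MI is a
finite-sample artifact and is floored at zero, with the flooring
flagged). Dihedral MI discretizes backbone phi/psi into 3 sectors and
side-chain chi into rotamer states (g+/t/g- for sp3, 2 states for
terminal sp2 dihedrals), then applies the same correction with
occupied-state counts. All entropies and MI values are in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mdinfonet.fluctuation import align_to_mean, pool_frames
from mdinfonet.trajio import Selection, Trajectory

LOG2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Fluctuation series

def fluctuation_series(ensemble: list[Trajectory] | np.ndarray,
                       sel: Selection) -> np.ndarray:
    """Scalar Calpha fluctuation series dR_i(t), shape (n_residues, T).

    Frames are pooled, aligned to the iterated pooled mean, and each
    residue's series is the Euclidean norm of its displacement from its
    mean position.
    """
    frames = ensemble if isinstance(ensemble, np.ndarray) else pool_frames(ensemble)
    aligned = align_to_mean(frames, sel)
    sub = aligned[:, sel.indices, :]
    disp = sub - sub.mean(axis=0)
    return np.linalg.norm(disp, axis=2).T


# ---------------------------------------------------------------------------
# Binning and entropy

@dataclass
class BinSpec:
    n_bins: int
    low: float
    high: float
    constant: bool = False
    entropy_trace: list[float] = field(default_factory=list)

    @property
    def bin_size(self) -> float:
        return (self.high - self.low) / self.n_bins if not self.constant else 0.0

    def edges(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_bins + 1)


@dataclass
class EntropyEstimate:
    h_observed: float
    h_corrected: float
    n_occupied: int
    n_samples: int


def _hist_entropy(series: np.ndarray, n_bins: int, low: float,
                  high: float) -> tuple[float, int]:
    counts, _ = np.histogram(series, bins=n_bins, range=(low, high))
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum()), int((counts > 0).sum())


def optimize_bins(series: np.ndarray, rel_tol: float = 0.02,
                  max_bins: int | None = None) -> BinSpec:
    """Pick the bin count for one fluctuation series.

    Scans N = 2, 3, ... over equal-width bins spanning the series range
    and returns the smallest N for which the relative entropy increment
    (H(N+1) - H(N))/H(N) drops to ``rel_tol`` or below. Hard-capped at
    sqrt(N_c) bins. A constant series is flagged with H = 0 and a
    single bin.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples")
    low, high = float(series.min()), float(series.max())
    if high == low:
        return BinSpec(n_bins=1, low=low, high=high, constant=True,
                       entropy_trace=[0.0])
    cap = max(2, int(math.sqrt(series.size))) if max_bins is None else max_bins
    trace: list[float] = []
    h_prev, _ = _hist_entropy(series, 2, low, high)
    trace.append(h_prev)
    n = 2
    while n < cap:
        h_next, _ = _hist_entropy(series, n + 1, low, high)
        trace.append(h_next)
        if h_prev > 0 and (h_next - h_prev) / h_prev <= rel_tol:
            return BinSpec(n_bins=n, low=low, high=high, entropy_trace=trace)
        h_prev = h_next
        n += 1
    return BinSpec(n_bins=cap, low=low, high=high, entropy_trace=trace)


def entropy(series: np.ndarray, binspec: BinSpec) -> EntropyEstimate:
    """Shannon entropy of the binned series with the finite-sampling
    correction H_corrected = H_observed + (N_b - 1)/N_c."""
    series = np.asarray(series, dtype=float)
    n_c = series.size
    if binspec.constant:
        return EntropyEstimate(0.0, 0.0, 1, n_c)
    h, n_b = _hist_entropy(series, binspec.n_bins, binspec.low, binspec.high)
    return EntropyEstimate(h_observed=h, h_corrected=h + (n_b - 1) / n_c,
                           n_occupied=n_b, n_samples=n_c)


# ---------------------------------------------------------------------------
# Mutual information on continuous (binned) series

@dataclass
class MIResult:
    mi: float              # corrected, floored at 0
    mi_observed: float
    nb_joint: int
    nb_i: int
    nb_j: int
    n_samples: int
    floored: bool = False


def _mi_from_counts(joint: np.ndarray) -> tuple[float, int, int, int]:
    """(MI_obs bits, occupied joint bins, occupied i bins, occupied j bins)."""
    n = joint.sum()
    p = joint / n
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    nz = p > 0
    denom = np.outer(pi, pj)[nz]
    mi = float((p[nz] * np.log2(p[nz] / denom)).sum())
    return mi, int(nz.sum()), int((pi > 0).sum()), int((pj > 0).sum())


def _corrected(mi_obs: float, nb_ij: int, nb_i: int, nb_j: int,
               n_c: int) -> MIResult:
    corr = mi_obs - (nb_ij - nb_i - nb_j + 1) / (2 * n_c)
    floored = corr < 0
    return MIResult(mi=max(corr, 0.0), mi_observed=mi_obs, nb_joint=nb_ij,
                    nb_i=nb_i, nb_j=nb_j, n_samples=n_c, floored=floored)


def mi_calpha(series_i: np.ndarray, series_j: np.ndarray,
              binspec_i: BinSpec, binspec_j: BinSpec) -> MIResult:
    """Finite-sample-corrected MI between two fluctuation series.

    The joint 2-D histogram uses each residue's own optimized bins; the
    correction subtracts (N_b(i,j) - N_b(i) - N_b(j) + 1)/(2 N_c).
    """
    si = np.asarray(series_i, dtype=float)
    sj = np.asarray(series_j, dtype=float)
    if si.size != sj.size:
        raise ValueError("series lengths differ")
    if binspec_i.constant or binspec_j.constant:
        return MIResult(0.0, 0.0, 1, 1, 1, si.size)
    joint, _, _ = np.histogram2d(
        si, sj, bins=[binspec_i.n_bins, binspec_j.n_bins],
        range=[[binspec_i.low, binspec_i.high],
               [binspec_j.low, binspec_j.high]])
    mi_obs, nb_ij, nb_i, nb_j = _mi_from_counts(joint)
    return _corrected(mi_obs, nb_ij, nb_i, nb_j, si.size)


@dataclass
class MIMatrix:
    """Symmetric residue-pair MI matrix with binning metadata.

    In 'calpha' mode the diagonal holds each residue's corrected
    entropy; in 'dihedral' mode the diagonal is NaN (excluded).
    """

    residue_keys: list[tuple[str, int]]
    res_names: list[str]
    matrix: np.ndarray
    n_samples: int
    mode: str = "calpha"
    nb_joint: np.ndarray | None = None
    n_floored: int = 0

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def to_pairs(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_residues, k=1)
        return pd.DataFrame({
            "res_i": [f"{self.residue_keys[a][0]}:{self.residue_keys[a][1]}"
                      for a in i],
            "res_j": [f"{self.residue_keys[b][0]}:{self.residue_keys[b][1]}"
                      for b in j],
            "mi_bits": self.matrix[i, j],
        })


def mi_matrix_calpha(ensemble: list[Trajectory] | np.ndarray,
                     sel: Selection,
                     residue_keys: list[tuple[str, int]] | None = None,
                     res_names: list[str] | None = None) -> MIMatrix:
    """All-pairs corrected Calpha-fluctuation MI over a pooled ensemble."""
    if isinstance(ensemble, np.ndarray):
        if residue_keys is None or res_names is None:
            raise ValueError("raw frames need explicit residue metadata")
        frames = ensemble
    else:
        ref = ensemble[0]
        residue_keys = [ref.atoms[i].residue_key for i in sel.indices]
        res_names = [ref.atoms[i].res_name for i in sel.indices]
        frames = pool_frames(ensemble)
    series = fluctuation_series(frames, sel)
    n_res, n_c = series.shape
    specs = [optimize_bins(series[i]) for i in range(n_res)]
    mat = np.zeros((n_res, n_res))
    n_floored = 0
    for i in range(n_res):
        mat[i, i] = entropy(series[i], specs[i]).h_corrected
        for j in range(i + 1, n_res):
            r = mi_calpha(series[i], series[j], specs[i], specs[j])
            mat[i, j] = mat[j, i] = r.mi
            n_floored += int(r.floored)
    return MIMatrix(residue_keys=residue_keys, res_names=res_names,
                    matrix=mat, n_samples=n_c, mode="calpha",
                    n_floored=n_floored)


# ---------------------------------------------------------------------------
# Dihedrals and rotamer states

PHI = ("C-", "N", "CA", "C")     # "-" suffix: previous residue
PSI = ("N", "CA", "C", "N+")     # "+" suffix: next residue

CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

# terminal dihedrals ending on an sp2 group get 2 symmetry states
TERMINAL_SP2: dict[str, set[str]] = {
    "ASP": {"chi2"}, "GLU": {"chi3"}, "PHE": {"chi2"}, "TYR": {"chi2"},
    "ASN": {"chi2"}, "GLN": {"chi3"}, "HIS": {"chi2"}, "TRP": {"chi2"},
}

CHEMICAL_CLASS: dict[str, str] = {
    **{r: "basic" for r in ("LYS", "ARG", "HIS")},
    **{r: "acidic" for r in ("ASP", "GLU")},
    **{r: "amide" for r in ("ASN", "GLN")},
    **{r: "polar" for r in ("SER", "THR", "TYR", "CYS")},
    **{r: "hydrophobic" for r in ("ALA", "VAL", "LEU", "ILE", "MET",
                                  "PHE", "TRP", "PRO", "GLY")},
}

CHI_COUNT: dict[str, int] = {r: len(v) for r, v in CHI_ATOMS.items()}


@dataclass
class DihedralSeries:
    """Per-frame torsion angles, degrees in (-180, 180]; absent
    dihedrals (missing atoms or not defined for the type) are None."""

    res_name: str
    angles: dict[str, np.ndarray | None]

    def present(self) -> list[str]:
        return [k for k, v in self.angles.items() if v is not None]


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> np.ndarray:
    """Signed torsion by the standard atan2 construction, degrees in
    (-180, 180]. Accepts (..., 3) stacks."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 to keep the (-180, 180] convention
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def extract_dihedrals(traj: Trajectory, chain: str, res_id: int) -> DihedralSeries:
    """phi, psi and chi1..chi4 series for one residue.

    A dihedral whose defining atoms are missing (chain termini for
    phi/psi, truncated side chains) is marked absent, never zero-filled.
    """
    index = {(a.chain, a.res_id, a.name): i for i, a in enumerate(traj.atoms)}
    me = [a for a in traj.atoms if a.chain == chain and a.res_id == res_id]
    if not me:
        raise KeyError(f"residue {chain}:{res_id} not found")
    res_name = me[0].res_name

    def find(name: str) -> int | None:
        if name.endswith("-"):
            return index.get((chain, res_id - 1, name[:-1]))
        if name.endswith("+"):
            return index.get((chain, res_id + 1, name[:-1]))
        return index.get((chain, res_id, name))

    def torsion(quad) -> np.ndarray | None:
        idx = [find(n) for n in quad]
        if any(i is None for i in idx):
            return None
        c = traj.coords
        return dihedral_angle(c[:, idx[0]], c[:, idx[1]],
                              c[:, idx[2]], c[:, idx[3]])

    angles: dict[str, np.ndarray | None] = {
        "phi": torsion(PHI), "psi": torsion(PSI)}
    chis = CHI_ATOMS.get(res_name, [])
    for k in range(4):
        name = f"chi{k + 1}"
        angles[name] = torsion(chis[k]) if k < len(chis) else None
    return DihedralSeries(res_name=res_name, angles=angles)


@dataclass
class RotamerStateSeries:
    """Per-frame categorical state per dihedral, states 1..n_states."""

    res_name: str
    states: dict[str, np.ndarray]
    n_states: dict[str, int]


def _backbone_state(theta: np.ndarray) -> np.ndarray:
    """Three equal 120-degree sectors anchored at -180 deg; the -180
    boundary belongs to the first sector's closed edge."""
    s = np.floor((theta + 180.0) / 120.0).astype(int) + 1
    return np.clip(s, 1, 3)


def _sp3_state(theta: np.ndarray) -> np.ndarray:
    """g+ (1): (0, 120]; t (2): |theta| > 120; g- (3): (-120, 0]."""
    out = np.full(theta.shape, 2, dtype=int)
    out[(theta > 0) & (theta <= 120)] = 1
    out[(theta > -120) & (theta <= 0)] = 3
    return out


def _sp2_state(theta: np.ndarray) -> np.ndarray:
    return np.where(np.abs(theta) <= 90.0, 1, 2)


def assign_rotamer_states(dihedrals: DihedralSeries,
                          sp2_table: dict[str, set[str]] | None = None
                          ) -> RotamerStateSeries:
    """Discretize a residue's dihedral series into rotamer states.

    Backbone phi/psi use 3 sectors; side-chain sp3 dihedrals use the
    g+/t/g- sectors at 0 and +-120 deg; terminal sp2 dihedrals (e.g.
    Asp chi2, Glu chi3, Phe/Tyr chi2) use 2 symmetry states. The sp2
    table is overridable for non-standard residues.
    """
    res = dihedrals.res_name
    if res not in CHI_ATOMS:
        raise KeyError(f"no rotamer library entry for residue type {res!r}")
    sp2 = (TERMINAL_SP2 if sp2_table is None else sp2_table).get(res, set())
    states: dict[str, np.ndarray] = {}
    n_states: dict[str, int] = {}
    for name, theta in dihedrals.angles.items():
        if theta is None:
            continue
        if name in ("phi", "psi"):
            states[name] = _backbone_state(theta)
            n_states[name] = 3
        elif name in sp2:
            states[name] = _sp2_state(theta)
            n_states[name] = 2
        else:
            states[name] = _sp3_state(theta)
            n_states[name] = 3
    return RotamerStateSeries(res_name=res, states=states, n_states=n_states)


def mi_categorical(states_a: np.ndarray, states_b: np.ndarray) -> MIResult:
    """Corrected MI between two categorical state series (occupied-state
    counts feed the finite-sampling correction)."""
    a = np.asarray(states_a)
    b = np.asarray(states_b)
    if a.size != b.size:
        raise ValueError("state series lengths differ")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((ua.size, ub.size))
    np.add.at(joint, (ia, ib), 1.0)
    mi_obs, nb_ij, nb_i, nb_j = _mi_from_counts(joint)
    return _corrected(mi_obs, nb_ij, nb_i, nb_j, a.size)


def mi_dihedral(states_i: RotamerStateSeries, states_j: RotamerStateSeries,
                aggregate: str = "sum"):
    """Residue-pair dihedral MI.

    Computes corrected categorical MI for every (dihedral of i, dihedral
    of j) pair and reduces with ``aggregate`` in {'sum', 'max', 'mean'}
    (sum is the default residue-level reduction). Returns
    (value, per_pair dict); a pair of residues with no usable dihedrals
    returns (None, {}) — absent, not zero.
    """
    if aggregate not in ("sum", "max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    pairs: dict[tuple[str, str], float] = {}
    for na, sa in states_i.states.items():
        for nb, sb in states_j.states.items():
            pairs[(na, nb)] = mi_categorical(sa, sb).mi
    if not pairs:
        return None, {}
    vals = np.array(list(pairs.values()))
    if aggregate == "sum":
        v = float(vals.sum())
    elif aggregate == "max":
        v = float(vals.max())
    else:
        v = float(vals.mean())
    return v, pairs


def mi_matrix_dihedral(traj_or_ensemble, sel: Selection,
                       aggregate: str = "sum",
                       min_separation: int = 5) -> MIMatrix:
    """Residue-pair dihedral MI matrix over pooled frames.

    Only pairs more than ``min_separation`` residues apart in sequence
    are computed (the distant-pair rule for dihedral summaries); closer
    pairs and the diagonal are NaN.
    """
    ensemble = (traj_or_ensemble if isinstance(traj_or_ensemble, list)
                else [traj_or_ensemble])
    frames = pool_frames(ensemble)
    ref = ensemble[0]
    pooled = Trajectory(atoms=ref.atoms, coords=frames,
                        frame_spacing=ref.frame_spacing)
    keys = [ref.atoms[i].residue_key for i in sel.indices]
    names = [ref.atoms[i].res_name for i in sel.indices]
    rotamers = []
    for chain, rid in keys:
        dh = extract_dihedrals(pooled, chain, rid)
        rotamers.append(assign_rotamer_states(dh))
    n = len(keys)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(keys[i][1] - keys[j][1]) <= min_separation:
                continue
            v, _ = mi_dihedral(rotamers[i], rotamers[j], aggregate=aggregate)
            if v is not None:
                mat[i, j] = mat[j, i] = v
    return MIMatrix(residue_keys=keys, res_names=names, matrix=mat,
                    n_samples=frames.shape[0], mode="dihedral")


# ---------------------------------------------------------------------------
# Aggregation schemes

def _distant_mask(matrix: MIMatrix, min_separation: int) -> np.ndarray:
    rid = np.array([k[1] for k in matrix.residue_keys])
    sep = np.abs(rid[:, None] - rid[None, :])
    mask = sep > min_separation
    np.fill_diagonal(mask, False)
    return mask


def aggregate_mi(matrix: MIMatrix, scheme: str,
                 reference: MIMatrix | None = None,
                 min_separation: int = 5):
    """Reduce an MI matrix by one of the reporting schemes.

    schemes:
      residue_mean   per-residue mean MI over distant partners (<MI>)
      delta          element-wise difference against a reference matrix
      type_mean      mean distant-pair MI grouped by residue type
      type_pair      residue-type-pair mean MI matrix
      chi_count_mean mean grouped by rotatable-bond (chi) count
      class_mean     mean grouped by chemical class
      class_pair     chemical-class-pair mean MI matrix
    """
    valid = ~np.isnan(matrix.matrix)
    distant = _distant_mask(matrix, min_separation) & valid

    if scheme == "delta":
        if reference is None:
            raise ValueError("delta scheme needs a reference matrix")
        if matrix.residue_keys != reference.residue_keys:
            raise ValueError("matrices cover different residues")
        return matrix.matrix - reference.matrix

    if scheme == "residue_mean":
        vals = np.where(distant, matrix.matrix, 0.0)
        counts = distant.sum(axis=1)
        sums = vals.sum(axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return pd.DataFrame({
            "res_id": [k[1] for k in matrix.residue_keys],
            "res_name": matrix.res_names,
            "mean_mi_bits": means,
        })

    def group_key(idx: int, kind: str):
        name = matrix.res_names[idx]
        if kind == "type":
            return name
        if kind == "class":
            if name not in CHEMICAL_CLASS:
                raise KeyError(f"no chemical class for residue type {name!r}")
            return CHEMICAL_CLASS[name]
        if name not in CHI_COUNT:
            raise KeyError(f"no chi count for residue type {name!r}")
        return CHI_COUNT[name]

    kind = {"type_mean": "type", "type_pair": "type",
            "chi_count_mean": "chi", "class_mean": "class",
            "class_pair": "class"}.get(scheme)
    if kind is None:
        raise ValueError(f"unknown scheme {scheme!r}")

    i_idx, j_idx = np.where(np.triu(distant, k=1))
    rows = []
    for a, b in zip(i_idx, j_idx):
        rows.append((group_key(a, kind), group_key(b, kind),
                     matrix.matrix[a, b]))
    if scheme in ("type_mean", "chi_count_mean", "class_mean"):
        acc: dict = {}
        for ga, gb, v in rows:
            acc.setdefault(ga, []).append(v)
            acc.setdefault(gb, []).append(v)
        return pd.DataFrame({
            "group": list(acc),
            "mean_mi_bits": [float(np.mean(v)) for v in acc.values()],
            "n_pairs": [len(v) for v in acc.values()],
        }).sort_values("group").reset_index(drop=True)
    # pair schemes
    acc = {}
    for ga, gb, v in rows:
        key = tuple(sorted((str(ga), str(gb))))
        acc.setdefault(key, []).append(v)
    return pd.DataFrame({
        "group_i": [k[0] for k in acc],
        "group_j": [k[1] for k in acc],
        "mean_mi_bits": [float(np.mean(v)) for v in acc.values()],
        "n_pairs": [len(v) for v in acc.values()],
    }).sort_values(["group_i", "group_j"]).reset_index(drop=True)
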