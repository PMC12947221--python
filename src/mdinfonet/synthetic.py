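"""Seeded synthetic inputs with planted, analytically known structure.

Every generator returns machine-readable ground truth next to its data
so tests never re-derive targets by hand: Gaussian ensembles carry
their planted correlation blocks, rotamer draws carry the exact MI of
the planted joint table, and hydrogen-bond scenes carry their realized
occupancy schedules. All randomness flows through a single integer
seed via numpy's Generator; identical seeds give bit-identical output.

These stand-ins emulate the statistical structure each analysis stage
assumes (block-correlated positional fluctuations, categorical rotamer
joints, scheduled donor-H-acceptor geometries); they are not physical
simulations and do not reproduce any real receptor's dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mdinfonet.trajio import AtomRecord, Trajectory


# ---------------------------------------------------------------------------
# Structure builders

def helix_ca_trace(n_res: int, radius: float = 2.3, rise: float = 1.5,
                   turn_deg: float = 100.0) -> np.ndarray:
    """Idealized alpha-helical Calpha trace, (n_res, 3) Angstrom."""
    k = np.arange(n_res)
    ang = np.radians(turn_deg) * k
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     rise * k], axis=1)


def ca_trajectory(frames: np.ndarray, res_names: list[str] | None = None,
                  chain: str = "A", frame_spacing: float = 0.04) -> Trajectory:
    """Wrap (T, N, 3) Calpha frames as a Trajectory of CA atoms."""
    n = frames.shape[1]
    names = res_names or ["ALA"] * n
    atoms = [AtomRecord(serial=i + 1, name="CA", element="C",
                        res_name=names[i], res_id=i + 1, chain=chain)
             for i in range(n)]
    return Trajectory(atoms=atoms, coords=frames, frame_spacing=frame_spacing)


# ---------------------------------------------------------------------------
# Gaussian ensembles with planted correlation

@dataclass
class CorrelationBlock:
    residues: list[int]          # 0-based residue indices
    rho: float                   # pairwise correlation of the block scalars

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must be in (-1, 1)")


@dataclass
class GaussianTrajSpec:
    n_res: int = 30
    n_frames: int = 2000
    sigma: float = 0.5           # per-coordinate fluctuation, Angstrom
    blocks: list[CorrelationBlock] = field(default_factory=list)
    seed: int = 0
    mean: np.ndarray | None = None
    frame_spacing: float = 0.04


@dataclass
class GaussianGroundTruth:
    sigma: float
    blocks: list[CorrelationBlock]
    block_vectors: list[np.ndarray]   # shared unit vector per block


def gen_gaussian_traj(spec: GaussianTrajSpec):
    """Sample a Gaussian Calpha ensemble about a mean structure.

    Uncorrelated residues get isotropic per-coordinate jitter of
    standard deviation sigma. Within a planted block, each residue's
    displacement lies along a shared random unit vector with scalar
    amplitudes that are equicorrelated at rho (s_i =
    sqrt(rho) z0 + sqrt(1-rho) z_i, all standard normal, scaled by
    sigma*sqrt(3) so displacement magnitudes match the isotropic
    residues). Returns (Trajectory, GaussianGroundTruth).
    """
    rng = np.random.default_rng(spec.seed)
    mean = spec.mean if spec.mean is not None else helix_ca_trace(spec.n_res)
    if mean.shape[0] != spec.n_res:
        raise ValueError("mean structure size mismatch")
    blocked = set()
    for b in spec.blocks:
        overlap = blocked & set(b.residues)
        if overlap:
            raise ValueError(f"residues {sorted(overlap)} in multiple blocks")
        blocked |= set(b.residues)
        if max(b.residues) >= spec.n_res:
            raise ValueError("block residue index out of range")
    disp = rng.normal(0.0, spec.sigma,
                      size=(spec.n_frames, spec.n_res, 3))
    vectors = []
    amp = spec.sigma * math.sqrt(3.0)
    for b in spec.blocks:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        vectors.append(u)
        z0 = rng.standard_normal(spec.n_frames)
        for r in b.residues:
            zi = rng.standard_normal(spec.n_frames)
            s = math.sqrt(b.rho) * z0 + math.sqrt(1.0 - b.rho) * zi
            disp[:, r, :] = amp * s[:, None] * u[None, :]
    frames = mean[None, :, :] + disp
    traj = ca_trajectory(frames, frame_spacing=spec.frame_spacing)
    return traj, GaussianGroundTruth(sigma=spec.sigma, blocks=spec.blocks,
                                     block_vectors=vectors)


def _rigid_mode_basis(structure: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 infinitesimal rigid-body modes
    (3 translations + 3 rotations about the centroid), (3N, 6)."""
    n = structure.shape[0]
    x = structure - structure.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        modes.append(t.reshape(-1))
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        modes.append(np.cross(e[None, :], x).reshape(-1))
    q, _ = np.linalg.qr(np.stack(modes, axis=1))
    return q


def gen_single_mode_traj(n_res: int, n_frames: int, amplitude_sigma: float,
                         seed: int = 0, mode: np.ndarray | None = None,
                         noise_sigma: float = 0.0):
    """Ensemble whose only (dominant) motion is along one 3N-dim mode.

    Frames are mean + c_t * U with c_t ~ N(0, amplitude_sigma^2), plus
    optional isotropic noise. The mode is projected onto the orthogonal
    complement of the rigid-body subspace so the planted motion is a
    genuine internal deformation (rigid components would be removed by
    alignment anyway). Returns (Trajectory, unit mode (3N,)).
    """
    rng = np.random.default_rng(seed)
    mean = helix_ca_trace(n_res)
    if mode is None:
        mode = rng.normal(size=3 * n_res)
    mode = np.asarray(mode, float)
    rigid = _rigid_mode_basis(mean)
    mode = mode - rigid @ (rigid.T @ mode)
    mode = mode / np.linalg.norm(mode)
    c = rng.normal(0.0, amplitude_sigma, size=n_frames)
    frames = (mean.reshape(-1)[None, :] + c[:, None] * mode[None, :])
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    frames = frames.reshape(n_frames, n_res, 3)
    return ca_trajectory(frames), mode


# ---------------------------------------------------------------------------
# Rotamer-state draws from planted joint tables

@dataclass
class RotamerJointSpec:
    joint: np.ndarray            # (k_a, k_b) probabilities, sums to 1
    n_frames: int = 7500
    seed: int = 0

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        if self.joint.ndim != 2 or np.any(self.joint < 0):
            raise ValueError("joint table must be a non-negative matrix")
        if abs(self.joint.sum() - 1.0) > 1e-9:
            raise ValueError("joint table must sum to 1")


def exact_table_mi(joint: np.ndarray) -> float:
    """Exact MI (bits) of a categorical joint distribution."""
    p = np.asarray(joint, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / np.outer(pi, pj)[nz])).sum())


def gen_rotamer_series(spec: RotamerJointSpec):
    """I.i.d. per-frame draws of the joint state pair.

    Returns (states_a, states_b, mi_exact) with states in 1..k.
    """
    rng = np.random.default_rng(spec.seed)
    ka, kb = spec.joint.shape
    flat = spec.joint.reshape(-1)
    draws = rng.choice(flat.size, size=spec.n_frames, p=flat)
    return (draws // kb + 1, draws % kb + 1, exact_table_mi(spec.joint))


# ---------------------------------------------------------------------------
# Hydrogen-bond scenes

@dataclass
class HBondSceneSpec:
    """Scheduled donor-H-acceptor pairs on a sparse toy peptide.

    Each entry of ``occupancies`` drives one donor/acceptor residue
    pair: in scheduled-on frames the triple satisfies the default
    geometric criteria with margin (H...A = 2.0 A, angle 180 deg); in
    off frames exactly one criterion is violated with margin
    (distance 2.9 A, or angle 110 deg at 1.9 A for 'angle' mode).
    """

    occupancies: list[float] = field(default_factory=lambda: [0.3])
    n_frames: int = 2000
    seed: int = 0
    violate: str = "distance"      # "distance" | "angle"

    def __post_init__(self) -> None:
        for o in self.occupancies:
            if not (0.0 <= o <= 1.0):
                raise ValueError("occupancies must be in [0, 1]")
        if self.violate not in ("distance", "angle"):
            raise ValueError("violate must be 'distance' or 'angle'")


def gen_hbond_scene(spec: HBondSceneSpec):
    """Build the scheduled H-bond trajectory.

    Returns (Trajectory, schedules) where schedules[k] is the boolean
    on/off series realized for pair k (Bernoulli at the target rate).
    Pairs are spaced 25 A apart so they cannot interact.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = len(spec.occupancies)
    atoms: list[AtomRecord] = []
    serial = 1
    base_positions = []
    for k in range(n_pairs):
        off = np.array([0.0, 25.0 * k, 0.0])
        donor_res = 2 * k + 1
        acc_res = 2 * k + 2
        for name, element, res_id, pos in [
            ("N", "N", donor_res, off + [0.0, 0.0, 0.0]),
            ("H", "H", donor_res, off + [1.0, 0.0, 0.0]),
            ("CA", "C", donor_res, off + [-0.8, 1.2, 0.0]),
            ("C", "C", acc_res, off + [4.2, 1.2, 0.0]),
            ("O", "O", acc_res, off + [3.0, 0.0, 0.0]),  # moved per frame
        ]:
            atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                    res_name="ALA", res_id=res_id, chain="A"))
            base_positions.append(np.asarray(pos, float))
            serial += 1
    base = np.array(base_positions)
    coords = np.tile(base[None, :, :], (spec.n_frames, 1, 1))
    schedules = []
    h_pos = np.array([1.0, 0.0, 0.0])
    on_o = h_pos + np.array([2.0, 0.0, 0.0])          # 2.0 A, 180 deg
    if spec.violate == "distance":
        off_o = h_pos + np.array([2.9, 0.0, 0.0])     # 2.9 A > 2.5 + margin
    else:
        ang = math.radians(110.0)
        off_o = h_pos + 1.9 * np.array([-math.cos(ang), math.sin(ang), 0.0])
        # 110 deg D-H-A angle at 1.9 A: distance passes, angle fails
    for k, occ in enumerate(spec.occupancies):
        on = rng.random(spec.n_frames) < occ
        schedules.append(on)
        o_index = 5 * k + 4
        offset = np.array([0.0, 25.0 * k, 0.0])
        coords[:, o_index, :] = np.where(
            on[:, None], (on_o + offset)[None, :], (off_o + offset)[None, :])
    return Trajectory(atoms=atoms, coords=coords), schedules


# ---------------------------------------------------------------------------
# Microswitch schedules

def gen_switch_scene(inactive_fraction: float, n_frames: int, seed: int = 0,
                     inactive_distance: float = 9.0,
                     active_distance: float = 12.0):
    """Two-atom distance switch toggling across a threshold.

    Frames are 'inactive' (short distance) with the given probability.
    Returns (Trajectory, on_schedule); pair atoms are residue 1 NH1 and
    residue 2 OE2 so a distance definition with threshold between the
    two planted values (e.g. the 10.5 A ionic-lock rule) classifies
    frames exactly as scheduled.
    """
    rng = np.random.default_rng(seed)
    on = rng.random(n_frames) < inactive_fraction
    d = np.where(on, inactive_distance, active_distance)
    atoms = [
        AtomRecord(serial=1, name="NH1", element="N", res_name="ARG",
                   res_id=1, chain="A"),
        AtomRecord(serial=2, name="OE2", element="O", res_name="GLU",
                   res_id=2, chain="A"),
        AtomRecord(serial=3, name="CA", element="C", res_name="ARG",
                   res_id=1, chain="A"),
    ]
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 1, 0] = d
    coords[:, 2, 1] = 2.0
    return Trajectory(atoms=atoms, coords=coords), on
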