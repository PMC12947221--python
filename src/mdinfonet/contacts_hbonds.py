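"""Geometric hydrogen-bond detection with occupancy accounting, and
persistent heavy-atom contact maps.

A hydrogen bond is a donor-H-acceptor triple with H...acceptor distance
<= 2.5 A and D-H-A angle >= 120 deg; donors are N/O atoms with a
covalently bonded hydrogen (H within 1.2 A in the same residue),
acceptors are protein O or N atoms. Bonds occurring in fewer than 0.1%
of the pooled frames are discarded as stochastic contacts.

Two residues are in contact in a frame when at least one heavy-atom
(C/N/O/S) pair sits within the 6.0 A cutoff; a contact is persistent
when present in at least 75% of the frames.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from mdinfonet.trajio import Selection, Trajectory

AtomKey = tuple[str, int, str]  # (chain, res_id, atom name)
ResidueKey = tuple[str, int]


class NoHydrogensError(ValueError):
    """H-bond detection requested on a structure without hydrogens."""


@dataclass
class HBondCriteria:
    min_angle_deg: float = 120.0
    max_ha_distance: float = 2.5       # Angstrom, H...acceptor
    min_frequency: float = 0.001       # fraction of pooled frames
    covalent_dh_cutoff: float = 1.2    # Angstrom, donor-H bond inference

    def __post_init__(self) -> None:
        if not (0 < self.min_angle_deg <= 180):
            raise ValueError("angle must be in (0, 180]")
        if self.max_ha_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 <= self.min_frequency <= 1):
            raise ValueError("frequency threshold must be in [0, 1]")


@dataclass
class HBondRecord:
    donor: AtomKey
    hydrogen: AtomKey
    acceptor: AtomKey
    occupancy: float
    n_frames: int
    per_traj_occupancy: list[float] = field(default_factory=list)

    @property
    def donor_residue(self) -> ResidueKey:
        return (self.donor[0], self.donor[1])

    @property
    def acceptor_residue(self) -> ResidueKey:
        return (self.acceptor[0], self.acceptor[1])

    @property
    def intra_residue(self) -> bool:
        return self.donor_residue == self.acceptor_residue


@dataclass
class HBondTable:
    records: list[HBondRecord]
    n_frames: int
    criteria: HBondCriteria

    def per_residue_counts(self) -> pd.DataFrame:
        """Per-residue aggregates over surviving records: bonds as donor,
        bonds as acceptor, unique acceptor partner residues, and mean
        occupancy of the residue's bonds (its persistence)."""
        donors: Counter = Counter()
        acceptors: Counter = Counter()
        partners: dict[ResidueKey, set] = defaultdict(set)
        occ: dict[ResidueKey, list] = defaultdict(list)
        for r in self.records:
            donors[r.donor_residue] += 1
            acceptors[r.acceptor_residue] += 1
            partners[r.donor_residue].add(r.acceptor_residue)
            occ[r.donor_residue].append(r.occupancy)
            occ[r.acceptor_residue].append(r.occupancy)
        keys = sorted(set(donors) | set(acceptors))
        return pd.DataFrame({
            "chain": [k[0] for k in keys],
            "res_id": [k[1] for k in keys],
            "n_as_donor": [donors[k] for k in keys],
            "n_as_acceptor": [acceptors[k] for k in keys],
            "n_unique_acceptor_residues": [len(partners[k]) for k in keys],
            "persistence": [float(np.mean(occ[k])) if occ[k] else 0.0
                            for k in keys],
        })

    def occupancy_weighted_counts(self) -> pd.DataFrame:
        """Alternative per-residue aggregate: sum of occupancies instead
        of record counts (the time-averaged number of bonds)."""
        donors: dict[ResidueKey, float] = defaultdict(float)
        acceptors: dict[ResidueKey, float] = defaultdict(float)
        for r in self.records:
            donors[r.donor_residue] += r.occupancy
            acceptors[r.acceptor_residue] += r.occupancy
        keys = sorted(set(donors) | set(acceptors))
        return pd.DataFrame({
            "chain": [k[0] for k in keys],
            "res_id": [k[1] for k in keys],
            "mean_bonds_as_donor": [donors[k] for k in keys],
            "mean_bonds_as_acceptor": [acceptors[k] for k in keys],
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "donor_res": f"{r.donor[0]}:{r.donor[1]}",
            "donor_atom": r.donor[2],
            "hydrogen": r.hydrogen[2],
            "acceptor_res": f"{r.acceptor[0]}:{r.acceptor[1]}",
            "acceptor_atom": r.acceptor[2],
            "occupancy": r.occupancy,
            "n_frames": r.n_frames,
        } for r in self.records])


@dataclass
class ContactMap:
    residue_keys: list[ResidueKey]
    fraction: np.ndarray     # symmetric per-pair contact fraction
    persistent: np.ndarray   # boolean, fraction >= threshold, diag False
    cutoff: float
    persistence_threshold: float

    def pair_list(self) -> pd.DataFrame:
        i, j = np.where(np.triu(self.persistent, k=1))
        return pd.DataFrame({
            "res_i": [f"{self.residue_keys[a][0]}:{self.residue_keys[a][1]}" for a in i],
            "res_j": [f"{self.residue_keys[b][0]}:{self.residue_keys[b][1]}" for b in j],
            "fraction": self.fraction[i, j],
        })


# ---------------------------------------------------------------------------

def _hbond_topology(traj: Trajectory, criteria: HBondCriteria,
                    frame: np.ndarray):
    """Donor-H pairs and acceptor candidates from one frame's geometry.

    Donor typing is geometric: an N/O atom owning an H within the
    covalent cutoff in the same residue. Topology inferred this way is
    frame-independent for chemically sane structures, so callers reuse
    it across frames.
    """
    h_idx = [i for i, a in enumerate(traj.atoms) if a.element == "H"]
    if not h_idx:
        raise NoHydrogensError(
            "structure contains no hydrogens; hydrogen bonds cannot be "
            "detected (deposited frames must include explicit H atoms)")
    heavy_no = [i for i, a in enumerate(traj.atoms) if a.element in ("N", "O")]
    pairs = []  # (donor index, hydrogen index)
    tree = cKDTree(frame[heavy_no])
    for h in h_idx:
        near = tree.query_ball_point(frame[h], criteria.covalent_dh_cutoff)
        for k in near:
            d = heavy_no[k]
            if traj.atoms[d].residue_key == traj.atoms[h].residue_key:
                pairs.append((d, h))
                break
    acceptors = np.array(heavy_no, dtype=int)
    return pairs, acceptors


def detect_hbonds_frame(traj: Trajectory, frame_index: int,
                        criteria: HBondCriteria | None = None,
                        _topology=None) -> list[tuple[AtomKey, AtomKey, AtomKey]]:
    """Detect donor-H-acceptor triples in one frame.

    Emits a triple iff the H...acceptor distance is at most the cutoff
    and the D-H-A angle is at least the minimum. The donor's own heavy
    atom is never its acceptor.
    """
    criteria = criteria or HBondCriteria()
    frame = traj.coords[frame_index]
    pairs, acceptors = (_topology if _topology is not None
                        else _hbond_topology(traj, criteria, frame))
    tree = cKDTree(frame[acceptors])
    out = []
    for d, h in pairs:
        near = tree.query_ball_point(frame[h], criteria.max_ha_distance)
        for k in near:
            a = int(acceptors[k])
            if a == d:
                continue
            v1 = frame[d] - frame[h]
            v2 = frame[a] - frame[h]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = np.clip(v1 @ v2 / denom, -1.0, 1.0)
            angle = np.degrees(np.arccos(cosang))
            if angle >= criteria.min_angle_deg:
                ka = traj.atoms
                out.append((
                    (ka[d].chain, ka[d].res_id, ka[d].name),
                    (ka[h].chain, ka[h].res_id, ka[h].name),
                    (ka[a].chain, ka[a].res_id, ka[a].name),
                ))
    return out


def hbond_table(ensemble: list[Trajectory],
                criteria: HBondCriteria | None = None) -> HBondTable:
    """Pool H-bond occurrences over the condition's trajectories.

    Occupancy = frames containing the triple / total pooled frames;
    records below the frequency threshold are dropped. Distinct
    hydrogens of a multi-H donor (e.g. the three Lys NZ protons) yield
    distinct records.
    """
    criteria = criteria or HBondCriteria()
    if not ensemble or all(t.n_frames == 0 for t in ensemble):
        raise ValueError("empty ensemble")
    counts: Counter = Counter()
    per_traj: list[Counter] = []
    total = 0
    for traj in ensemble:
        topo = _hbond_topology(traj, criteria, traj.coords[0])
        local: Counter = Counter()
        for k in range(traj.n_frames):
            for triple in set(detect_hbonds_frame(traj, k, criteria,
                                                  _topology=topo)):
                local[triple] += 1
        per_traj.append(local)
        counts.update(local)
        total += traj.n_frames
    records = []
    for triple, n in sorted(counts.items()):
        occ = n / total
        if occ < criteria.min_frequency:
            continue
        records.append(HBondRecord(
            donor=triple[0], hydrogen=triple[1], acceptor=triple[2],
            occupancy=occ, n_frames=n,
            per_traj_occupancy=[c[triple] / t.n_frames
                                for c, t in zip(per_traj, ensemble)],
        ))
    return HBondTable(records=records, n_frames=total, criteria=criteria)


def contact_map(ensemble: list[Trajectory], cutoff: float = 6.0,
                persistence: float = 0.75) -> ContactMap:
    """Average residue contact map over pooled frames.

    Per frame, residues i and j are in contact iff their closest
    heavy-atom (C, N, O, S) pair is within ``cutoff``; the persistent
    map keeps pairs whose per-frame contact fraction reaches
    ``persistence``. Heavy atoms rather than Calpha avoid
    underestimating side-chain contacts.
    """
    ref = ensemble[0]
    heavy = [i for i, a in enumerate(ref.atoms) if a.is_heavy]
    if not heavy:
        raise ValueError("no heavy atoms in ensemble")
    res_keys = ref.residue_keys()
    res_index = {k: n for n, k in enumerate(res_keys)}
    atom_res = np.array([res_index[ref.atoms[i].residue_key] for i in heavy])
    nres = len(res_keys)
    hits = np.zeros((nres, nres))
    total = 0
    for traj in ensemble:
        for k in range(traj.n_frames):
            pos = traj.coords[k][heavy]
            tree = cKDTree(pos)
            frame_contacts = np.zeros((nres, nres), dtype=bool)
            for a, b in tree.query_pairs(cutoff):
                ra, rb = atom_res[a], atom_res[b]
                if ra != rb:
                    frame_contacts[ra, rb] = frame_contacts[rb, ra] = True
            hits += frame_contacts
            total += 1
    fraction = hits / total
    persistent = fraction >= persistence
    np.fill_diagonal(persistent, False)
    return ContactMap(residue_keys=res_keys, fraction=fraction,
                      persistent=persistent, cutoff=cutoff,
                      persistence_threshold=persistence)
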