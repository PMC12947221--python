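"""Multi-model PDB trajectory I/O, atom selection and rigid superposition.

The trajectory dialect is the one used for deposited per-run protein
trajectories: a sequence of MODEL/ENDMDL blocks of fixed-column ATOM
records (a bare ATOM block without MODEL keywords is read as a single
frame). Coordinates are Angstrom throughout; no unit conversion happens
anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class PDBParseError(ValueError):
    """Malformed or inconsistent multi-model PDB input."""


class GeometryError(ValueError):
    """Degenerate geometry (too few or collinear atoms) for superposition."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology of every frame.

    ``res_id`` is the author residue number of the source PDB (1-based);
    residue identity throughout the package is the (chain, res_id) pair.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.res_id)

    @property
    def is_heavy(self) -> bool:
        return self.element in ("C", "N", "O", "S")


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom table.

    coords has shape (n_frames, n_atoms, 3) in Angstrom. frame_spacing is
    the sampling interval in ns per frame (0.04 ns for the deposited runs).
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    frame_spacing: float = 0.04

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} != "
                f"atom table length {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def has_hydrogens(self) -> bool:
        """Whether any hydrogen is present; reported at load time because
        H-bond analysis needs explicit hydrogens while every other stage
        silently ignores their absence."""
        return any(a.element == "H" for a in self.atoms)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique residue keys in atom-table order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)


@dataclass
class Selection:
    """Resolved, frame-stable atom index selection.

    Built from a predicate over AtomRecord; the resolved indices are
    strictly increasing and identical for every frame since the atom
    table is shared.
    """

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @staticmethod
    def from_predicate(traj: Trajectory,
                       pred: Callable[[AtomRecord], bool],
                       label: str = "") -> "Selection":
        idx = [i for i, a in enumerate(traj.atoms) if pred(a)]
        return Selection(np.array(idx, dtype=int), label=label)

    @staticmethod
    def calpha(traj: Trajectory, res_ids: Iterable[int] | None = None,
               chain: str | None = None) -> "Selection":
        wanted = None if res_ids is None else set(res_ids)
        return Selection.from_predicate(
            traj,
            lambda a: a.name == "CA"
            and (wanted is None or a.res_id in wanted)
            and (chain is None or a.chain == chain),
            label="calpha",
        )

    @staticmethod
    def by_atoms(traj: Trajectory,
                 keys: Iterable[tuple[str, int, str]]) -> "Selection":
        """Select by (chain, res_id, atom name) keys; order follows the
        atom table, and every key must resolve."""
        keyset = set(keys)
        idx = [i for i, a in enumerate(traj.atoms)
               if (a.chain, a.res_id, a.name) in keyset]
        found = {(traj.atoms[i].chain, traj.atoms[i].res_id,
                  traj.atoms[i].name) for i in idx}
        missing = keyset - found
        if missing:
            raise KeyError(f"atoms not found: {sorted(missing)}")
        return Selection(np.array(idx, dtype=int))

    @staticmethod
    def heavy(traj: Trajectory, res_ids: Iterable[int] | None = None) -> "Selection":
        wanted = None if res_ids is None else set(res_ids)
        return Selection.from_predicate(
            traj,
            lambda a: a.is_heavy and (wanted is None or a.res_id in wanted),
            label="heavy",
        )

    @staticmethod
    def all(traj: Trajectory) -> "Selection":
        return Selection(np.arange(traj.n_atoms), label="all")


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference."""

    rotation: np.ndarray   # 3x3 proper orthogonal
    translation: np.ndarray  # applied after rotation, Angstrom
    rmsd: float            # over the fit selection, after transform

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB parsing

def _infer_element(element_field: str, atom_name: str) -> str:
    """Element from columns 77-78, falling back to the leading letters of
    the atom name (digits and primes stripped; a leading digit as in '1HB'
    is skipped)."""
    el = element_field.strip()
    if el:
        return el.capitalize() if len(el) > 1 else el.upper()
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        raise PDBParseError(f"cannot infer element for atom name {atom_name!r}")
    # protein-only scope: the leading letter is the element (CA is Calpha
    # carbon, never calcium; metals/ions are out of scope)
    return name[0].upper()


def _parse_atom_line(line: str) -> tuple[AtomRecord, str, np.ndarray]:
    """Parse one fixed-column ATOM/HETATM record -> (record, altloc, xyz)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17]
        res_name = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = _infer_element(line[76:78] if len(line) >= 78 else "", name)
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record: {line.rstrip()!r}") from exc
    rec = AtomRecord(serial=serial, name=name, element=element,
                     res_name=res_name, res_id=res_id, chain=chain)
    return rec, altloc, np.array([x, y, z])


def read_pdb_trajectory(path, frame_spacing: float = 0.04) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory.

    Frames appear in file order. Atom ordering must be identical across
    models; an inconsistent atom count raises PDBParseError naming the
    offending model index. Alternate locations other than ' '/'A' are
    dropped. A file without MODEL keywords yields a single-frame
    trajectory.
    """
    frames: list[list[np.ndarray]] = []
    atom_tables: list[list[AtomRecord]] = []
    current_coords: list[np.ndarray] | None = None
    current_atoms: list[AtomRecord] | None = None
    model_indices: list[int] = []
    in_model = False
    saw_model_kw = False

    def _close(model_idx: int) -> None:
        nonlocal current_coords, current_atoms
        if current_coords is None:
            return
        frames.append(current_coords)
        atom_tables.append(current_atoms)  # type: ignore[arg-type]
        model_indices.append(model_idx)
        current_coords, current_atoms = None, None

    with open(path) as fh:
        for line in fh:
            rec_type = line[:6]
            if rec_type.startswith("MODEL"):
                saw_model_kw = True
                in_model = True
                current_coords, current_atoms = [], []
            elif rec_type.startswith("ENDMDL"):
                _close(len(frames) + 1)
                in_model = False
            elif rec_type in ("ATOM  ", "HETATM"):
                rec, altloc, xyz = _parse_atom_line(line)
                if altloc not in (" ", "A", ""):
                    continue
                if current_coords is None:
                    if saw_model_kw and not in_model:
                        # stray ATOM between models: tolerate by opening
                        current_coords, current_atoms = [], []
                        in_model = True
                    elif not saw_model_kw:
                        current_coords, current_atoms = [], []
                current_coords.append(xyz)          # type: ignore[union-attr]
                current_atoms.append(rec)           # type: ignore[union-attr]
    _close(len(frames) + 1)

    if not frames or not frames[0]:
        raise PDBParseError(f"no ATOM records found in {path}")

    n0 = len(frames[0])
    for k, fr in enumerate(frames):
        if len(fr) != n0:
            raise PDBParseError(
                f"model {model_indices[k]} has {len(fr)} atoms, "
                f"expected {n0} (model 1)"
            )
    coords = np.array(frames, dtype=float)
    return Trajectory(atoms=atom_tables[0], coords=coords,
                      frame_spacing=frame_spacing)


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB (MODEL numbered from 1)."""
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, a in enumerate(traj.atoms):
                x, y, z = traj.coords[m, i]
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.serial % 100000:5d} {name:<4.4s} "
                    f"{a.res_name:>3.3s} {a.chain:1.1s}{a.res_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition

def superpose(mobile: np.ndarray, reference: np.ndarray,
              sel: Selection | None = None) -> SuperpositionResult:
    """Least-squares (Kabsch) rigid fit of one frame onto another.

    mobile and reference are (n_atoms, 3) frames; the fit is computed over
    ``sel`` (all atoms when None). Requires >= 3 non-collinear selected
    atoms. The returned transform maps mobile coordinates onto the
    reference; apply it to the full frame with ``result.apply``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = sel.indices if sel is not None else np.arange(mobile.shape[0])
    a = mobile[idx]
    b = reference[idx]
    if a.shape[0] < 3:
        raise GeometryError(f"superposition needs >=3 atoms, got {a.shape[0]}")
    ca = a - a.mean(axis=0)
    # collinearity: rank of centered cloud < 2
    if np.linalg.matrix_rank(ca, tol=1e-8) < 2:
        raise GeometryError("selected atoms are collinear")
    cb = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(cb, ca)
    R = rot.as_matrix()
    t = b.mean(axis=0) - a.mean(axis=0) @ R.T
    fitted = a @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
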