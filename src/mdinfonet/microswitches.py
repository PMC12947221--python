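"""Canonical GPCR microswitch panel with inactive-state threshold verdicts.

Five conserved conformational reporters discriminate inactive from
active class A GPCR ensembles: the TM3-TM6 ionic lock (Arg3.50-Glu6.30
salt bridge, short when intact), the extracellular Tyr-Tyr aromatic
gate, the NPxxY motif RMSD tracking the TM7 inward rotation, the PIF
motif RMSD for TM3/TM6 repacking, and the Trp-Phe rotamer toggle. RMSDs
are measured after alignment on the motif's heavy atoms against an
inactive-state reference structure (2RH1 for the beta2 adrenergic
receptor). Residue IDs come from a configuration table keyed by
Ballesteros-Weinstein labels so the panel ports to other receptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mdinfonet.trajio import Selection, Trajectory, superpose


@dataclass
class MicroswitchDefinition:
    """One panel entry: an atom-pair distance or a motif RMSD, with an
    optional inactive-state rule (comparator 'lt'/'gt' + threshold, A)."""

    name: str
    kind: str                                  # "distance" | "motif_rmsd"
    atoms: list[tuple[str, int, str]] = field(default_factory=list)
    motif_res_ids: list[int] = field(default_factory=list)
    comparator: str | None = None              # "lt" | "gt" | None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "motif_rmsd"):
            raise ValueError(f"unknown microswitch kind {self.kind!r}")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def is_inactive(self, values: np.ndarray) -> np.ndarray | None:
        if self.comparator is None or self.threshold is None:
            return None
        if self.comparator == "lt":
            return values < self.threshold
        return values > self.threshold


def default_definitions(chain: str = "A") -> list[MicroswitchDefinition]:
    """The beta2AR panel with inactive-state thresholds.

    Ionic lock Arg131(NH1)-Glu268(OE2) < 10.5 A; aromatic gate
    Tyr219(CZ)-Tyr326(CZ) > 14.6 A; NPxxY (322-327) RMSD < 2 A; PIF
    (Ile121 + Phe282) RMSD < 2.2 A; Trp286/Phe290 toggle RMSD and
    Cys106-Cys191 Calpha distance reported without verdicts.
    """
    return [
        MicroswitchDefinition(
            name="ionic_lock", kind="distance",
            atoms=[(chain, 131, "NH1"), (chain, 268, "OE2")],
            comparator="lt", threshold=10.5),
        MicroswitchDefinition(
            name="yy_gate", kind="distance",
            atoms=[(chain, 219, "CZ"), (chain, 326, "CZ")],
            comparator="gt", threshold=14.6),
        MicroswitchDefinition(
            name="npxxy_rmsd", kind="motif_rmsd",
            motif_res_ids=list(range(322, 328)),
            comparator="lt", threshold=2.0),
        MicroswitchDefinition(
            name="pif_rmsd", kind="motif_rmsd",
            motif_res_ids=[121, 282],
            comparator="lt", threshold=2.2),
        MicroswitchDefinition(
            name="toggle_rmsd", kind="motif_rmsd",
            motif_res_ids=[286, 290]),
        MicroswitchDefinition(
            name="cys_bridge", kind="distance",
            atoms=[(chain, 106, "CA"), (chain, 191, "CA")]),
    ]


def atom_pair_series(traj: Trajectory,
                     definition: MicroswitchDefinition) -> np.ndarray:
    """Euclidean distance between the two named atoms per frame (no
    alignment; distances are rigid-motion invariant)."""
    if definition.kind != "distance" or len(definition.atoms) != 2:
        raise ValueError(f"{definition.name}: not an atom-pair definition")
    try:
        sel = Selection.by_atoms(traj, definition.atoms)
    except KeyError as exc:
        raise KeyError(f"{definition.name}: {exc}") from exc
    i, j = sel.indices
    # preserve the order the definition names the atoms in
    return np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :], axis=1)


def motif_rmsd_series(traj: Trajectory, definition: MicroswitchDefinition,
                      reference: Trajectory,
                      reference_frame: int = 0) -> np.ndarray:
    """Per-frame motif heavy-atom RMSD against an inactive reference.

    Each frame is superposed on the reference over the motif's heavy
    atoms and the RMSD is taken over the same atoms (alignment selection
    = measurement selection, the minimal reading of RMSD-after-alignment
    for a local motif).
    """
    if definition.kind != "motif_rmsd" or not definition.motif_res_ids:
        raise ValueError(f"{definition.name}: not a motif definition")
    wanted = set(definition.motif_res_ids)
    keys = [(a.chain, a.res_id, a.name) for a in traj.atoms
            if a.res_id in wanted and a.is_heavy]
    ref_keys = {(a.chain, a.res_id, a.name) for a in reference.atoms}
    keys = [k for k in keys if k in ref_keys]
    if len(keys) < 3:
        raise ValueError(f"{definition.name}: motif resolves to <3 shared "
                         "heavy atoms")
    sel_t = Selection.by_atoms(traj, keys)
    sel_r = Selection.by_atoms(reference, keys)
    ref = reference.coords[reference_frame][sel_r.indices]
    out = np.empty(traj.n_frames)
    local = Selection(np.arange(len(keys)))
    for k in range(traj.n_frames):
        mob = traj.coords[k][sel_t.indices]
        out[k] = superpose(mob, ref, local).rmsd
    return out


@dataclass
class MicroswitchPanel:
    """Per-frame series and summaries for every definition, per
    trajectory and pooled."""

    definitions: list[MicroswitchDefinition]
    series: dict[str, list[np.ndarray]]        # name -> per-trajectory series
    summary: pd.DataFrame

    def pooled(self, name: str) -> np.ndarray:
        return np.concatenate(self.series[name])


def panel(ensemble: list[Trajectory],
          definitions: list[MicroswitchDefinition] | None = None,
          reference: Trajectory | None = None,
          reference_frame: int = 0) -> MicroswitchPanel:
    """Evaluate the microswitch panel over an ensemble of trajectories.

    Returns per-frame series, per-trajectory median and IQR, and the
    pooled inactive fraction for every thresholded definition. An empty
    definition list yields an empty panel.
    """
    definitions = default_definitions() if definitions is None else definitions
    series: dict[str, list[np.ndarray]] = {}
    rows = []
    for d in definitions:
        per_traj = []
        for traj in ensemble:
            if d.kind == "distance":
                vals = atom_pair_series(traj, d)
            else:
                if reference is None:
                    raise ValueError(f"{d.name}: motif RMSD needs a reference")
                vals = motif_rmsd_series(traj, d, reference, reference_frame)
            per_traj.append(vals)
        series[d.name] = per_traj
        pooled = np.concatenate(per_traj) if per_traj else np.array([])
        verdict = d.is_inactive(pooled) if pooled.size else None
        for t_idx, vals in enumerate(per_traj):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({
                "name": d.name, "trajectory": t_idx, "median": med,
                "iqr": q3 - q1,
                "inactive_fraction": (float(np.mean(d.is_inactive(vals)))
                                      if verdict is not None else np.nan),
            })
        if per_traj:
            q1, med, q3 = np.percentile(pooled, [25, 50, 75])
            rows.append({
                "name": d.name, "trajectory": "pooled", "median": med,
                "iqr": q3 - q1,
                "inactive_fraction": (float(np.mean(verdict))
                                      if verdict is not None else np.nan),
            })
    summary = pd.DataFrame(rows, columns=["name", "trajectory", "median",
                                          "iqr", "inactive_fraction"])
    return MicroswitchPanel(definitions=definitions, series=series,
                            summary=summary)
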