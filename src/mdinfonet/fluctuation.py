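"""RMSD time series, per-residue RMSF, windowed RMSF QC and condition
differences.

RMSD is reported against frame 0 of each replicate (common reporting
convention); RMSF is referenced to the iterated pooled mean structure,
the same fluctuation reference used by the mutual-information stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mdinfonet.trajio import Selection, Trajectory, superpose


class EnsembleError(ValueError):
    """Trajectories of an ensemble do not share an atom table."""


@dataclass
class RMSDSeries:
    values: np.ndarray          # per-frame Angstrom
    times_ns: np.ndarray
    region: str = "All"
    align_label: str = ""


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Angstrom) over an aligned, pooled ensemble."""

    residue_keys: list[tuple[str, int]]
    values: np.ndarray
    n_frames: int = 0
    window_ns: tuple[float, float] | None = None
    condition: str = ""


def _check_shared_atoms(ensemble: list[Trajectory]) -> None:
    ref = ensemble[0].atoms
    for k, t in enumerate(ensemble[1:], start=1):
        if len(t.atoms) != len(ref) or any(
            (a.name, a.res_id, a.chain) != (b.name, b.res_id, b.chain)
            for a, b in zip(t.atoms, ref)
        ):
            raise EnsembleError(f"trajectory {k} atom table differs from trajectory 0")


def pool_frames(ensemble: list[Trajectory]) -> np.ndarray:
    """Concatenate frames of replicate trajectories (frames, atoms, 3)."""
    _check_shared_atoms(ensemble)
    return np.concatenate([t.coords for t in ensemble], axis=0)


def _batch_fit(frames: np.ndarray, ref: np.ndarray,
               idx: np.ndarray) -> np.ndarray:
    """Kabsch-superpose every frame onto ref over the index set, applying
    the per-frame transform to all atoms (batched SVD)."""
    sub = frames[:, idx, :]
    mob_mean = sub.mean(axis=1, keepdims=True)
    ref_sub = ref[idx]
    ref_mean = ref_sub.mean(axis=0)
    P = sub - mob_mean
    H = np.einsum("tni,nj->tij", P, ref_sub - ref_mean)
    U, _, Vt = np.linalg.svd(H)
    V = np.transpose(Vt, (0, 2, 1))
    Ut = np.transpose(U, (0, 2, 1))
    d = np.sign(np.linalg.det(V @ Ut))
    D = np.zeros_like(H)
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = V @ D @ Ut
    centered = frames - mob_mean
    return np.einsum("tij,tnj->tni", R, centered) + ref_mean


def align_to_mean(frames: np.ndarray, sel: Selection,
                  tol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Iteratively superpose frames onto their evolving mean structure.

    Each iteration fits every frame onto the current mean over ``sel``
    and recomputes the mean, until the mean moves by less than ``tol``
    Angstrom (max coordinate change). Returns the aligned copy.
    """
    out = np.array(frames, dtype=float, copy=True)
    ref = out[0]
    for _ in range(max_iter):
        out = _batch_fit(out, ref, sel.indices)
        new_mean = out.mean(axis=0)
        shift = float(np.max(np.abs(new_mean - ref)))
        ref = new_mean
        if shift < tol:
            break
    return out


def rmsd_series(traj: Trajectory, align_sel: Selection,
                measure_sel: Selection, reference_frame: int = 0,
                region: str = "All") -> RMSDSeries:
    """Per-frame RMSD after superposing each frame on a reference frame.

    Alignment is computed over ``align_sel``; the deviation is measured
    over ``measure_sel`` (e.g. align on the stable core, measure over
    ICL3 to isolate loop motion).
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range "
                         f"(0..{traj.n_frames - 1})")
    ref = traj.coords[reference_frame]
    vals = np.empty(traj.n_frames)
    mi = measure_sel.indices
    for k in range(traj.n_frames):
        fitted = superpose(traj.coords[k], ref, align_sel).apply(traj.coords[k])
        vals[k] = np.sqrt(np.mean(np.sum((fitted[mi] - ref[mi]) ** 2, axis=1)))
    times = np.arange(traj.n_frames) * traj.frame_spacing
    return RMSDSeries(values=vals, times_ns=times, region=region,
                      align_label=align_sel.label)


def _rmsf_from_frames(frames: np.ndarray, sel: Selection) -> np.ndarray:
    aligned = align_to_mean(frames, sel)
    sub = aligned[:, sel.indices, :]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def rmsf_profile(ensemble: list[Trajectory], sel: Selection,
                 condition: str = "") -> RMSFProfile:
    """RMSF per selected atom over the pooled replicate frames.

    Frames of all replicates are pooled, aligned to the iterated pooled
    mean, and RMSF_i = sqrt(<|r_i - <r_i>|^2>) is computed per selected
    atom (one Calpha per residue in the usual use).
    """
    frames = pool_frames(ensemble)
    vals = _rmsf_from_frames(frames, sel)
    keys = [ensemble[0].atoms[i].residue_key for i in sel.indices]
    return RMSFProfile(residue_keys=keys, values=vals,
                       n_frames=frames.shape[0], condition=condition)


def windowed_rmsf(ensemble: list[Trajectory], sel: Selection,
                  window_ns: float) -> list[RMSFProfile]:
    """Non-overlapping consecutive time windows of RMSF, per replicate,
    pooled across replicates window-by-window; the trailing partial
    window is dropped. Used as a stationarity QC (25 ns windows over a
    100 ns production run give four windows of 625 frames at 0.04
    ns/frame)."""
    _check_shared_atoms(ensemble)
    spacing = ensemble[0].frame_spacing
    wlen = int(round(window_ns / spacing))
    if abs(wlen * spacing - window_ns) > 1e-9:
        raise ValueError(f"window {window_ns} ns is not a multiple of the "
                         f"frame spacing {spacing} ns")
    if wlen < 2:
        raise ValueError("window must span at least 2 frames")
    n_frames = min(t.n_frames for t in ensemble)
    n_windows = n_frames // wlen
    out: list[RMSFProfile] = []
    keys = [ensemble[0].atoms[i].residue_key for i in sel.indices]
    for w in range(n_windows):
        lo, hi = w * wlen, (w + 1) * wlen
        frames = np.concatenate([t.coords[lo:hi] for t in ensemble], axis=0)
        vals = _rmsf_from_frames(frames, sel)
        out.append(RMSFProfile(residue_keys=keys, values=vals,
                               n_frames=frames.shape[0],
                               window_ns=(lo * spacing, hi * spacing)))
    return out


def delta_rmsf(profile_a: RMSFProfile, profile_b: RMSFProfile,
               regions: dict[str, set[int]] | None = None):
    """Per-residue RMSF difference a - b, with max |delta| per named region.

    Regions map a label to a set of residue ids (e.g. the ICL3 core).
    Returns (delta_values, region_max) where delta is antisymmetric in
    the two profiles by construction.
    """
    if profile_a.residue_keys != profile_b.residue_keys:
        raise ValueError("RMSF profiles cover different residues")
    delta = profile_a.values - profile_b.values
    region_max: dict[str, float] = {}
    if regions:
        for label, resids in regions.items():
            mask = np.array([rk[1] in resids for rk in profile_a.residue_keys])
            region_max[label] = float(np.max(np.abs(delta[mask]))) if mask.any() else 0.0
    return delta, region_max


def rmsf_table(profile: RMSFProfile,
               regions: dict[str, set[int]] | None = None):
    """Tidy per-residue table: residue id, region label, RMSF (Angstrom)."""
    import pandas as pd

    labels = []
    for chain, rid in profile.residue_keys:
        lab = ""
        if regions:
            for name, resids in regions.items():
                if rid in resids:
                    lab = name
                    break
        labels.append(lab)
    return pd.DataFrame({
        "chain": [c for c, _ in profile.residue_keys],
        "res_id": [r for _, r in profile.residue_keys],
        "region": labels,
        "rmsf_A": profile.values,
    })
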