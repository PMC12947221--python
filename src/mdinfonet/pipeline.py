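"""End-to-end orchestration from a single YAML config.

Stages run in dependency order (I/O -> fluctuation / PCA / contacts &
H-bonds / microswitches -> mutual information -> network); every output
table is plain text and the run manifest records parameters, seeds,
input digests and per-file content digests, so re-running an identical
config reproduces identical bytes for every deterministic stage.

Use from Python:

    from mdinfonet.pipeline import PipelineConfig, run
    manifest = run(PipelineConfig.from_yaml("config.yaml"))

or from a shell: ``python -m mdinfonet.pipeline config.yaml``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mdinfonet import (
    HBondCriteria, NetworkConfig, Selection, build_graph, contact_map,
    degree_centrality, betweenness_centrality, default_definitions,
    hbond_table, mi_matrix_calpha, panel, read_pdb_trajectory, rmsd_series,
    rmsf_profile, fit_pca, project, rmsf_along_pc,
)
from mdinfonet.infotheory import aggregate_mi, mi_matrix_dihedral
from mdinfonet.microswitches import MicroswitchDefinition
from mdinfonet.minet import distance_matrix, edge_table
from mdinfonet.fluctuation import rmsf_table
from mdinfonet import synthetic
from mdinfonet.trajio import write_pdb_trajectory

log = logging.getLogger("mdinfonet.pipeline")

#: shipped stage parameter defaults (all overridable in the config)
DEFAULTS = {
    "hbond_min_angle_deg": 120.0,
    "hbond_max_ha_distance": 2.5,
    "hbond_min_frequency": 0.001,
    "contact_cutoff": 6.0,
    "contact_persistence": 0.75,
    "bin_convergence_tol": 0.02,
    "mi_threshold": 0.25,
    "network_distance_cutoff": 6.0,
    "network_min_separation": 6,
    "dihedral_min_separation": 5,
    "ionic_lock_threshold": 10.5,
    "yy_gate_threshold": 14.6,
    "npxxy_threshold": 2.0,
    "pif_threshold": 2.2,
    "rmsip_k": 5,
}

ALL_STAGES = ["simulate", "fluct", "pca", "hbonds", "contacts",
              "microswitch", "mi-calpha", "mi-dihedral", "network"]


@dataclass
class PipelineConfig:
    output_dir: Path
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    trajectories: dict[str, list[Path]] = field(default_factory=dict)
    reference: Path | None = None
    simulate: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    regions: dict[str, list[int]] = field(default_factory=dict)
    microswitch_definitions: list[dict] = field(default_factory=list)
    frame_spacing: float = 0.04

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = PipelineConfig(
            output_dir=Path(raw.get("output_dir", "mdinfonet_out")),
            stages=raw.get("stages", list(ALL_STAGES)),
            seed=int(raw.get("seed", 0)),
            trajectories={c: [Path(p) for p in ps]
                          for c, ps in (raw.get("trajectories") or {}).items()},
            reference=Path(raw["reference"]) if raw.get("reference") else None,
            simulate=raw.get("simulate") or {},
            parameters=raw.get("parameters") or {},
            regions=raw.get("regions") or {},
            microswitch_definitions=raw.get("microswitch_definitions") or [],
            frame_spacing=float(raw.get("frame_spacing", 0.04)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for cond, paths in self.trajectories.items():
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{cond}: {p}")
        if self.reference is not None and not Path(self.reference).exists():
            raise FileNotFoundError(str(self.reference))
        for k in self.parameters:
            if k not in DEFAULTS:
                raise ValueError(f"unknown parameter {k!r}")

    def param(self, key: str):
        return self.parameters.get(key, DEFAULTS[key])


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["outputs"][path.name] = _digest(path)


def _write_matrix(mat: np.ndarray, path: Path, manifest: dict) -> None:
    np.savetxt(path, mat, fmt="%.6g")
    manifest["outputs"][path.name] = _digest(path)


def _simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> dict:
    """Generate per-condition synthetic replicate ensembles (plus an
    H-bond scene and a microswitch scene), written as multi-model PDB
    so downstream stages exercise the real reader path."""
    sim = cfg.simulate
    n_res = int(sim.get("n_res", 30))
    n_frames = int(sim.get("n_frames", 300))
    n_rep = int(sim.get("n_replicates", 2))
    conditions = sim.get("conditions", {"control": {"blocks": []}})
    paths: dict[str, list[Path]] = {}
    for c_idx, (cond, spec) in enumerate(sorted(conditions.items())):
        blocks = [synthetic.CorrelationBlock(residues=b["residues"],
                                             rho=float(b["rho"]))
                  for b in spec.get("blocks", [])]
        paths[cond] = []
        for r in range(n_rep):
            traj, _ = synthetic.gen_gaussian_traj(synthetic.GaussianTrajSpec(
                n_res=n_res, n_frames=n_frames,
                sigma=float(sim.get("sigma", 0.5)), blocks=blocks,
                seed=cfg.seed + 1000 * c_idx + r,
                frame_spacing=cfg.frame_spacing))
            p = out / f"sim_{cond}_rep{r}.pdb"
            write_pdb_trajectory(traj, p)
            manifest["outputs"][p.name] = _digest(p)
            paths[cond].append(p)
    scene, _ = synthetic.gen_hbond_scene(synthetic.HBondSceneSpec(
        occupancies=list(sim.get("hbond_occupancies", [0.3])),
        n_frames=n_frames, seed=cfg.seed + 77))
    p = out / "sim_hbond_scene.pdb"
    write_pdb_trajectory(scene, p)
    manifest["outputs"][p.name] = _digest(p)
    paths["hbond_scene"] = [p]
    switch, _ = synthetic.gen_switch_scene(
        float(sim.get("switch_inactive_fraction", 0.5)), n_frames,
        seed=cfg.seed + 99)
    p = out / "sim_switch_scene.pdb"
    write_pdb_trajectory(switch, p)
    manifest["outputs"][p.name] = _digest(p)
    paths["switch_scene"] = [p]
    return paths


def run(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    manifest: dict = {
        "seed": cfg.seed,
        "stages": cfg.stages,
        "parameters": {k: cfg.param(k) for k in DEFAULTS},
        "inputs": {},
        "outputs": {},
        "completed": [],
    }
    traj_paths = dict(cfg.trajectories)
    if "simulate" in cfg.stages:
        log.info("stage simulate")
        traj_paths.update(_simulate(cfg, out, manifest))
        manifest["completed"].append("simulate")

    ensembles: dict[str, list] = {}
    for cond, paths in traj_paths.items():
        ensembles[cond] = [read_pdb_trajectory(p, cfg.frame_spacing)
                           for p in paths]
        for p in paths:
            manifest["inputs"][str(p)] = _digest(Path(p))
        for t in ensembles[cond]:
            log.info("loaded %s: %d frames, %d atoms, hydrogens=%s",
                     cond, t.n_frames, t.n_atoms, t.has_hydrogens)

    analysis_conds = {
        c: e for c, e in ensembles.items()
        if all(sum(a.name == "CA" for a in t.atoms) >= 3 for t in e)
    }

    try:
        if "fluct" in cfg.stages:
            log.info("stage fluct")
            for cond, ens in analysis_conds.items():
                sel = Selection.calpha(ens[0])
                if len(sel) < 3:
                    continue
                prof = rmsf_profile(ens, sel, condition=cond)
                regions = {k: set(range(v[0], v[1] + 1))
                           for k, v in cfg.regions.items()}
                _write(rmsf_table(prof, regions),
                       out / f"rmsf_{cond}.tsv", manifest)
                for r, traj in enumerate(ens):
                    series = rmsd_series(traj, sel, sel, 0)
                    _write(pd.DataFrame({"time_ns": series.times_ns,
                                         "rmsd_A": series.values}),
                           out / f"rmsd_{cond}_rep{r}.tsv", manifest)
            manifest["completed"].append("fluct")

        models = {}
        if "pca" in cfg.stages:
            log.info("stage pca")
            for cond, ens in analysis_conds.items():
                sel = Selection.calpha(ens[0])
                if len(sel) < 3:
                    continue
                model = fit_pca(ens, sel)
                models[cond] = (model, ens, sel)
                _write(pd.DataFrame({
                    "mode": np.arange(1, model.n_modes + 1),
                    "eigenvalue_A2": model.eigenvalues,
                    "cumulative_ratio": model.cumulative_ratio,
                }), out / f"pca_spectrum_{cond}.tsv", manifest)
                k = min(cfg.param("rmsip_k"), model.n_modes)
                _write_matrix(model.eigenvectors[:, :k],
                              out / f"pca_modes_{cond}.txt", manifest)
                from mdinfonet.fluctuation import pool_frames
                frames = pool_frames(ens)
                p1 = project(frames, model, 0, prealigned=False)
                p2 = project(frames, model, 1, prealigned=False)
                _write(pd.DataFrame({"frame": np.arange(p1.values.size),
                                     "pc1": p1.values, "pc2": p2.values}),
                       out / f"pca_proj_{cond}.tsv", manifest)
            manifest["completed"].append("pca")

        if "hbonds" in cfg.stages:
            log.info("stage hbonds")
            criteria = HBondCriteria(
                min_angle_deg=cfg.param("hbond_min_angle_deg"),
                max_ha_distance=cfg.param("hbond_max_ha_distance"),
                min_frequency=cfg.param("hbond_min_frequency"))
            for cond, ens in ensembles.items():
                if not ens[0].has_hydrogens:
                    log.info("hbonds: %s has no hydrogens, skipped", cond)
                    continue
                table = hbond_table(ens, criteria)
                _write(table.to_frame(), out / f"hbonds_{cond}.tsv", manifest)
                _write(table.per_residue_counts(),
                       out / f"hbonds_{cond}_residues.tsv", manifest)
                _write(table.occupancy_weighted_counts(),
                       out / f"hbonds_{cond}_weighted.tsv", manifest)
            manifest["completed"].append("hbonds")

        if "contacts" in cfg.stages:
            log.info("stage contacts")
            for cond, ens in analysis_conds.items():
                cm = contact_map(ens, cfg.param("contact_cutoff"),
                                 cfg.param("contact_persistence"))
                _write_matrix(cm.fraction,
                              out / f"contact_fraction_{cond}.txt", manifest)
                _write(cm.pair_list(), out / f"contacts_{cond}.tsv", manifest)
            manifest["completed"].append("contacts")

        if "microswitch" in cfg.stages:
            log.info("stage microswitch")
            defs = ([MicroswitchDefinition(
                        name=d["name"], kind=d["kind"],
                        atoms=[tuple(a) for a in d.get("atoms", [])],
                        motif_res_ids=d.get("motif_res_ids", []),
                        comparator=d.get("comparator"),
                        threshold=d.get("threshold"))
                     for d in cfg.microswitch_definitions]
                    if cfg.microswitch_definitions else None)
            reference = (read_pdb_trajectory(cfg.reference)
                         if cfg.reference else None)
            targets = (ensembles if defs is not None
                       else {})   # default beta2AR panel needs real IDs
            for cond, ens in targets.items():
                try:
                    pn = panel(ens, defs, reference)
                except (KeyError, ValueError) as exc:
                    log.info("microswitch: %s skipped (%s)", cond, exc)
                    continue
                _write(pn.summary, out / f"microswitch_{cond}.tsv", manifest)
            manifest["completed"].append("microswitch")

        mi_mats = {}
        if "mi-calpha" in cfg.stages:
            log.info("stage mi-calpha")
            for cond, ens in analysis_conds.items():
                sel = Selection.calpha(ens[0])
                if len(sel) < 3:
                    continue
                mat = mi_matrix_calpha(ens, sel)
                mi_mats[cond] = (mat, ens, sel)
                _write_matrix(mat.matrix, out / f"mi_calpha_{cond}.txt",
                              manifest)
                _write(mat.to_pairs(), out / f"mi_calpha_{cond}_pairs.tsv",
                       manifest)
                _write(aggregate_mi(mat, "residue_mean"),
                       out / f"mi_calpha_{cond}_residue_mean.tsv", manifest)
            manifest["completed"].append("mi-calpha")

        if "network" in cfg.stages:
            log.info("stage network")
            ncfg = NetworkConfig(
                mi_threshold=cfg.param("mi_threshold"),
                distance_cutoff=cfg.param("network_distance_cutoff"),
                min_separation=cfg.param("network_min_separation"))
            for cond, (mat, ens, sel) in mi_mats.items():
                dist = distance_matrix(ens, sel)
                g = build_graph(mat, dist, ncfg)
                _write(edge_table(g), out / f"network_edges_{cond}.tsv",
                       manifest)
                deg = degree_centrality(g)
                btw = betweenness_centrality(g)
                deg["betweenness_centrality"] = \
                    btw["betweenness_centrality"].values
                _write(deg, out / f"network_centrality_{cond}.tsv", manifest)
            manifest["completed"].append("network")

        if "mi-dihedral" in cfg.stages:
            log.info("stage mi-dihedral")
            for cond, ens in analysis_conds.items():
                # needs full side-chain atoms; Calpha-only input has no
                # dihedrals, so emit nothing rather than zeros
                has_sidechains = any(a.name == "CB" for a in ens[0].atoms)
                if not has_sidechains:
                    log.info("mi-dihedral: %s lacks side chains, skipped",
                             cond)
                    continue
                sel = Selection.calpha(ens[0])
                mat = mi_matrix_dihedral(
                    ens, sel, min_separation=cfg.param(
                        "dihedral_min_separation"))
                _write_matrix(np.nan_to_num(mat.matrix),
                              out / f"mi_dihedral_{cond}.txt", manifest)
                for scheme in ("type_mean", "class_mean", "class_pair",
                               "chi_count_mean"):
                    _write(aggregate_mi(mat, scheme),
                           out / f"mi_dihedral_{cond}_{scheme}.tsv", manifest)
            manifest["completed"].append("mi-dihedral")
    except Exception as exc:     # manifest records partial completion
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def main(argv: list[str] | None = None) -> int:
    import argparse

    ap = argparse.ArgumentParser(
        description="Run the trajectory-analysis pipeline from a YAML config")
    ap.add_argument("config", help="pipeline YAML configuration")
    args = ap.parse_args(argv)
    run(PipelineConfig.from_yaml(args.config))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
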