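"""End-to-end orchestration: forces -> averages -> difference -> stress
-> network -> geometry -> reports.

A single YAML config drives the run; every tabular output is CSV with a
unit-bearing header, and a JSON manifest records versions, seeds and
stage counts.  Outputs are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fda_stats import (
    AveragedPairForces,
    ForceDifference,
    average_ensemble,
    force_difference,
    punctual_stress,
)
from .force_network import (
    DEFAULT_CUTOFF_PN,
    build_graph,
    extract_pathways,
    largest_component,
    scan_cutoffs,
)
from .geometry import AngleTriplet, angle_difference, angle_profile, detect_hbonds
from .model_io.pdb import load_trajectory_pdb, write_stress_pdb
from .model_io.topology import load_topology
from .model_io.types import TrajectoryEnsemble, ValidationError
from .model_io.xyz import read_xyz_trajectory
from .pairforce.engine import PairForceEngine

logger = logging.getLogger("fdanet")

DEFAULT_CUTOFF_GRID = [10, 15, 20, 25, 30, 35, 40, 50, 60, 70, 80, 90, 110, 130, 160, 200, 300]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    topology_apo: Path
    topology_holo: Path
    trajectories_apo: List[Path]
    trajectories_holo: List[Path]
    output_dir: Path
    structure: Optional[Path] = None
    cutoff_grid: List[float] = field(default_factory=lambda: list(DEFAULT_CUTOFF_GRID))
    default_cutoff_pN: float = DEFAULT_CUTOFF_PN
    nonbonded_cutoff_nm: float = 6.0
    min_seq_separation: int = 0
    sources: List[int] = field(default_factory=list)
    targets: List[int] = field(default_factory=list)
    angle_triplets: List[str] = field(default_factory=list)
    hbond_donors: List[int] = field(default_factory=list)
    hbond_acceptors: List[int] = field(default_factory=list)
    hbond_d_max_A: float = 3.5
    hbond_angle_min_deg: float = 120.0
    hbond_min_occupancy: float = 0.5
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        try:
            return cls._from_dict(raw, base)
        except KeyError as exc:
            raise ConfigError(f"{path}: missing config key {exc}")

    @classmethod
    def _from_dict(cls, raw: dict, base: Path) -> "RunConfig":
        def p(v) -> Path:
            q = Path(v)
            return q if q.is_absolute() else base / q

        groups = raw.get("groups", {})
        hbonds = raw.get("hbonds", {})
        return cls(
            topology_apo=p(raw["topology_apo"]),
            topology_holo=p(raw["topology_holo"]),
            trajectories_apo=[p(v) for v in raw["trajectories_apo"]],
            trajectories_holo=[p(v) for v in raw["trajectories_holo"]],
            output_dir=p(raw["output_dir"]),
            structure=p(raw["structure"]) if raw.get("structure") else None,
            cutoff_grid=list(raw.get("cutoff_grid", DEFAULT_CUTOFF_GRID)),
            default_cutoff_pN=float(raw.get("default_cutoff_pN", DEFAULT_CUTOFF_PN)),
            nonbonded_cutoff_nm=float(raw.get("nonbonded_cutoff_nm", 6.0)),
            min_seq_separation=int(raw.get("min_seq_separation", 0)),
            sources=list(groups.get("sources", [])),
            targets=list(groups.get("targets", [])),
            angle_triplets=list(raw.get("angle_triplets", [])),
            hbond_donors=list(hbonds.get("donors", [])),
            hbond_acceptors=list(hbonds.get("acceptors", [])),
            hbond_d_max_A=float(hbonds.get("d_max_A", 3.5)),
            hbond_angle_min_deg=float(hbonds.get("angle_min_deg", 120.0)),
            hbond_min_occupancy=float(hbonds.get("min_occupancy", 0.5)),
            seed=int(raw.get("seed", 1)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def validate(self) -> None:
        missing = [
            str(f)
            for f in [self.topology_apo, self.topology_holo]
            + self.trajectories_apo
            + self.trajectories_holo
            + ([self.structure] if self.structure else [])
            if not Path(f).exists()
        ]
        if missing:
            raise ConfigError(f"missing input files: {', '.join(missing)}")
        if not self.trajectories_apo or not self.trajectories_holo:
            raise ConfigError("need at least one trajectory per state")
        if sorted(self.cutoff_grid) != list(self.cutoff_grid):
            raise ConfigError("cutoff grid must be sorted ascending")


def load_ensemble(paths: Sequence[Path], state_label: str) -> TrajectoryEnsemble:
    """Read one replica per trajectory file (extended XYZ or multi-model PDB)."""
    replicas = []
    for path in paths:
        path = Path(path)
        if path.suffix.lower() == ".pdb":
            _, frames = load_trajectory_pdb(path)
        else:
            frames = read_xyz_trajectory(path)
        replicas.append(frames)
    return TrajectoryEnsemble(replicas=replicas, state_label=state_label)


# ----------------------------------------------------------------------
# CSV writers (every table carries units in its header)
# ----------------------------------------------------------------------
def averaged_to_frame(avg: AveragedPairForces) -> pd.DataFrame:
    gm, sd = avg.grand_mean, avg.sd
    rows = [
        (i, j, gm[s], sd[s], avg.n_replicas)
        for (i, j), s in sorted(avg.pair_index.items())
    ]
    return pd.DataFrame(rows, columns=["i", "j", "mean_pN", "sd_pN", "n_replicas"])


def frame_to_averaged(df: pd.DataFrame, state_label: str = "") -> AveragedPairForces:
    from .fda_stats import average_from_arrays

    keys = [(int(r.i), int(r.j)) for r in df.itertuples()]
    means = df["mean_pN"].to_numpy()[None, :]
    return average_from_arrays(keys, means, [0], state_label=state_label)


def diff_to_frame(diff: ForceDifference) -> pd.DataFrame:
    rows = [(i, j, v) for (i, j), v in sorted(diff.items())]
    return pd.DataFrame(rows, columns=["i", "j", "delta_pN"])


def frame_to_diff(df: pd.DataFrame) -> ForceDifference:
    return ForceDifference(
        data={(int(r.i), int(r.j)): float(r.delta_pN) for r in df.itertuples()}
    )


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


# ----------------------------------------------------------------------
# the pipeline
# ----------------------------------------------------------------------
def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute all stages; returns a name -> path map of artifacts."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    manifest: Dict[str, object] = {
        "fdanet_version": __version__,
        "seed": config.seed,
        "default_cutoff_pN": config.default_cutoff_pN,
        "stages": {},
    }

    def record(name: str, path: Path, **counts) -> None:
        artifacts[name] = path
        manifest["stages"][name] = {"path": str(path), **counts}
        logger.info("stage %s -> %s %s", name, path, counts or "")

    apo_sys = load_topology(config.topology_apo)
    holo_sys = load_topology(config.topology_holo)
    ens_apo = load_ensemble(config.trajectories_apo, "apo")
    ens_holo = load_ensemble(config.trajectories_holo, "holo")
    if ens_apo.n_atoms != apo_sys.n_atoms or ens_holo.n_atoms != holo_sys.n_atoms:
        raise ValidationError("trajectory atom count does not match topology")

    eng_apo = PairForceEngine(apo_sys, config.nonbonded_cutoff_nm)
    eng_holo = PairForceEngine(holo_sys, config.nonbonded_cutoff_nm)

    avg_apo = average_ensemble(eng_apo, ens_apo, "apo")
    avg_holo = average_ensemble(eng_holo, ens_holo, "holo")
    path = out / "averaged_apo.csv"
    _csv(averaged_to_frame(avg_apo), path)
    record("averaged_apo", path, n_pairs=len(avg_apo.pair_index))
    path = out / "averaged_holo.csv"
    _csv(averaged_to_frame(avg_holo), path)
    record("averaged_holo", path, n_pairs=len(avg_holo.pair_index))

    diff = force_difference(avg_apo, avg_holo)
    path = out / "force_difference.csv"
    _csv(diff_to_frame(diff), path)
    record("force_difference", path, n_pairs=len(diff))

    residue_of = holo_sys.residue_of
    stress = punctual_stress(diff, residue_of=residue_of)
    path = out / "stress_atoms.csv"
    _csv(
        pd.DataFrame(
            sorted(stress.atom_stress.items()), columns=["atom", "stress_pN"]
        ),
        path,
    )
    record("stress_atoms", path, n_atoms=len(stress.atom_stress))
    path = out / "stress_residues.csv"
    _csv(
        pd.DataFrame(
            sorted(stress.residue_stress.items()), columns=["residue", "stress_pN"]
        ),
        path,
    )
    record("stress_residues", path)

    ref_frame = ens_holo.replicas[0][0]
    path = out / "stress.pdb"
    write_stress_pdb(holo_sys, ref_frame, stress.as_array(holo_sys.n_atoms), path)
    record("stress_pdb", path)

    sources = config.sources or holo_sys.groups.get("sources", [])
    targets = config.targets or holo_sys.groups.get("targets", [])
    source_res = sorted({residue_of[a] for a in sources}) if sources else []
    target_res = sorted({residue_of[a] for a in targets}) if targets else []
    if source_res and target_res:
        scan = scan_cutoffs(
            diff,
            residue_of,
            source_res,
            target_res,
            config.cutoff_grid,
            min_seq_separation=config.min_seq_separation,
        )
        path = out / "cutoff_scan.csv"
        _csv(
            pd.DataFrame(
                [
                    (r.cutoff_pN, r.vertex_count, r.n_components, r.connected)
                    for r in scan.rows
                ],
                columns=["cutoff_pN", "vertex_count", "n_components", "connected"],
            ),
            path,
        )
        record("cutoff_scan", path, recommended=scan.recommended_cutoff_pN)
        manifest["recommended_cutoff_pN"] = scan.recommended_cutoff_pN

        graph = build_graph(
            diff,
            residue_of,
            config.default_cutoff_pN,
            min_seq_separation=config.min_seq_separation,
        )
        path = out / "edges.csv"
        _csv(
            pd.DataFrame(graph.edges, columns=["residue_u", "residue_v", "weight_pN"]),
            path,
        )
        record("edges", path, n_edges=len(graph.edges))

        lcc, count = largest_component(graph)
        pathways = extract_pathways(lcc, source_res, target_res)
        path = out / "pathways.txt"
        with open(path, "w") as fh:
            fh.write(f"# pathways at cutoff {config.default_cutoff_pN} pN (residues)\n")
            fh.write(f"# largest component vertex count: {count}\n")
            for chain in pathways.paths:
                fh.write(" -> ".join(str(r) for r in chain) + "\n")
            for s, t in pathways.unreachable:
                fh.write(f"# unreachable: {s} -> {t}\n")
        record("pathways", path, n_paths=len(pathways.paths))

    rows = []
    for text in config.angle_triplets:
        triplet = AngleTriplet.parse(text)
        prof_a = angle_profile(ens_apo, apo_sys, triplet)
        prof_h = angle_profile(ens_holo, holo_sys, triplet)
        d = angle_difference(prof_a, prof_h)
        rows.append(
            (
                triplet.label,
                *triplet.residues,
                prof_a.mean,
                prof_a.sd,
                prof_h.mean,
                prof_h.sd,
                *d.rounded,
            )
        )
    if rows:
        path = out / "angles.csv"
        _csv(
            pd.DataFrame(
                rows,
                columns=[
                    "label",
                    "res_i",
                    "res_j",
                    "res_k",
                    "apo_mean_deg",
                    "apo_sd_deg",
                    "holo_mean_deg",
                    "holo_sd_deg",
                    "diff_deg",
                    "diff_sd_deg",
                ],
            ),
            path,
        )
        record("angles", path, n_triplets=len(rows))

    if config.hbond_donors and config.hbond_acceptors:
        hrows = []
        for label, ens, system in (("apo", ens_apo, apo_sys), ("holo", ens_holo, holo_sys)):
            for hb in detect_hbonds(
                ens,
                system,
                config.hbond_donors,
                config.hbond_acceptors,
                d_max_A=config.hbond_d_max_A,
                angle_min_deg=config.hbond_angle_min_deg,
                min_occupancy=config.hbond_min_occupancy,
            ):
                hrows.append(
                    (label, hb.donor, hb.acceptor, hb.mean_distance_A, hb.occupancy)
                )
        path = out / "hbonds.csv"
        _csv(
            pd.DataFrame(
                hrows,
                columns=["state", "donor", "acceptor", "mean_distance_A", "occupancy"],
            ),
            path,
        )
        record("hbonds", path, n_bonds=len(hrows))

    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = path
    return artifacts
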