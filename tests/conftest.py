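"""Shared fixtures: random small systems and the (expensive) benchmark."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from fdanet.fda_stats import average_ensemble, force_difference
from fdanet.force_network import build_graph, largest_component, scan_cutoffs
from fdanet.model_io.types import AtomRecord, Frame, MolecularSystem
from fdanet.pairforce.engine import PairForceEngine
from fdanet.synthetic_system import (
    TwoDomainSpec,
    build_two_domain_system,
    make_holo,
    negative_control_spec,
    sample_ensemble,
)

CUTOFF_GRID = [10, 15, 20, 25, 30, 35, 40, 50, 60, 70, 80, 90, 110, 130, 160, 200, 300]


def make_random_system(rng: np.random.Generator, n_atoms: int = 20):
    """Random parameterized system with all five interaction kinds.

    Coordinates are drawn with a minimum separation so LJ cores and
    finite differences stay well conditioned.
    """
    coords = []
    while len(coords) < n_atoms:
        cand = rng.uniform(0, 2.0, size=3)
        if all(np.linalg.norm(cand - c) > 0.25 for c in coords):
            coords.append(cand)
    coords = np.array(coords)

    atoms = [
        AtomRecord(
            atom_index=i + 1,
            atom_name="X",
            element="C",
            residue_index=i // 2 + 1,
            residue_name="UNK",
            charge=float(rng.uniform(-0.5, 0.5)),
            lj_sigma=0.3,
            lj_epsilon=0.2,
        )
        for i in range(n_atoms)
    ]
    bonds = []
    for i in range(1, n_atoms):
        r0 = float(np.linalg.norm(coords[i - 1] - coords[i]) * rng.uniform(0.9, 1.1))
        bonds.append((i, i + 1, float(rng.uniform(500, 2000)), r0))
    angles = []
    for i in range(1, n_atoms - 1, 4):
        angles.append((i, i + 1, i + 2, float(rng.uniform(50, 300)), float(rng.uniform(80, 150))))
    dihedrals = []
    for i in range(1, n_atoms - 2, 6):
        dihedrals.append(
            (i, i + 1, i + 2, i + 3, float(rng.uniform(2, 20)), int(rng.integers(1, 4)), float(rng.uniform(0, 360)))
        )
    system = MolecularSystem(atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals)
    system.rebuild_exclusions()
    system.validate()
    return system, Frame(coords)


@pytest.fixture(scope="session")
def benchmark():
    """Default-spec positive-control benchmark, sampled once per session."""
    spec = TwoDomainSpec(seed=1)
    apo, apo_frame, truth = build_two_domain_system(spec)
    holo, holo_frame = make_holo(apo, apo_frame, spec)
    truth.ligand_residues = {
        holo.atoms[i - 1].residue_index for i in holo.groups["ligand"]
    }
    eng_apo = PairForceEngine(apo, spec.nonbonded_cutoff_nm)
    eng_holo = PairForceEngine(holo, spec.nonbonded_cutoff_nm)
    ens_apo = sample_ensemble(apo, apo_frame, spec, state_label="apo", engine=eng_apo)
    ens_holo = sample_ensemble(holo, holo_frame, spec, state_label="holo", engine=eng_holo)
    avg_apo = average_ensemble(eng_apo, ens_apo)
    avg_holo = average_ensemble(eng_holo, ens_holo)
    diff = force_difference(avg_apo, avg_holo)
    residue_of = holo.residue_of
    scan = scan_cutoffs(
        diff,
        residue_of,
        sorted(truth.binding_residues),
        sorted(truth.hinge_pair),
        CUTOFF_GRID,
    )
    lcc = None
    if scan.recommended_cutoff_pN is not None:
        graph = build_graph(diff, residue_of, scan.recommended_cutoff_pN)
        lcc, _ = largest_component(graph)
    return {
        "spec": spec,
        "apo": apo,
        "holo": holo,
        "truth": truth,
        "ens_apo": ens_apo,
        "ens_holo": ens_holo,
        "diff": diff,
        "avg_apo": avg_apo,
        "avg_holo": avg_holo,
        "residue_of": residue_of,
        "scan": scan,
        "lcc": lcc,
    }


@pytest.fixture(scope="session")
def negative_benchmark():
    """Signal-free control at reduced sampling (noise calibration)."""
    spec = replace(negative_control_spec(TwoDomainSpec(seed=1)), n_replicas=3, n_frames=300)
    apo, apo_frame, truth = build_two_domain_system(spec)
    holo, holo_frame = make_holo(apo, apo_frame, spec)
    eng_apo = PairForceEngine(apo, spec.nonbonded_cutoff_nm)
    eng_holo = PairForceEngine(holo, spec.nonbonded_cutoff_nm)
    ens_apo = sample_ensemble(apo, apo_frame, spec, state_label="apo", engine=eng_apo)
    ens_holo = sample_ensemble(holo, holo_frame, spec, state_label="holo", engine=eng_holo)
    avg_apo = average_ensemble(eng_apo, ens_apo)
    avg_holo = average_ensemble(eng_holo, ens_holo)
    diff = force_difference(avg_apo, avg_holo)
    residue_of = holo.residue_of
    scan = scan_cutoffs(
        diff,
        residue_of,
        sorted(truth.binding_residues),
        sorted(truth.hinge_pair),
        CUTOFF_GRID,
    )
    return {"spec": spec, "truth": truth, "diff": diff, "residue_of": residue_of, "scan": scan}
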