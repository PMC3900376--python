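"""Minimal PDB reading/writing.

Only ATOM/HETATM/MODEL/ENDMDL/TER/REMARK records are interpreted.  A
hand-rolled fixed-column parser is used (rather than a full-featured
structure library) because the pipeline needs line-number-addressable
parse errors, a documented cross-chain renumbering rule with an audit
map, and control over the B-factor column for stress annotation.

Renumbering rule: residues are renumbered consecutively from 1 in file
order; a chain break or a jump in the author residue numbering starts a
new residue.  The original (chain, resSeq) of each renumbered residue is
retained in ``system.metadata["residue_audit"]``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import AtomRecord, Frame, MolecularSystem, ValidationError
from .units import ANGSTROM_PER_NM


class PDBParseError(ValueError):
    pass


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return {
            "record": line[:6].strip(),
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "resname": line[17:20].strip() or "UNK",
            "chain": line[21:22],
            "resseq": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "bfactor": float(line[60:66]) if line[60:66].strip() else 0.0,
            "element": line[76:78].strip(),
        }
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}")


def _guess_element(name: str) -> str:
    stripped = name.strip()
    return (stripped[:1] or "X").upper()


def load_structure(path) -> Tuple[MolecularSystem, Frame]:
    """Read the first model of a PDB file into a system and a frame.

    Coordinates are converted from Angstrom to nm.  Groups ``protein``
    (ATOM records), ``hetero`` (HETATM records) and one ``chain_<id>``
    per chain are populated.
    """
    systems, frames = _read_pdb(Path(path), first_model_only=True)
    return systems, frames[0]


def load_trajectory_pdb(path) -> Tuple[MolecularSystem, List[Frame]]:
    """Read a multi-model PDB as a trajectory (all models, one system)."""
    return _read_pdb(Path(path), first_model_only=False)


def _read_pdb(path: Path, first_model_only: bool) -> Tuple[MolecularSystem, List[Frame]]:
    atoms: List[AtomRecord] = []
    groups: Dict[str, List[int]] = {"protein": [], "hetero": []}
    audit: List[Tuple[str, int]] = []
    frames: List[Frame] = []
    coords: List[List[float]] = []
    first_model_done = False
    residue_counter = 0
    prev_key: Optional[Tuple[str, int]] = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "ENDMDL":
                if coords:
                    frames.append(Frame(np.array(coords) / ANGSTROM_PER_NM))
                    coords = []
                    first_model_done = True
                if first_model_only:
                    break
                continue
            if record not in ("ATOM", "HETATM"):
                continue
            parsed = _parse_atom_line(line, lineno)
            coords.append([parsed["x"], parsed["y"], parsed["z"]])
            if first_model_done:
                continue
            key = (parsed["chain"], parsed["resseq"])
            if key != prev_key:
                residue_counter += 1
                audit.append(key)
                prev_key = key
            idx = len(atoms) + 1
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=parsed["name"],
                    element=parsed["element"] or _guess_element(parsed["name"]),
                    residue_index=residue_counter,
                    residue_name=parsed["resname"],
                )
            )
            group = "protein" if parsed["record"] == "ATOM" else "hetero"
            groups[group].append(idx)
            chain_group = f"chain_{parsed['chain'].strip() or '_'}"
            groups.setdefault(chain_group, []).append(idx)

    if coords:
        frames.append(Frame(np.array(coords) / ANGSTROM_PER_NM))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    for i, frame in enumerate(frames):
        if frame.n_atoms != len(atoms):
            raise PDBParseError(
                f"{path}: model {i + 1} has {frame.n_atoms} atoms, "
                f"expected {len(atoms)}"
            )
    system = MolecularSystem(
        atoms=atoms,
        groups={k: v for k, v in groups.items() if v},
        metadata={"residue_audit": audit, "source": str(path)},
    )
    system.validate()
    return system, frames


def _format_atom_line(
    atom: AtomRecord, xyz_A: np.ndarray, bfactor: float, serial: int
) -> str:
    name = atom.atom_name
    # PDB convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:5d} {name_field}"
        f" {atom.residue_name[:3]:>3s} A{atom.residue_index % 10000:4d}    "
        f"{xyz_A[0]:8.3f}{xyz_A[1]:8.3f}{xyz_A[2]:8.3f}"
        f"{1.00:6.2f}{bfactor:6.2f}          "
        f"{atom.element[:2]:>2s}\n"
    )


def write_structure(
    system: MolecularSystem,
    frame: Frame,
    path,
    bfactors: Optional[Sequence[float]] = None,
    remarks: Optional[Sequence[str]] = None,
) -> None:
    """Write a single-model PDB file (coordinates converted nm -> A)."""
    if frame.n_atoms != system.n_atoms:
        raise ValidationError(
            f"frame has {frame.n_atoms} atoms but system has {system.n_atoms}"
        )
    bvals = np.zeros(system.n_atoms) if bfactors is None else np.asarray(bfactors, float)
    if bvals.shape != (system.n_atoms,):
        raise ValidationError("one B-factor per atom required")
    with open(path, "w") as fh:
        for remark in remarks or ():
            fh.write(f"REMARK 100 {remark}\n")
        for atom, xyz, b in zip(system.atoms, frame.coordinates, bvals):
            fh.write(_format_atom_line(atom, xyz * ANGSTROM_PER_NM, b, atom.atom_index))
        fh.write("TER\nEND\n")


def write_trajectory_pdb(system: MolecularSystem, frames: Sequence[Frame], path) -> None:
    """Write frames as a multi-model PDB trajectory."""
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for atom, xyz in zip(system.atoms, frame.coordinates):
                fh.write(
                    _format_atom_line(atom, xyz * ANGSTROM_PER_NM, 0.0, atom.atom_index)
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_stress_pdb(system: MolecularSystem, frame: Frame, values, path) -> float:
    """Write per-atom values into the B-factor column.

    Values are rescaled to [0, 99.99] so they survive the fixed-width
    field; the scale factor is recorded in a REMARK line and returned.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != (system.n_atoms,):
        raise ValidationError(
            f"got {vals.size} values for {system.n_atoms} atoms"
        )
    if not np.isfinite(vals).all():
        raise ValidationError("per-atom values must be finite")
    vmax = float(vals.max()) if vals.size else 0.0
    scale = 99.99 / vmax if vmax > 0 else 1.0
    write_structure(
        system,
        frame,
        path,
        bfactors=np.clip(vals * scale, 0.0, 99.99),
        remarks=[f"STRESS SCALE {scale:.6e} (bfactor = stress_pN * scale)"],
    )
    return scale


def read_bfactors(path) -> np.ndarray:
    """B-factor column of the first model (round-trip helper)."""
    out: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "ENDMDL":
                break
            if record in ("ATOM", "HETATM"):
                out.append(_parse_atom_line(line, lineno)["bfactor"])
    return np.array(out)
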