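"""Reader/writer for the minimal text topology dialect.

Sections, introduced by a bracketed header, hold whitespace-separated
columns; ``;`` and ``#`` start comments.  All indices are 1-based.

[atoms]       index  name  element  resid  resname  charge  sigma_nm  epsilon_kJmol
[bonds]       i  j  k_b_kJmolnm2  r0_nm
[angles]      i  j  k  k_theta_kJmolrad2  theta0_deg
[dihedrals]   i  j  k  l  k_phi_kJmol  multiplicity  phase_deg
[exclusions]  i  j          (explicit extras; 1-2/1-3 are auto-generated)
[groups]      name  i1 i2 ...

Exclusions are regenerated on load from the 1-2/1-3 rule over [bonds]
plus any explicit [exclusions] entries.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Set, Tuple

from .types import (
    AtomRecord,
    MolecularSystem,
    ValidationError,
    canonical_pair,
    generate_exclusions,
)


class TopologyParseError(ValueError):
    pass


_SECTIONS = ("atoms", "bonds", "angles", "dihedrals", "exclusions", "groups")


def load_topology(path) -> MolecularSystem:
    """Parse a topology file into a coordinate-free MolecularSystem."""
    path = Path(path)
    system = MolecularSystem(atoms=[])
    explicit: Set[Tuple[int, int]] = set()
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";")[0].split("#")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").lower()
                if section not in _SECTIONS:
                    raise TopologyParseError(
                        f"{path}:{lineno}: unknown section [{section}]"
                    )
                continue
            if section is None:
                raise TopologyParseError(f"{path}:{lineno}: data before any section")
            parts = line.split()
            try:
                _parse_row(system, explicit, section, parts)
            except (ValueError, IndexError) as exc:
                raise TopologyParseError(f"{path}:{lineno}: {exc}")
    system.metadata["explicit_exclusions"] = explicit
    system.exclusions = generate_exclusions(system.bonds, explicit)
    try:
        system.validate()
    except ValidationError as exc:
        raise TopologyParseError(f"{path}: {exc}")
    return system


def _parse_row(
    system: MolecularSystem,
    explicit: Set[Tuple[int, int]],
    section: str,
    parts: List[str],
) -> None:
    if section == "atoms":
        system.atoms.append(
            AtomRecord(
                atom_index=int(parts[0]),
                atom_name=parts[1],
                element=parts[2],
                residue_index=int(parts[3]),
                residue_name=parts[4],
                charge=float(parts[5]),
                lj_sigma=float(parts[6]),
                lj_epsilon=float(parts[7]),
            )
        )
    elif section == "bonds":
        system.bonds.append(
            (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]))
        )
    elif section == "angles":
        system.angles.append(
            (int(parts[0]), int(parts[1]), int(parts[2]), float(parts[3]), float(parts[4]))
        )
    elif section == "dihedrals":
        system.dihedrals.append(
            (
                int(parts[0]),
                int(parts[1]),
                int(parts[2]),
                int(parts[3]),
                float(parts[4]),
                int(parts[5]),
                float(parts[6]),
            )
        )
    elif section == "exclusions":
        explicit.add(canonical_pair(int(parts[0]), int(parts[1])))
    elif section == "groups":
        system.groups[parts[0]] = [int(v) for v in parts[1:]]


def write_topology(system: MolecularSystem, path) -> None:
    with open(path, "w") as fh:
        fh.write("[atoms]\n; index name element resid resname charge sigma epsilon\n")
        for a in system.atoms:
            fh.write(
                f"{a.atom_index} {a.atom_name} {a.element} {a.residue_index} "
                f"{a.residue_name} {a.charge:.6f} {a.lj_sigma:.6f} {a.lj_epsilon:.6f}\n"
            )
        fh.write("[bonds]\n; i j k_b r0\n")
        for i, j, kb, r0 in system.bonds:
            fh.write(f"{i} {j} {kb:.6f} {r0:.9f}\n")
        fh.write("[angles]\n; i j k k_theta theta0_deg\n")
        for i, j, k, kt, t0 in system.angles:
            fh.write(f"{i} {j} {k} {kt:.6f} {t0:.9f}\n")
        fh.write("[dihedrals]\n; i j k l k_phi mult phase_deg\n")
        for i, j, k, l, kp, mult, phase in system.dihedrals:
            fh.write(f"{i} {j} {k} {l} {kp:.6f} {mult} {phase:.9f}\n")
        explicit = system.metadata.get("explicit_exclusions", set())
        fh.write("[exclusions]\n; i j (explicit only)\n")
        for i, j in sorted(explicit):
            fh.write(f"{i} {j}\n")
        fh.write("[groups]\n; name members\n")
        for name, members in system.groups.items():
            fh.write(f"{name} " + " ".join(str(m) for m in members) + "\n")
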