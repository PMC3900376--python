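"""Domain types shared by every stage of the pipeline.

Atom and residue indices are 1-based everywhere user-facing (PDB
convention); the conversion to 0-based array rows happens only where
coordinates are indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np


class ValidationError(ValueError):
    pass


@dataclass
class AtomRecord:
    """A single particle with its nonbonded parameters.

    charge in elementary charges, lj_sigma in nm, lj_epsilon in kJ/mol.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValidationError(
                f"atom {self.atom_index}: LJ parameters must be non-negative"
            )


# Bonded term tuples (1-based atom indices, MD units):
#   bond:     (i, j, k_b kJ/mol/nm^2, r0 nm)
#   angle:    (i, j, k, k_theta kJ/mol/rad^2, theta0 degrees)
#   dihedral: (i, j, k, l, k_phi kJ/mol, multiplicity, phase degrees)
Bond = Tuple[int, int, float, float]
Angle = Tuple[int, int, int, float, float]
Dihedral = Tuple[int, int, int, int, float, int, float]


def canonical_pair(i: int, j: int) -> Tuple[int, int]:
    return (i, j) if i < j else (j, i)


def generate_exclusions(
    bonds: Sequence[Bond], extra: Optional[Set[Tuple[int, int]]] = None
) -> Set[Tuple[int, int]]:
    """1-2 and 1-3 exclusions from the bond graph plus explicit entries.

    Returned pairs are canonical (i < j); generation is idempotent and
    symmetric by construction.
    """
    adjacency: Dict[int, Set[int]] = {}
    for i, j, *_ in bonds:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)
    excl: Set[Tuple[int, int]] = set()
    for i, j, *_ in bonds:
        excl.add(canonical_pair(i, j))
    for j, neighbors in adjacency.items():
        for i in neighbors:
            for k in neighbors:
                if i < k:
                    excl.add((i, k))
    if extra:
        for i, j in extra:
            if i != j:
                excl.add(canonical_pair(i, j))
    return excl


def one_four_pairs(
    bonds: Sequence[Bond], exclusions: Set[Tuple[int, int]]
) -> Set[Tuple[int, int]]:
    """Atom pairs connected by exactly three bonds and not excluded."""
    adjacency: Dict[int, Set[int]] = {}
    for i, j, *_ in bonds:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)
    pairs: Set[Tuple[int, int]] = set()
    for a in adjacency:
        for b in adjacency[a]:
            for c in adjacency[b]:
                if c == a:
                    continue
                for d in adjacency[c]:
                    if d in (a, b):
                        continue
                    p = canonical_pair(a, d)
                    if p not in exclusions:
                        pairs.add(p)
    return pairs


@dataclass
class MolecularSystem:
    """Atoms plus all interaction terms and named selections."""

    atoms: List[AtomRecord]
    bonds: List[Bond] = field(default_factory=list)
    angles: List[Angle] = field(default_factory=list)
    dihedrals: List[Dihedral] = field(default_factory=list)
    exclusions: Set[Tuple[int, int]] = field(default_factory=set)
    groups: Dict[str, List[int]] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_of(self) -> Dict[int, int]:
        return {a.atom_index: a.residue_index for a in self.atoms}

    @property
    def residue_name_of(self) -> Dict[int, str]:
        return {a.residue_index: a.residue_name for a in self.atoms}

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def lj_params(self) -> Tuple[np.ndarray, np.ndarray]:
        sigma = np.array([a.lj_sigma for a in self.atoms], dtype=float)
        eps = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        return sigma, eps

    def alpha_carbon_of(self, residue_index: int) -> int:
        """Atom index of the CA atom of a residue (or its only atom)."""
        members = [a for a in self.atoms if a.residue_index == residue_index]
        if not members:
            raise ValidationError(f"no atoms in residue {residue_index}")
        for a in members:
            if a.atom_name.strip() == "CA":
                return a.atom_index
        if len(members) == 1:
            return members[0].atom_index
        raise ValidationError(f"residue {residue_index} has no CA atom")

    def rebuild_exclusions(self) -> None:
        """Regenerate 1-2/1-3 exclusions, keeping explicit extra entries."""
        extra = set(self.metadata.get("explicit_exclusions", set()))
        self.exclusions = generate_exclusions(self.bonds, extra)

    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise ValidationError("system has no atoms")
        indices = [a.atom_index for a in self.atoms]
        if indices != list(range(1, n + 1)):
            raise ValidationError("atom indices must be contiguous from 1")
        resids = [a.residue_index for a in self.atoms]
        if any(b < a for a, b in zip(resids, resids[1:])):
            raise ValidationError("residue indices must be nondecreasing")

        def check(idx: Sequence[int], term: tuple, kind: str) -> None:
            for i in idx:
                if not (1 <= i <= n):
                    raise ValidationError(
                        f"{kind} term {term} references missing atom {i} "
                        f"(system has {n} atoms)"
                    )

        seen_bonds = set()
        for b in self.bonds:
            check(b[:2], b, "bond")
            p = canonical_pair(b[0], b[1])
            if p in seen_bonds:
                raise ValidationError(f"duplicate bond between atoms {p}")
            seen_bonds.add(p)
        for a in self.angles:
            check(a[:3], a, "angle")
        for d in self.dihedrals:
            check(d[:4], d, "dihedral")
        for i, j in self.exclusions:
            check((i, j), (i, j), "exclusion")
        for name, members in self.groups.items():
            check(members, (name,), f"group {name!r}")


@dataclass
class Frame:
    """Coordinates of one snapshot, in nm; optional orthorhombic box."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError("coordinates must have shape (n_atoms, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class TrajectoryEnsemble:
    """Ordered replicas of frame sequences for one thermodynamic state."""

    replicas: List[List[Frame]]
    state_label: str = ""

    def __post_init__(self) -> None:
        if not self.replicas or any(len(r) == 0 for r in self.replicas):
            raise ValidationError("every replica must contain at least one frame")
        counts = {f.n_atoms for rep in self.replicas for f in rep}
        if len(counts) != 1:
            raise ValidationError(
                f"inconsistent atom counts across frames: {sorted(counts)}"
            )

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_atoms(self) -> int:
        return self.replicas[0][0].n_atoms

    def iter_frames(self):
        for rep in self.replicas:
            yield from rep
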