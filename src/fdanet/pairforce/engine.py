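"""Per-frame pairwise force evaluation.

`PairForceEngine` precomputes the pair universe of a system (bonded
pairs plus all non-excluded nonbonded pairs) and evaluates, per frame:

* signed scalar pair forces over that universe (fast vectorized path,
  used for ensemble averaging and for the Langevin sampler),
* total potential energy and per-atom forces,
* a sparse `PairForceMatrix` in pN with optional per-kind breakdown.

Scalar sign convention: positive repulsive, negative attractive
(the sign of -dU/dr projected on the interatomic axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ..model_io.types import Frame, MolecularSystem, canonical_pair, one_four_pairs
from ..model_io.units import COULOMB_CONSTANT, KJ_MOL_NM_TO_PN
from .decompose import central_decomposition
from .terms import SingularGeometryError, angle_forces, dihedral_forces

KINDS = ("bond", "angle", "dihedral", "coulomb", "lj")

_MIN_R = 1e-6  # nm; closer nonbonded atoms are a singular geometry


@dataclass
class PairForceVector:
    """Vector force on atom i exerted by atom j (Newton: F_ji = -F_ij)."""

    i: int
    j: int
    force: np.ndarray  # kJ/mol/nm, acting on i
    kind: str

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("PairForceVector requires i < j")


@dataclass
class PairForceMatrix:
    """Sparse symmetric signed scalar pair forces of one frame, in pN."""

    n_atoms: int
    cutoff_nm: float
    data: Dict[Tuple[int, int], float] = field(default_factory=dict)
    kinds: Optional[Dict[str, Dict[Tuple[int, int], float]]] = None
    degenerate_terms: int = 0

    def get(self, i: int, j: int) -> float:
        if i == j:
            raise KeyError("no diagonal entries in a pair force matrix")
        return self.data.get(canonical_pair(i, j), 0.0)

    def items(self):
        return self.data.items()

    def __len__(self) -> int:
        return len(self.data)



def _scatter_pairs(forces: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray, fvec: np.ndarray) -> None:
    # bincount-based accumulation; np.add.at is much slower in the hot loop
    n = forces.shape[0]
    for d in range(3):
        forces[:, d] += np.bincount(idx_i, weights=fvec[:, d], minlength=n)
        forces[:, d] -= np.bincount(idx_j, weights=fvec[:, d], minlength=n)


class PairForceEngine:
    """Evaluates pair forces for a fixed topology.

    Parameters
    ----------
    system:
        Fully parameterized system (validated).
    cutoff_nm:
        Plain truncation cutoff for Coulomb and LJ interactions.
    scale14:
        Scaling of 1-4 nonbonded interactions (1.0 = full strength).
    """

    def __init__(self, system: MolecularSystem, cutoff_nm: float, scale14: float = 1.0):
        if cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")
        system.validate()
        self.system = system
        self.cutoff_nm = float(cutoff_nm)
        n = system.n_atoms
        self.n_atoms = n

        self._bond_i = np.array([b[0] - 1 for b in system.bonds], dtype=int)
        self._bond_j = np.array([b[1] - 1 for b in system.bonds], dtype=int)
        self._bond_k = np.array([b[2] for b in system.bonds], dtype=float)
        self._bond_r0 = np.array([b[3] for b in system.bonds], dtype=float)

        self._angles = [
            (a[0] - 1, a[1] - 1, a[2] - 1, a[3], a[4]) for a in system.angles
        ]
        self._dihedrals = [
            (d[0] - 1, d[1] - 1, d[2] - 1, d[3] - 1, d[4], d[5], d[6])
            for d in system.dihedrals
        ]

        charges = system.charges()
        sigma, eps = system.lj_params()
        excl = system.exclusions
        onefour = one_four_pairs(system.bonds, excl)
        nb_i: List[int] = []
        nb_j: List[int] = []
        nb_fqq: List[float] = []
        nb_sig: List[float] = []
        nb_eps: List[float] = []
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if (i, j) in excl:
                    continue
                scale = scale14 if (i, j) in onefour else 1.0
                nb_i.append(i - 1)
                nb_j.append(j - 1)
                nb_fqq.append(scale * COULOMB_CONSTANT * charges[i - 1] * charges[j - 1])
                nb_sig.append(0.5 * (sigma[i - 1] + sigma[j - 1]))
                nb_eps.append(scale * np.sqrt(eps[i - 1] * eps[j - 1]))
        self._nb_i = np.array(nb_i, dtype=int)
        self._nb_j = np.array(nb_j, dtype=int)
        self._nb_fqq = np.array(nb_fqq, dtype=float)
        self._nb_sig = np.array(nb_sig, dtype=float)
        self._nb_eps = np.array(nb_eps, dtype=float)
        self._nb_sig6 = self._nb_sig**6
        self._nb_eps4 = 4.0 * self._nb_eps
        self._nb_eps24 = 24.0 * self._nb_eps

        # pair-slot universe: bonded-term pairs + nonbonded pairs
        slots: Dict[Tuple[int, int], int] = {}

        def slot(i0: int, j0: int) -> int:
            key = canonical_pair(i0 + 1, j0 + 1)
            if key not in slots:
                slots[key] = len(slots)
            return slots[key]

        self._bond_slots = np.array(
            [slot(i, j) for i, j in zip(self._bond_i, self._bond_j)], dtype=int
        )
        self._angle_pair_slots = [
            [slot(t[a], t[b]) for a, b in ((0, 1), (0, 2), (1, 2))]
            for t in self._angles
        ]
        self._dihedral_pair_slots = [
            [
                slot(t[a], t[b])
                for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
            ]
            for t in self._dihedrals
        ]
        self._nb_slots = np.array(
            [slot(i, j) for i, j in zip(self._nb_i, self._nb_j)], dtype=int
        )
        self.pair_slots: Dict[Tuple[int, int], int] = slots
        self.pair_keys: List[Tuple[int, int]] = sorted(slots, key=slots.get)
        self.n_pairs = len(slots)
        self._bonded_slot_mask = np.zeros(self.n_pairs, dtype=bool)
        self._bonded_slot_mask[self._bond_slots] = True
        for group in self._angle_pair_slots + self._dihedral_pair_slots:
            self._bonded_slot_mask[group] = True

    # ------------------------------------------------------------------
    # fast vectorized paths
    # ------------------------------------------------------------------
    def _nonbonded_raw(self, coords: np.ndarray):
        """Distances and per-pair coulomb/LJ energies and scalar forces."""
        d = coords[self._nb_i] - coords[self._nb_j]
        r2 = np.einsum("ij,ij->i", d, d)
        if r2.size and float(r2.min()) < _MIN_R * _MIN_R:
            k = int(np.argmin(r2))
            raise SingularGeometryError(
                f"atoms {self._nb_i[k] + 1} and {self._nb_j[k] + 1} overlap "
                f"(r = {np.sqrt(r2[k]):.2e} nm)"
            )
        within = r2 <= self.cutoff_nm * self.cutoff_nm
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        inv_r2 = inv_r * inv_r
        e_coul = self._nb_fqq * inv_r
        f_coul = e_coul * inv_r
        s6 = self._nb_sig6 * (inv_r2 * inv_r2 * inv_r2)
        s12 = s6 * s6
        e_lj = self._nb_eps4 * (s12 - s6)
        f_lj = self._nb_eps24 * (2.0 * s12 - s6) * inv_r
        zero = ~within
        for arr in (e_coul, f_coul, e_lj, f_lj):
            arr[zero] = 0.0
        return d, r, within, e_coul, f_coul, e_lj, f_lj

    def scalar_pair_values(
        self, coords: np.ndarray, detail: bool = False
    ):
        """Signed scalar pair forces (kJ/mol/nm) over the slot universe.

        Returns (values, within_mask, degenerate_count) or, with
        ``detail=True``, (values, within_mask, degenerate_count, kinds).
        """
        values = np.zeros(self.n_pairs)
        kinds = {k: np.zeros(self.n_pairs) for k in KINDS} if detail else None
        degenerate = 0

        if len(self._bond_i):
            d = coords[self._bond_i] - coords[self._bond_j]
            r = np.linalg.norm(d, axis=1)
            fb = -self._bond_k * (r - self._bond_r0)
            values += np.bincount(self._bond_slots, weights=fb, minlength=self.n_pairs)
            if detail:
                np.add.at(kinds["bond"], self._bond_slots, fb)

        for t, pair_slots in zip(self._angles, self._angle_pair_slots):
            i, j, k, kt, t0 = t
            _, _, fi, fj, fk = angle_forces(coords[i], coords[j], coords[k], kt, t0)
            dec = central_decomposition(
                coords[[i, j, k]], np.vstack([fi, fj, fk])
            )
            if dec.degenerate:
                degenerate += 1
            for lam, s in zip(dec.lambdas, pair_slots):
                values[s] += lam
                if detail:
                    kinds["angle"][s] += lam

        for t, pair_slots in zip(self._dihedrals, self._dihedral_pair_slots):
            i, j, k, l, kp, mult, phase = t
            out = dihedral_forces(
                coords[i], coords[j], coords[k], coords[l], kp, mult, phase
            )
            dec = central_decomposition(coords[[i, j, k, l]], np.vstack(out[2:]))
            if dec.degenerate:
                degenerate += 1
            for lam, s in zip(dec.lambdas, pair_slots):
                values[s] += lam
                if detail:
                    kinds["dihedral"][s] += lam

        within_mask = self._bonded_slot_mask.copy()
        if len(self._nb_i):
            _, _, within, _, f_coul, _, f_lj = self._nonbonded_raw(coords)
            values += np.bincount(
                self._nb_slots, weights=f_coul + f_lj, minlength=self.n_pairs
            )
            within_mask[self._nb_slots[within]] = True
            if detail:
                np.add.at(kinds["coulomb"], self._nb_slots, f_coul)
                np.add.at(kinds["lj"], self._nb_slots, f_lj)

        if detail:
            return values, within_mask, degenerate, kinds
        return values, within_mask, degenerate

    def energy_forces(self, coords: np.ndarray) -> Tuple[float, np.ndarray]:
        """Total potential energy (kJ/mol) and per-atom forces."""
        energy = 0.0
        forces = np.zeros_like(coords)

        if len(self._bond_i):
            d = coords[self._bond_i] - coords[self._bond_j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self._bond_r0
            energy += float(0.5 * np.sum(self._bond_k * dr * dr))
            fvec = (-self._bond_k * dr / r)[:, None] * d
            _scatter_pairs(forces, self._bond_i, self._bond_j, fvec)

        for i, j, k, kt, t0 in self._angles:
            e, _, fi, fj, fk = angle_forces(coords[i], coords[j], coords[k], kt, t0)
            energy += e
            forces[i] += fi
            forces[j] += fj
            forces[k] += fk

        for i, j, k, l, kp, mult, phase in self._dihedrals:
            out = dihedral_forces(
                coords[i], coords[j], coords[k], coords[l], kp, mult, phase
            )
            energy += out[0]
            for idx, f in zip((i, j, k, l), out[2:]):
                forces[idx] += f

        if len(self._nb_i):
            d, r, within, e_coul, f_coul, e_lj, f_lj = self._nonbonded_raw(coords)
            energy += float(np.sum(e_coul + e_lj))
            fvec = ((f_coul + f_lj) / r)[:, None] * d
            _scatter_pairs(forces, self._nb_i, self._nb_j, fvec)

        return energy, forces

    # ------------------------------------------------------------------
    # matrix / vector products
    # ------------------------------------------------------------------
    def pair_force_matrix(self, coords: np.ndarray, detail: bool = False) -> PairForceMatrix:
        """Sparse matrix of signed scalar pair forces, in pN."""
        if detail:
            values, within, degenerate, kinds = self.scalar_pair_values(
                coords, detail=True
            )
        else:
            values, within, degenerate = self.scalar_pair_values(coords)
            kinds = None
        data = {
            key: values[s] * KJ_MOL_NM_TO_PN
            for key, s in self.pair_slots.items()
            if within[s]
        }
        kind_maps = None
        if kinds is not None:
            kind_maps = {
                k: {
                    key: v[s] * KJ_MOL_NM_TO_PN
                    for key, s in self.pair_slots.items()
                    if within[s] and v[s] != 0.0
                }
                for k, v in kinds.items()
            }
        return PairForceMatrix(
            n_atoms=self.n_atoms,
            cutoff_nm=self.cutoff_nm,
            data=data,
            kinds=kind_maps,
            degenerate_terms=degenerate,
        )

    def pair_force_vectors(self, coords: np.ndarray) -> List[PairForceVector]:
        """Vector-stage pair forces (kJ/mol/nm), for oracle tests.

        Two-body contributions lie along the interatomic axis; multi-body
        terms are decomposed into central pair forces.  Contributions to
        the same pair from different kinds are kept as separate entries.
        """
        out: List[PairForceVector] = []

        def axis_vec(i0: int, j0: int, scalar: float) -> np.ndarray:
            a, b = canonical_pair(i0, j0)
            d = coords[a - 1] - coords[b - 1]
            return scalar * d / np.linalg.norm(d)

        for (i, j, k, r0) in self.system.bonds:
            d = coords[i - 1] - coords[j - 1]
            r = float(np.linalg.norm(d))
            scalar = -k * (r - r0)
            out.append(PairForceVector(*canonical_pair(i, j), axis_vec(i, j, scalar), "bond"))

        for t, term in zip(self._angles, self.system.angles):
            i, j, k, kt, t0 = t
            _, _, fi, fj, fk = angle_forces(coords[i], coords[j], coords[k], kt, t0)
            dec = central_decomposition(coords[[i, j, k]], np.vstack([fi, fj, fk]))
            atoms = (i + 1, j + 1, k + 1)
            for lam, (a, b) in zip(dec.lambdas, dec.pairs):
                ci, cj = canonical_pair(atoms[a], atoms[b])
                out.append(PairForceVector(ci, cj, axis_vec(ci, cj, lam), "angle"))

        for t in self._dihedrals:
            i, j, k, l, kp, mult, phase = t
            res = dihedral_forces(
                coords[i], coords[j], coords[k], coords[l], kp, mult, phase
            )
            dec = central_decomposition(coords[[i, j, k, l]], np.vstack(res[2:]))
            atoms = (i + 1, j + 1, k + 1, l + 1)
            for lam, (a, b) in zip(dec.lambdas, dec.pairs):
                ci, cj = canonical_pair(atoms[a], atoms[b])
                out.append(PairForceVector(ci, cj, axis_vec(ci, cj, lam), "dihedral"))

        if len(self._nb_i):
            d, r, within, e_coul, f_coul, e_lj, f_lj = self._nonbonded_raw(
                coords
            )
            for idx in np.nonzero(within)[0]:
                i1 = int(self._nb_i[idx]) + 1
                j1 = int(self._nb_j[idx]) + 1
                u = d[idx] / r[idx]
                if f_coul[idx] != 0.0:
                    out.append(PairForceVector(i1, j1, f_coul[idx] * u, "coulomb"))
                if f_lj[idx] != 0.0:
                    out.append(PairForceVector(i1, j1, f_lj[idx] * u, "lj"))
        return out

    def nonbonded_group_energy(
        self, coords: np.ndarray, atoms_a: Sequence[int], atoms_b: Sequence[int]
    ) -> float:
        """Cross-group nonbonded (coulomb + LJ) energy, kJ/mol."""
        set_a = set(atoms_a)
        set_b = set(atoms_b)
        if set_a & set_b:
            raise ValueError("groups overlap at the atom level")
        if not set_a or not set_b:
            raise ValueError("empty group")
        in_a = np.isin(self._nb_i + 1, list(set_a)) | np.isin(self._nb_j + 1, list(set_a))
        in_b = np.isin(self._nb_i + 1, list(set_b)) | np.isin(self._nb_j + 1, list(set_b))
        cross = in_a & in_b
        if not cross.any():
            return 0.0
        _, _, within, e_coul, _, e_lj, _ = self._nonbonded_raw(coords)
        return float(np.sum((e_coul + e_lj)[cross]))


# ----------------------------------------------------------------------
# module-level convenience operations
# ----------------------------------------------------------------------
def pairwise_forces_frame(
    system: MolecularSystem,
    frame: Frame,
    cutoff_nm: float,
    detail: bool = False,
    engine: Optional[PairForceEngine] = None,
) -> PairForceMatrix:
    """Scalar pair-force matrix of one frame over all interaction types."""
    eng = engine or PairForceEngine(system, cutoff_nm)
    return eng.pair_force_matrix(frame.coordinates, detail=detail)


def scalarize(pair_force: PairForceVector, frame: Frame) -> float:
    """Signed scalar (pN): norm of the vector, positive if repulsive.

    The sign is that of the projection of the force on atom i onto the
    axis from j to i.
    """
    d = frame.coordinates[pair_force.i - 1] - frame.coordinates[pair_force.j - 1]
    r = float(np.linalg.norm(d))
    if r <= 0:
        raise SingularGeometryError("coincident atoms in scalarize")
    norm = float(np.linalg.norm(pair_force.force))
    if norm == 0.0:
        return 0.0
    sign = 1.0 if float(pair_force.force @ d) >= 0 else -1.0
    return sign * norm * KJ_MOL_NM_TO_PN


def group_pair_forces(
    matrix: PairForceMatrix, group_u: Iterable[int], group_v: Iterable[int]
) -> float:
    """Residue/group-wise force: sum of signed scalars over spanning pairs."""
    set_u = set(group_u)
    set_v = set(group_v)
    if set_u & set_v:
        raise ValueError("groups overlap at the atom level")
    total = 0.0
    for (i, j), val in matrix.items():
        if (i in set_u and j in set_v) or (j in set_u and i in set_v):
            total += val
    return total


def interaction_energy(
    system: MolecularSystem,
    ensemble,
    group_a: Sequence[int],
    group_b: Sequence[int],
    cutoff_nm: float,
) -> Tuple[float, float]:
    """Mean +/- SD (across replicas) of the cross-group nonbonded energy."""
    engine = PairForceEngine(system, cutoff_nm)
    replica_means = []
    for replica in ensemble.replicas:
        vals = [
            engine.nonbonded_group_energy(f.coordinates, group_a, group_b)
            for f in replica
        ]
        replica_means.append(float(np.mean(vals)))
    mean = float(np.mean(replica_means))
    sd = float(np.std(replica_means, ddof=1)) if len(replica_means) > 1 else 0.0
    return mean, sd
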