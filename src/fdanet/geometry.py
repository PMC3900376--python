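"""Bending angles, hydrogen bonds and rigid-body superposition.

Angles are computed at full precision in degrees and reported rounded
to 0.1 deg; angle-difference uncertainties combine per-state standard
deviations in independent quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model_io.types import Frame, MolecularSystem, TrajectoryEnsemble, ValidationError
from .model_io.units import ANGSTROM_PER_NM


@dataclass(frozen=True)
class AngleTriplet:
    """Three residue indices whose CA atoms define a bending angle."""

    residues: Tuple[int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.residues)) != 3:
            raise ValidationError("angle triplet residues must be distinct")

    @classmethod
    def parse(cls, text: str, label: str = "") -> "AngleTriplet":
        """Parse '188-192-199' style notation."""
        parts = [int(p) for p in text.replace(":", "-").split("-")]
        if len(parts) != 3:
            raise ValidationError(f"cannot parse angle triplet {text!r}")
        return cls(tuple(parts), label=label or text)


@dataclass
class AngleProfile:
    triplet: AngleTriplet
    replica_means: np.ndarray  # degrees
    state_label: str = ""

    @property
    def mean(self) -> float:
        return float(self.replica_means.mean())

    @property
    def sd(self) -> float:
        if self.replica_means.size < 2:
            return 0.0
        return float(self.replica_means.std(ddof=1))


@dataclass
class AngleDifference:
    triplet: AngleTriplet
    delta: float  # degrees, full precision
    sd: float  # quadrature-propagated, full precision

    @property
    def rounded(self) -> Tuple[float, float]:
        """(delta, sd) rounded to one decimal for reporting."""
        return (round(self.delta, 1), round(self.sd, 1))


@dataclass
class HBond:
    donor: int
    acceptor: int
    hydrogen: Optional[int]
    mean_distance_A: float
    occupancy: float


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # nm; x_fit = R @ x_mobile + t
    rmsd_A: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def bending_angle(coords: np.ndarray, atom_triplet: Sequence[int]) -> float:
    """Angle (degrees) at the middle atom of a 1-based atom triplet."""
    i, j, k = atom_triplet
    a = coords[i - 1] - coords[j - 1]
    b = coords[k - 1] - coords[j - 1]
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na < 1e-9 or nb < 1e-9:
        raise ValidationError("zero-length arm in bending angle")
    cos_t = float(np.clip((a @ b) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cos_t))


def angle_profile(
    ensemble: TrajectoryEnsemble,
    system: MolecularSystem,
    triplet: AngleTriplet,
) -> AngleProfile:
    """Per-replica mean bending angle; ensemble mean/SD across replicas."""
    atoms = [system.alpha_carbon_of(r) for r in triplet.residues]
    replica_means = np.array(
        [
            np.mean([bending_angle(f.coordinates, atoms) for f in rep])
            for rep in ensemble.replicas
        ]
    )
    return AngleProfile(
        triplet=triplet,
        replica_means=replica_means,
        state_label=ensemble.state_label,
    )


def angle_difference(profile_a: AngleProfile, profile_b: AngleProfile) -> AngleDifference:
    """a minus b, with SD propagated in independent quadrature."""
    if profile_a.triplet.residues != profile_b.triplet.residues:
        raise ValidationError(
            f"triplet mismatch: {profile_a.triplet.residues} vs "
            f"{profile_b.triplet.residues}"
        )
    return AngleDifference(
        triplet=profile_a.triplet,
        delta=profile_a.mean - profile_b.mean,
        sd=math.hypot(profile_a.sd, profile_b.sd),
    )


def _find_hydrogens(system: MolecularSystem, donor: int) -> List[int]:
    out = []
    for i, j, *_ in system.bonds:
        other = j if i == donor else i if j == donor else None
        if other is not None and system.atoms[other - 1].element.upper() == "H":
            out.append(other)
    return out


def detect_hbonds(
    ensemble: TrajectoryEnsemble,
    system: MolecularSystem,
    donors: Sequence[int],
    acceptors: Sequence[int],
    d_max_A: float = 3.5,
    angle_min_deg: float = 120.0,
    min_occupancy: float = 0.5,
) -> List[HBond]:
    """Geometric hydrogen bonds with per-frame occupancy.

    Criterion: donor-acceptor distance <= d_max_A and, when a hydrogen
    is bonded to the donor, a D-H...A angle (at H) >= angle_min_deg.
    Bonds below ``min_occupancy`` are dropped.
    """
    if not donors or not acceptors:
        raise ValidationError("donor and acceptor selections must be nonempty")
    d_max_nm = d_max_A / ANGSTROM_PER_NM
    frames = list(ensemble.iter_frames())
    results: List[HBond] = []
    for d in donors:
        hydrogens = _find_hydrogens(system, d)
        for a in acceptors:
            if a == d:
                continue
            hit = 0
            dist_sum = 0.0
            used_h: Optional[int] = None
            for frame in frames:
                c = frame.coordinates
                r_da = float(np.linalg.norm(c[d - 1] - c[a - 1]))
                if r_da > d_max_nm:
                    continue
                if hydrogens:
                    ok = False
                    for h in hydrogens:
                        v1 = c[d - 1] - c[h - 1]
                        v2 = c[a - 1] - c[h - 1]
                        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                        if denom < 1e-12:
                            continue
                        ang = math.degrees(
                            math.acos(float(np.clip((v1 @ v2) / denom, -1, 1)))
                        )
                        if ang >= angle_min_deg:
                            ok = True
                            used_h = h
                            break
                    if not ok:
                        continue
                hit += 1
                dist_sum += r_da
            occupancy = hit / len(frames)
            if occupancy >= min_occupancy and hit > 0:
                results.append(
                    HBond(
                        donor=d,
                        acceptor=a,
                        hydrogen=used_h,
                        mean_distance_A=dist_sum / hit * ANGSTROM_PER_NM,
                        occupancy=occupancy,
                    )
                )
    results.sort(key=lambda h: (-h.occupancy, h.donor, h.acceptor))
    return results


def superpose(
    mobile: Frame,
    reference: Frame,
    selection: Optional[Sequence[int]] = None,
) -> Superposition:
    """Kabsch least-squares rigid-body fit of mobile onto reference.

    ``selection`` holds 1-based atom indices (default: all atoms);
    at least 3 non-collinear atoms are required.
    """
    if selection is None:
        idx = np.arange(mobile.n_atoms)
    else:
        idx = np.asarray(selection, dtype=int) - 1
    x = mobile.coordinates[idx]
    y = reference.coordinates[idx]
    if x.shape != y.shape:
        raise ValidationError("selection size mismatch between frames")
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 atoms to superpose")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if np.linalg.matrix_rank(xc, tol=1e-9) < 2:
        raise ValidationError("collinear selection cannot define a superposition")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = y.mean(axis=0) - rot @ x.mean(axis=0)
    fitted = x @ rot.T + trans
    rmsd_nm = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return Superposition(
        rotation=rot, translation=trans, rmsd_A=rmsd_nm * ANGSTROM_PER_NM
    )
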