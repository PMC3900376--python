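"""Analytic energies and forces of the supported interaction terms.

All inputs/outputs in MD units: nm, kJ/mol, kJ/mol/nm, radians inside,
degrees at the API boundary where noted.  Scalar pair forces follow the
convention: positive = repulsive (pushes the pair apart), i.e. -dU/dr.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np


class SingularGeometryError(ValueError):
    pass


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross has large call overhead for single 3-vectors
    return np.array(
        (
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        )
    )


def _norm(a: np.ndarray) -> float:
    return math.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])


def bond_energy_scalar(k: float, r0: float, r: float) -> Tuple[float, float]:
    """Harmonic bond: energy and signed scalar pair force (-dU/dr)."""
    dr = r - r0
    return 0.5 * k * dr * dr, -k * dr


def coulomb_energy_scalar(fqq: float, r: float) -> Tuple[float, float]:
    """Coulomb with premultiplied prefactor*charges; (-dU/dr) = fqq/r^2."""
    return fqq / r, fqq / (r * r)


def lj_energy_scalar(eps: float, sigma: float, r: float) -> Tuple[float, float]:
    """12-6 Lennard-Jones energy and signed scalar pair force."""
    if eps == 0.0:
        return 0.0, 0.0
    s6 = (sigma / r) ** 6
    s12 = s6 * s6
    return 4.0 * eps * (s12 - s6), 24.0 * eps * (2.0 * s12 - s6) / r


def angle_forces(
    p_i: np.ndarray,
    p_j: np.ndarray,
    p_k: np.ndarray,
    k_theta: float,
    theta0_deg: float,
) -> Tuple[float, float, np.ndarray, np.ndarray, np.ndarray]:
    """Harmonic angle at j: (energy, theta_rad, F_i, F_j, F_k)."""
    rij = p_i - p_j
    rkj = p_k - p_j
    nij = _norm(rij)
    nkj = _norm(rkj)
    if nij < 1e-9 or nkj < 1e-9:
        raise SingularGeometryError("zero-length angle arm")
    uij = rij / nij
    ukj = rkj / nkj
    cos_t = float(np.clip(uij @ ukj, -1.0, 1.0))
    theta = math.acos(cos_t)
    theta0 = math.radians(theta0_deg)
    energy = 0.5 * k_theta * (theta - theta0) ** 2
    du_dtheta = k_theta * (theta - theta0)
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-24))
    dtheta_di = (cos_t * uij - ukj) / (nij * sin_t)
    dtheta_dk = (cos_t * ukj - uij) / (nkj * sin_t)
    f_i = -du_dtheta * dtheta_di
    f_k = -du_dtheta * dtheta_dk
    return energy, theta, f_i, -(f_i + f_k), f_k


def dihedral_angle(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Torsion angle in radians, IUPAC sign convention."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    m = _cross(n1, b2 / _norm(b2))
    return math.atan2(float(m @ n2), float(n1 @ n2))


def dihedral_forces(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    k_phi: float,
    multiplicity: int,
    phase_deg: float,
) -> Tuple[float, float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Periodic dihedral U = k(1 + cos(n*phi - phase)).

    Returns (energy, phi_rad, F1, F2, F3, F4).
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    n1_sq = float(n1 @ n1)
    n2_sq = float(n2 @ n2)
    b2_norm = float(_norm(b2))
    if n1_sq < 1e-18 or n2_sq < 1e-18 or b2_norm < 1e-9:
        raise SingularGeometryError("collinear dihedral geometry")
    phi = dihedral_angle(p1, p2, p3, p4)
    delta = math.radians(phase_deg)
    energy = k_phi * (1.0 + math.cos(multiplicity * phi - delta))
    du_dphi = -k_phi * multiplicity * math.sin(multiplicity * phi - delta)

    dphi_d1 = (b2_norm / n1_sq) * n1
    dphi_d4 = -(b2_norm / n2_sq) * n2
    s12 = float(b1 @ b2) / (b2_norm * b2_norm)
    s32 = float(b3 @ b2) / (b2_norm * b2_norm)
    dphi_d2 = -(1.0 + s12) * dphi_d1 + s32 * dphi_d4
    dphi_d3 = s12 * dphi_d1 - (1.0 + s32) * dphi_d4

    f1 = -du_dphi * dphi_d1
    f2 = -du_dphi * dphi_d2
    f3 = -du_dphi * dphi_d3
    f4 = -du_dphi * dphi_d4
    return energy, phi, f1, f2, f3, f4
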