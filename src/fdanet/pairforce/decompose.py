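"""Decomposition of multi-body atomic forces into central pair forces.

For a term over m atoms the atomic forces of the term are expressed as
pair forces acting along the interatomic axes of all m(m-1)/2 pairs:

    F_a = sum_{b != a} lambda_ab * u_ab,   u_ab = (x_a - x_b)/|x_a - x_b|

lambda_ab > 0 is repulsive.  The linear system is solved exactly for
3-body terms in generic geometry and in the least-squares sense for
4-body terms; degenerate (collinear/planar-singular) geometries fall
back to the minimum-norm solution and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Tuple

import numpy as np

from .terms import SingularGeometryError

#: singular values below this fraction of the largest are treated as rank loss
_RCOND = 1e-8


@dataclass
class CentralDecomposition:
    pairs: List[Tuple[int, int]]  # local indices into the term's atoms
    lambdas: np.ndarray  # signed scalar pair forces, kJ/mol/nm
    residual: float  # rms mismatch vs input atomic forces
    degenerate: bool


def central_decomposition(
    positions: np.ndarray, forces: np.ndarray
) -> CentralDecomposition:
    """Solve for central pair forces reproducing the given atomic forces."""
    positions = np.asarray(positions, dtype=float)
    forces = np.asarray(forces, dtype=float)
    m = positions.shape[0]
    pairs = list(combinations(range(m), 2))
    a_mat = np.zeros((3 * m, len(pairs)))
    for col, (a, b) in enumerate(pairs):
        d = positions[a] - positions[b]
        r = np.linalg.norm(d)
        if r < 1e-9:
            raise SingularGeometryError(
                f"overlapping atoms in multi-body term (pair {a},{b})"
            )
        u = d / r
        a_mat[3 * a : 3 * a + 3, col] = u
        a_mat[3 * b : 3 * b + 3, col] = -u
    rhs = forces.reshape(-1)
    lambdas, _, rank, sv = np.linalg.lstsq(a_mat, rhs, rcond=_RCOND)
    degenerate = rank < len(pairs)
    residual = float(np.sqrt(np.mean((a_mat @ lambdas - rhs) ** 2)))
    return CentralDecomposition(pairs, lambdas, residual, degenerate)
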