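"""Ensemble statistics of scalar pair forces.

Averaging is replica-first: each replica's frames are averaged (a pair
absent from a frame contributes 0 to that frame), the grand mean is the
unweighted mean of replica means, and spreads are standard deviations
across replica means.  State differencing treats a pair absent from one
state as having zero mean there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model_io.types import canonical_pair
from .pairforce.engine import PairForceMatrix

PairKey = Tuple[int, int]


@dataclass
class AveragedPairForces:
    """Replica-resolved means of signed scalar pair forces (pN)."""

    pair_index: Dict[PairKey, int]
    replica_means: np.ndarray  # (n_replicas, n_pairs)
    frames_per_replica: List[int]
    state_label: str = ""

    @property
    def n_replicas(self) -> int:
        return self.replica_means.shape[0]

    @property
    def grand_mean(self) -> np.ndarray:
        return self.replica_means.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.n_replicas < 2:
            return np.zeros(self.replica_means.shape[1])
        return self.replica_means.std(axis=0, ddof=1)

    def mean_of(self, i: int, j: int) -> float:
        slot = self.pair_index.get(canonical_pair(i, j))
        return 0.0 if slot is None else float(self.grand_mean[slot])

    def items(self) -> Iterable[Tuple[PairKey, float]]:
        gm = self.grand_mean
        for key, slot in self.pair_index.items():
            yield key, float(gm[slot])


@dataclass
class ForceDifference:
    """Per-pair difference of state means: state_a minus state_b (pN)."""

    data: Dict[PairKey, float]
    label_a: str = "apo"
    label_b: str = "complex"

    def get(self, i: int, j: int) -> float:
        return self.data.get(canonical_pair(i, j), 0.0)

    def items(self):
        return self.data.items()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PunctualStressProfile:
    """Per-atom stress (sum_j |dF_ij|, pN) and a residue aggregate."""

    atom_stress: Dict[int, float]
    residue_stress: Dict[int, float] = field(default_factory=dict)
    aggregation: str = "sum"

    def as_array(self, n_atoms: int) -> np.ndarray:
        out = np.zeros(n_atoms)
        for atom, val in self.atom_stress.items():
            out[atom - 1] = val
        return out

    @property
    def max_stress(self) -> float:
        return max(self.atom_stress.values(), default=0.0)


def average_pair_forces(
    replicas: Sequence[Sequence[PairForceMatrix]], state_label: str = ""
) -> AveragedPairForces:
    """Average per-frame matrices, replica-first.

    A pair missing from a frame counts as 0 for that frame; the pair
    universe is the union over all frames.
    """
    if not replicas or any(len(r) == 0 for r in replicas):
        raise ValueError("every replica must contain at least one frame")
    pair_index: Dict[PairKey, int] = {}
    sums: List[np.ndarray] = []
    for matrices in replicas:
        acc: Dict[PairKey, float] = {}
        for m in matrices:
            for key, val in m.items():
                acc[key] = acc.get(key, 0.0) + val
        for key in acc:
            if key not in pair_index:
                pair_index[key] = len(pair_index)
        row = np.zeros(len(pair_index))
        for key, total in acc.items():
            row[pair_index[key]] = total / len(matrices)
        sums.append(row)
    n_pairs = len(pair_index)
    replica_means = np.zeros((len(replicas), n_pairs))
    for r, row in enumerate(sums):
        replica_means[r, : row.size] = row
    return AveragedPairForces(
        pair_index=pair_index,
        replica_means=replica_means,
        frames_per_replica=[len(r) for r in replicas],
        state_label=state_label,
    )


def average_from_arrays(
    pair_keys: Sequence[PairKey],
    replica_means: np.ndarray,
    frames_per_replica: Sequence[int],
    state_label: str = "",
) -> AveragedPairForces:
    """Build averages from a fixed pair universe (fast engine path)."""
    replica_means = np.atleast_2d(np.asarray(replica_means, dtype=float))
    if replica_means.shape[1] != len(pair_keys):
        raise ValueError("replica mean width does not match pair key count")
    return AveragedPairForces(
        pair_index={key: s for s, key in enumerate(pair_keys)},
        replica_means=replica_means,
        frames_per_replica=list(frames_per_replica),
        state_label=state_label,
    )


def average_ensemble(
    engine, ensemble, state_label: str = ""
) -> AveragedPairForces:
    """Replica-first averages over a trajectory ensemble (fast path).

    Uses the engine's fixed pair universe; a nonbonded pair beyond the
    cutoff in a frame contributes 0 for that frame, matching the
    absent-pair rule of :func:`average_pair_forces`.
    """
    from .model_io.units import KJ_MOL_NM_TO_PN

    rows = []
    for replica in ensemble.replicas:
        acc = np.zeros(engine.n_pairs)
        for frame in replica:
            values, _, _ = engine.scalar_pair_values(frame.coordinates)
            acc += values
        rows.append(acc / len(replica) * KJ_MOL_NM_TO_PN)
    return average_from_arrays(
        engine.pair_keys,
        np.vstack(rows),
        [len(r) for r in ensemble.replicas],
        state_label=state_label or ensemble.state_label,
    )


def force_difference(
    avg_a: AveragedPairForces, avg_b: AveragedPairForces
) -> ForceDifference:
    """dF_ij = mean_a - mean_b; absent pairs count as zero-mean."""
    data: Dict[PairKey, float] = {}
    mean_a = dict(avg_a.items())
    mean_b = dict(avg_b.items())
    for key in set(mean_a) | set(mean_b):
        data[key] = mean_a.get(key, 0.0) - mean_b.get(key, 0.0)
    return ForceDifference(
        data=data, label_a=avg_a.state_label or "a", label_b=avg_b.state_label or "b"
    )


def punctual_stress(
    diff: ForceDifference,
    residue_of: Optional[Mapping[int, int]] = None,
    aggregation: str = "sum",
) -> PunctualStressProfile:
    """Per-atom dF_i = sum_j |dF_ij|; optional residue aggregate."""
    if aggregation not in ("sum", "max"):
        raise ValueError("aggregation must be 'sum' or 'max'")
    atom_stress: Dict[int, float] = {}
    for (i, j), val in diff.items():
        mag = abs(val)
        atom_stress[i] = atom_stress.get(i, 0.0) + mag
        atom_stress[j] = atom_stress.get(j, 0.0) + mag
    residue_stress: Dict[int, float] = {}
    if residue_of is not None:
        for atom, val in atom_stress.items():
            res = residue_of[atom]
            if aggregation == "sum":
                residue_stress[res] = residue_stress.get(res, 0.0) + val
            else:
                residue_stress[res] = max(residue_stress.get(res, 0.0), val)
    return PunctualStressProfile(
        atom_stress=atom_stress, residue_stress=residue_stress, aggregation=aggregation
    )


def ligand_binding_profile(
    avg: AveragedPairForces,
    ligand_atoms: Sequence[int],
    residue_of: Mapping[int, int],
) -> List[Tuple[int, float]]:
    """Per-residue |F_uv| against the whole ligand, sorted descending.

    F_uv is the sum of signed scalar pair-force means over atom pairs
    spanning the residue and the ligand; the ranking reports |F_uv| (pN).
    """
    ligand = set(ligand_atoms)
    if not ligand:
        raise ValueError("ligand group is empty")
    per_residue: Dict[int, float] = {}
    for (i, j), mean in avg.items():
        if (i in ligand) == (j in ligand):
            continue
        protein_atom = j if i in ligand else i
        res = residue_of[protein_atom]
        per_residue[res] = per_residue.get(res, 0.0) + mean
    ranking = [(res, abs(total)) for res, total in per_residue.items()]
    ranking.sort(key=lambda item: (-item[1], item[0]))
    return ranking


@dataclass
class ConvergenceProfile:
    running_mean: np.ndarray
    first_half_mean: float
    second_half_mean: float
    tolerance: float
    converged: bool


def convergence_profile(
    series: Sequence[float], tolerance: Optional[float] = None
) -> ConvergenceProfile:
    """Running mean of a pair-force series and a half-split check.

    Default tolerance is three standard errors of the half-mean
    difference (2*sd/sqrt(N) for an iid series), so an uncorrelated
    series is flagged converged with ~99.7% probability.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 frames")
    running = np.cumsum(x) / np.arange(1, x.size + 1)
    half = x.size // 2
    first = float(x[:half].mean())
    second = float(x[half:].mean())
    if tolerance is None:
        se_diff = 2.0 * float(x.std(ddof=1)) / np.sqrt(x.size)
        tolerance = 3.0 * se_diff
    return ConvergenceProfile(
        running_mean=running,
        first_half_mean=first,
        second_half_mean=second,
        tolerance=float(tolerance),
        converged=abs(first - second) <= tolerance,
    )
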