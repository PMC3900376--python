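import numpy as np
import pytest

from fdanet.model_io.types import AtomRecord, Frame, MolecularSystem, TrajectoryEnsemble
from fdanet.model_io.units import COULOMB_CONSTANT, KJ_MOL_NM_TO_PN
from fdanet.pairforce import (
    PairForceEngine,
    PairForceVector,
    SingularGeometryError,
    angle_forces,
    central_decomposition,
    dihedral_forces,
    group_pair_forces,
    interaction_energy,
    pairwise_forces_frame,
    scalarize,
)

from conftest import make_random_system


def two_particle_system(charges=(0.0, 0.0), bond=None, sigma=0.0, eps=0.0):
    atoms = [
        AtomRecord(i + 1, "X", "C", i + 1, "UNK", charges[i], sigma, eps)
        for i in range(2)
    ]
    system = MolecularSystem(atoms=atoms, bonds=[bond] if bond else [])
    system.rebuild_exclusions()
    return system


class TestTwoBodyForces:
    def test_harmonic_bond_hookes_law(self):
        system = two_particle_system(bond=(1, 2, 1000.0, 0.1))
        frame = Frame(np.array([[0.0, 0, 0], [0.12, 0, 0]]))
        matrix = pairwise_forces_frame(system, frame, cutoff_nm=1.0)
        # stretched bond: magnitude k*dr = 20 kJ/mol/nm, attractive (negative)
        assert matrix.get(1, 2) == pytest.approx(-20.0 * KJ_MOL_NM_TO_PN)
        vectors = PairForceEngine(system, 1.0).pair_force_vectors(frame.coordinates)
        (bond_vec,) = [v for v in vectors if v.kind == "bond"]
        # force on atom 1 points toward atom 2 (shortens the bond)
        assert bond_vec.force[0] > 0

    def test_coulomb_prefactor(self):
        system = two_particle_system(charges=(1.0, 1.0))
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        matrix = pairwise_forces_frame(system, frame, cutoff_nm=2.0)
        assert matrix.get(1, 2) == pytest.approx(
            COULOMB_CONSTANT * KJ_MOL_NM_TO_PN, rel=1e-9
        )
        assert matrix.get(1, 2) > 0  # repulsive

    def test_overlapping_atoms_raise(self):
        system = two_particle_system(charges=(1.0, 1.0))
        frame = Frame(np.array([[0.0, 0, 0], [1e-8, 0, 0]]))
        with pytest.raises(SingularGeometryError):
            pairwise_forces_frame(system, frame, cutoff_nm=1.0)


class TestFiniteDifferenceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pair_decomposition_matches_gradient(self, seed):
        rng = np.random.default_rng(seed)
        system, frame = make_random_system(rng, n_atoms=20)
        engine = PairForceEngine(system, cutoff_nm=100.0)
        vectors = engine.pair_force_vectors(frame.coordinates)
        net = np.zeros((20, 3))
        for v in vectors:
            net[v.i - 1] += v.force
            net[v.j - 1] -= v.force
        h = 1e-6
        fd = np.zeros_like(net)
        x = frame.coordinates
        for a in range(20):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[a, d] += h
                xm[a, d] -= h
                ep, _ = engine.energy_forces(xp)
                em, _ = engine.energy_forces(xm)
                fd[a, d] = -(ep - em) / (2 * h)
        rel = np.abs(net - fd).max() / np.abs(fd).max()
        assert rel < 1e-5

    def test_newtons_third_law_and_zero_total_force(self):
        rng = np.random.default_rng(5)
        system, frame = make_random_system(rng, n_atoms=15)
        engine = PairForceEngine(system, cutoff_nm=100.0)
        vectors = engine.pair_force_vectors(frame.coordinates)
        total = sum((v.force for v in vectors), np.zeros(3))
        # each pair contributes +F to i and -F to j by storage convention,
        # so the net internal force is the sum over pair vectors minus itself
        net = np.zeros((system.n_atoms, 3))
        for v in vectors:
            net[v.i - 1] += v.force
            net[v.j - 1] -= v.force
        assert np.abs(net.sum(axis=0)).max() < 1e-9


class TestMultibodyDecomposition:
    def test_angle_at_equilibrium_gives_zero(self):
        p = np.array([[1.0, 0, 0], [0.0, 0, 0], [np.cos(1.0), np.sin(1.0), 0]])
        theta0 = np.degrees(1.0)
        _, _, fi, fj, fk = angle_forces(p[0], p[1], p[2], 300.0, theta0)
        assert np.abs(np.vstack([fi, fj, fk])).max() < 1e-10

    def test_bent_triplet_reconstruction(self):
        # water-like geometry
        p = np.array([[0.096, 0, 0], [0.0, 0, 0], [-0.024, 0.093, 0]])
        _, _, fi, fj, fk = angle_forces(p[0], p[1], p[2], 400.0, 104.5 + 7.0)
        forces = np.vstack([fi, fj, fk])
        dec = central_decomposition(p, forces)
        recon = np.zeros((3, 3))
        for lam, (a, b) in zip(dec.lambdas, dec.pairs):
            u = (p[a] - p[b]) / np.linalg.norm(p[a] - p[b])
            recon[a] += lam * u
            recon[b] -= lam * u
        np.testing.assert_allclose(recon, forces, atol=1e-10)
        assert not dec.degenerate

    def test_dihedral_at_minimum_gives_zero(self):
        p = np.array(
            [[0.0, 0.1, 0], [0.0, 0, 0], [0.15, 0, 0], [0.15, 0.08, 0.06]]
        )
        from fdanet.pairforce import dihedral_angle

        phi = np.degrees(dihedral_angle(*p))
        # U = k(1 + cos(phi - phase)) is minimal when phi - phase = 180 deg
        out = dihedral_forces(*p, 10.0, 1, phi - 180.0)
        assert np.abs(np.vstack(out[2:])).max() < 1e-10

    def test_residual_small_on_generic_4body(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.normal(size=(4, 3))
            out = dihedral_forces(*p, 8.0, 2, 60.0)
            dec = central_decomposition(p, np.vstack(out[2:]))
            assert dec.residual < 1e-8

    def test_collinear_geometry_flagged_degenerate(self):
        p = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
        dec = central_decomposition(p, np.zeros((3, 3)))
        assert dec.degenerate


class TestScalarize:
    def test_attractive_negative(self):
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        # force on atom 1 pointing toward atom 2 = attraction
        pf = PairForceVector(1, 2, np.array([10.0, 0, 0]), "coulomb")
        assert scalarize(pf, frame) < 0

    def test_repulsive_positive(self):
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        pf = PairForceVector(1, 2, np.array([-10.0, 0, 0]), "coulomb")
        assert scalarize(pf, frame) > 0

    def test_zero_vector(self):
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        pf = PairForceVector(1, 2, np.zeros(3), "lj")
        assert scalarize(pf, frame) == 0.0

    def test_sign_matches_charge_product(self):
        for q2, expected_sign in ((1.0, 1), (-1.0, -1)):
            system = two_particle_system(charges=(1.0, q2))
            frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
            m = pairwise_forces_frame(system, frame, cutoff_nm=2.0)
            assert np.sign(m.get(1, 2)) == expected_sign


class TestGroupForces:
    def test_single_pair(self):
        system = two_particle_system(charges=(1.0, 1.0))
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        m = pairwise_forces_frame(system, frame, cutoff_nm=2.0)
        assert group_pair_forces(m, [1], [2]) == pytest.approx(m.get(1, 2))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        system, frame = make_random_system(rng, n_atoms=30)
        m = pairwise_forces_frame(system, frame, cutoff_nm=100.0)
        group_u = list(range(1, 11))
        group_v = list(range(16, 31))
        expected = 0.0
        for i in group_u:
            for j in group_v:
                expected += m.get(i, j)
        assert group_pair_forces(m, group_u, group_v) == pytest.approx(expected)

    def test_disjoint_groups_required(self):
        system = two_particle_system(charges=(1.0, 1.0))
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        m = pairwise_forces_frame(system, frame, cutoff_nm=2.0)
        with pytest.raises(ValueError):
            group_pair_forces(m, [1, 2], [2])

    def test_groups_beyond_cutoff_zero(self):
        system = two_particle_system(charges=(1.0, 1.0))
        frame = Frame(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        m = pairwise_forces_frame(system, frame, cutoff_nm=1.0)
        assert group_pair_forces(m, [1], [2]) == 0.0


class TestInteractionEnergy:
    def _ensemble(self, coords):
        return TrajectoryEnsemble([[Frame(np.array(coords))]], "s")

    def test_coulomb_energy_value(self):
        system = two_particle_system(charges=(1.0, -1.0))
        ens = self._ensemble([[0.0, 0, 0], [1.0, 0, 0]])
        mean, sd = interaction_energy(system, ens, [1], [2], cutoff_nm=2.0)
        assert mean == pytest.approx(-COULOMB_CONSTANT, rel=1e-9)
        assert sd == 0.0

    def test_beyond_cutoff_zero(self):
        system = two_particle_system(charges=(1.0, -1.0))
        ens = self._ensemble([[0.0, 0, 0], [5.0, 0, 0]])
        mean, _ = interaction_energy(system, ens, [1], [2], cutoff_nm=1.0)
        assert mean == 0.0

    def test_additivity_of_kinds(self):
        system = two_particle_system(charges=(1.0, -1.0), sigma=0.3, eps=0.2)
        frame = Frame(np.array([[0.0, 0, 0], [0.4, 0, 0]]))
        engine = PairForceEngine(system, 2.0)
        total = engine.nonbonded_group_energy(frame.coordinates, [1], [2])
        _, _, _, e_coul, _, e_lj, _ = engine._nonbonded_raw(frame.coordinates)
        assert total == pytest.approx(float(e_coul.sum() + e_lj.sum()))

    def test_empty_group_errors(self):
        system = two_particle_system(charges=(1.0, -1.0))
        ens = self._ensemble([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError):
            interaction_energy(system, ens, [], [2], cutoff_nm=1.0)


class TestMatrixInvariants:
    def test_no_diagonal_and_canonical_keys(self):
        rng = np.random.default_rng(21)
        system, frame = make_random_system(rng, n_atoms=12)
        m = pairwise_forces_frame(system, frame, cutoff_nm=100.0)
        for i, j in m.data:
            assert i < j

    def test_momentum_balance_of_pair_sums(self):
        rng = np.random.default_rng(22)
        system, frame = make_random_system(rng, n_atoms=12)
        engine = PairForceEngine(system, cutoff_nm=100.0)
        _, forces = engine.energy_forces(frame.coordinates)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9


class TestRigidMotionInvariance:
    def test_scalar_pair_values_invariant(self):
        rng = np.random.default_rng(33)
        system, frame = make_random_system(rng, n_atoms=12)
        engine = PairForceEngine(system, cutoff_nm=100.0)
        base, _, _ = engine.scalar_pair_values(frame.coordinates)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.2, 1.1, -0.4]).as_matrix()
        moved = frame.coordinates @ rot.T + np.array([3.0, -1.0, 0.5])
        rotated, _, _ = engine.scalar_pair_values(moved)
        np.testing.assert_allclose(rotated, base, atol=1e-8)
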