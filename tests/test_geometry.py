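"""Kabsch superposition, salt bridges, Ser->Asp mutation, RMSD/RMSF."""

import math

import numpy as np
import pytest

from agcphos.geometry import (
    BASIC_N,
    dihedral,
    kabsch_superpose,
    matched_ca_rmsd,
    mutate_ser_to_asp,
    place_atom,
    rmsd_trace,
    rmsf,
    saltbridge_network,
)
from agcphos.pdbio import Trajectory
from agcphos.synthetic import (
    gen_phospho_site_structure,
    gen_structure_pair,
    gen_trajectory,
    rotation_matrix,
)
from tests.conftest import brute_force_min_rmsd


class TestKabsch:
    def test_identity(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        R, t, r = kabsch_superpose(X, X)
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)

    def test_rigid_motion_gives_zero(self):
        X = np.random.default_rng(1).normal(size=(25, 3))
        R90 = rotation_matrix(np.array([0.0, 0.0, 1.0]), 90.0)
        Y = X @ R90.T + np.array([3.0, -1.0, 7.0])
        assert kabsch_superpose(X, Y)[2] == pytest.approx(0.0, abs=1e-10)

    def test_minimal_asymmetric_case_matches_numerical_minimum(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        Y = np.array([[0.0, 0, 1], [1, 0, 0], [0, 1, 0]])
        assert kabsch_superpose(X, Y)[2] == pytest.approx(
            brute_force_min_rmsd(X, Y), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_minimisation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        X = rng.normal(size=(n, 3)) * 3
        Y = rng.normal(size=(n, 3)) * 3
        assert kabsch_superpose(X, Y)[2] == pytest.approx(
            brute_force_min_rmsd(X, Y), abs=1e-6
        )

    def test_matches_scipy_rotation_alignment(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(12)
        X, Y = rng.normal(size=(2, 30, 3))
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        _, rssd = Rotation.align_vectors(Yc, Xc)
        assert kabsch_superpose(X, Y)[2] == pytest.approx(
            rssd / math.sqrt(len(X)), abs=1e-9
        )

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(2, 15, 3))
        r_xy = kabsch_superpose(X, Y)[2]
        assert kabsch_superpose(Y, X)[2] == pytest.approx(r_xy, abs=1e-9)
        R = rotation_matrix(rng.normal(size=3), 37.0)
        assert kabsch_superpose(X @ R.T + 5.0, Y)[2] == pytest.approx(r_xy, abs=1e-9)

    def test_no_reflection(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3))
        Y = X.copy()
        Y[:, 0] *= -1  # mirror image
        R, _, r = kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert r > 0.1

    def test_size_mismatch_error(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestMatchedCaRmsd:
    def test_self_pairing_is_zero(self):
        a, _, _ = gen_structure_pair(n_atoms=20, seed=0)
        pairs = [(i + 1, i + 1) for i in range(20)]
        assert matched_ca_rmsd(a, a, pairs) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self):
        a, b, _ = gen_structure_pair(n_atoms=30, noise_sigma=0.0, seed=1)
        pairs = [(i + 1, i + 1) for i in range(30)]
        assert matched_ca_rmsd(a, b, pairs) == pytest.approx(0.0, abs=1e-10)

    def test_missing_ca_error_names_residue(self):
        a, _, _ = gen_structure_pair(n_atoms=5, seed=2)
        with pytest.raises(KeyError, match="A:99"):
            matched_ca_rmsd(a, a, [(1, 1), (99, 2)])


class TestSaltBridges:
    def test_planted_contacts_recovered(self, planted_site):
        model, _, spec = planted_site
        contacts = saltbridge_network(model, ("A", 227), cutoff=4.0)
        # the 2.2 and 3.0 Å arginines bridge; the 5.2 Å lysine does not
        assert [c.basic_residue[2] for c in contacts] == ["ARG", "ARG"]
        assert [c.min_distance for c in contacts] == pytest.approx(
            [2.2, 3.0], abs=1e-6
        )

    def test_asp_center_discriminates_near_from_far(self):
        model, _ = gen_phospho_site_structure(
            [("ARG", 2.8), ("LYS", 5.2)], center_type="ASP", seed=4
        )
        contacts = saltbridge_network(model, ("A", 227), cutoff=4.0)
        assert len(contacts) == 1
        assert contacts[0].basic_residue[2] == "ARG"
        assert contacts[0].min_distance == pytest.approx(2.8, abs=1e-6)

    def test_monotone_in_cutoff(self, planted_site):
        model, _, _ = planted_site
        previous: set = set()
        for cutoff in (2.0, 2.5, 3.5, 4.5, 6.0):
            now = {
                c.basic_residue
                for c in saltbridge_network(model, ("A", 227), cutoff=cutoff)
            }
            assert previous <= now
            previous = now

    def test_empty_network_below_any_contact(self, planted_site):
        model, _, _ = planted_site
        assert saltbridge_network(model, ("A", 227), cutoff=1.9) == []

    def test_wrong_center_type_is_error(self, planted_site):
        model, _, _ = planted_site
        with pytest.raises(ValueError):
            saltbridge_network(model, ("A", 201))  # an ARG, not acidic
        with pytest.raises(KeyError):
            saltbridge_network(model, ("A", 999))

    def test_sorted_by_distance(self, planted_site):
        model, _, _ = planted_site
        contacts = saltbridge_network(model, ("A", 227), cutoff=8.0)
        dists = [c.min_distance for c in contacts]
        assert dists == sorted(dists)


class TestMutateSerToAsp:
    def test_isolated_serine_atom_set(self):
        model, _ = gen_phospho_site_structure([], center_type="SEP", seed=0)
        mutant = mutate_ser_to_asp(model, ("A", 227))
        names = {a.name for a in mutant.residue("A", 227)}
        assert names == {"N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"}
        assert mutant.residue("A", 227)[0].residue_name == "ASP"

    def test_environment_atoms_do_not_move(self, planted_site):
        model, _, _ = planted_site
        mutant = mutate_ser_to_asp(model, ("A", 227))
        before = {
            (a.chain, a.residue_number, a.name): a.coords
            for a in model.atoms
            if a.residue_number != 227
        }
        after = {
            (a.chain, a.residue_number, a.name): a.coords
            for a in mutant.atoms
            if a.residue_number != 227
        }
        assert before == after

    def test_ideal_side_chain_geometry(self, planted_site):
        model, _, _ = planted_site
        mutant = mutate_ser_to_asp(model, ("A", 227))
        atoms = {a.name: np.array(a.coords) for a in mutant.residue("A", 227)}
        assert np.linalg.norm(atoms["CG"] - atoms["CB"]) == pytest.approx(1.516, abs=1e-3)
        for od in ("OD1", "OD2"):
            assert np.linalg.norm(atoms[od] - atoms["CG"]) == pytest.approx(1.249, abs=1e-3)
        # OD1 and OD2 are anti across the carboxylate plane
        chi2_od1 = dihedral(atoms["CA"], atoms["CB"], atoms["CG"], atoms["OD1"])
        chi2_od2 = dihedral(atoms["CA"], atoms["CB"], atoms["CG"], atoms["OD2"])
        assert abs(abs(chi2_od1 - chi2_od2) - 180.0) < 1e-3

    def test_backbone_unchanged(self, planted_site):
        model, _, _ = planted_site
        mutant = mutate_ser_to_asp(model, ("A", 227))
        for name in ("N", "CA", "C", "O", "CB"):
            assert model.atom("A", 227, name).coords == mutant.atom(
                "A", 227, name
            ).coords

    def test_chosen_rotamer_is_the_exhaustive_best(self, planted_site):
        """Re-score every candidate rotamer independently; the op's pick
        must achieve the maximal (clash, salt-bridge) score."""
        from agcphos.geometry import (
            CHI1_CANDIDATES,
            CHI2_CANDIDATES,
            CLASH_DISTANCE,
            SALT_BRIDGE_REWARD_CUTOFF,
            _ANGLE_CA_CB_CG,
            _ANGLE_CB_CG_OD,
            _BOND_CB_CG,
            _BOND_CG_OD,
        )

        model, _, _ = planted_site
        mutant = mutate_ser_to_asp(model, ("A", 227))
        env = np.array(
            [a.coords for a in model.atoms if a.residue_number != 227]
        )
        basic = np.array(
            [
                a.coords
                for a in model.atoms
                if a.residue_name in BASIC_N and a.name in BASIC_N[a.residue_name]
            ]
        )
        n = np.array(model.atom("A", 227, "N").coords)
        ca = np.array(model.atom("A", 227, "CA").coords)
        cb = np.array(model.atom("A", 227, "CB").coords)

        def score(cg, od1, od2):
            s = 0.0
            for atom in (cg, od1, od2):
                if (np.linalg.norm(env - atom, axis=1) < CLASH_DISTANCE).any():
                    s -= 10.0
            for atom in (od1, od2):
                if (np.linalg.norm(basic - atom, axis=1) <= SALT_BRIDGE_REWARD_CUTOFF).any():
                    s += 1.0
            return s

        best = -np.inf
        for chi1 in CHI1_CANDIDATES:
            cg = place_atom(n, ca, cb, _BOND_CB_CG, _ANGLE_CA_CB_CG, chi1)
            for chi2 in CHI2_CANDIDATES:
                od1 = place_atom(ca, cb, cg, _BOND_CG_OD, _ANGLE_CB_CG_OD, chi2)
                od2 = place_atom(ca, cb, cg, _BOND_CG_OD, _ANGLE_CB_CG_OD, chi2 + 180)
                best = max(best, score(cg, od1, od2))
        atoms = {a.name: np.array(a.coords) for a in mutant.residue("A", 227)}
        assert score(atoms["CG"], atoms["OD1"], atoms["OD2"]) == pytest.approx(best)

    def test_determinism(self, planted_site):
        model, _, _ = planted_site
        m1 = mutate_ser_to_asp(model, ("A", 227))
        m2 = mutate_ser_to_asp(model, ("A", 227))
        np.testing.assert_array_equal(m1.coords(), m2.coords())

    def test_wrong_residue_is_error(self, planted_site):
        model, _, _ = planted_site
        with pytest.raises(ValueError):
            mutate_ser_to_asp(model, ("A", 201))


class TestRmsdTrace:
    def test_identical_frames_all_zero(self):
        traj, _ = gen_trajectory(5, np.zeros(10), seed=0)
        trace = rmsd_trace(traj, traj.models[0])
        assert all(r == pytest.approx(0.0, abs=1e-9) for _, r in trace)

    def test_rigid_motions_all_zero(self):
        traj, _ = gen_trajectory(8, np.zeros(12), global_wobble=True, seed=1)
        trace = rmsd_trace(traj, traj.models[0])
        assert all(r == pytest.approx(0.0, abs=1e-8) for _, r in trace)

    def test_noise_trace_matches_sigma_sqrt3(self):
        sigma = 0.4
        traj, _ = gen_trajectory(100, np.full(200, sigma), seed=2)
        trace = rmsd_trace(traj, traj.models[0])
        # frame 0 to itself is 0; later frames fluctuate around sigma*sqrt(3)
        # relative to the (itself noisy) reference: sqrt(2)*sigma*sqrt(3)
        assert trace[0][1] == pytest.approx(0.0, abs=1e-9)
        mean_later = np.mean([r for f, r in trace[1:]])
        assert mean_later == pytest.approx(
            math.sqrt(2) * sigma * math.sqrt(3), rel=0.1
        )


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        traj, _ = gen_trajectory(10, np.zeros(10), seed=0)
        assert all(v == pytest.approx(0.0, abs=1e-12) for _, v in rmsf(traj))

    def test_recovers_sigma_sqrt3(self):
        sigma = 0.5
        traj, _ = gen_trajectory(2000, np.full(60, sigma), seed=3)
        values = np.array([v for _, v in rmsf(traj)])
        assert np.mean(values) == pytest.approx(sigma * math.sqrt(3), rel=0.05)

    def test_global_wobble_removed_by_superposition(self):
        traj, _ = gen_trajectory(20, np.zeros(15), global_wobble=True, seed=4)
        assert all(v == pytest.approx(0.0, abs=1e-6) for _, v in rmsf(traj))

    def test_scaling_equivariance(self):
        traj, _ = gen_trajectory(50, np.full(20, 0.3), seed=5)
        scaled = Trajectory(
            models=[m.with_coords(m.coords() * 2.0) for m in traj.models]
        )
        v1 = np.array([v for _, v in rmsf(traj)])
        v2 = np.array([v for _, v in rmsf(scaled)])
        np.testing.assert_allclose(v2, 2.0 * v1, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_flexible_group_always_exceeds_rigid_group(self, seed):
        sigma = np.full(30, 0.2)
        sigma[10:20] = 0.8
        traj, _ = gen_trajectory(60, sigma, seed=seed)
        values = np.array([v for _, v in rmsf(traj)])
        assert values[10:20].mean() > np.r_[values[:10], values[20:]].mean()

    def test_single_frame_is_error(self):
        traj, _ = gen_trajectory(2, np.zeros(5), seed=0)
        with pytest.raises(ValueError):
            rmsf(Trajectory(models=traj.models[:1]))
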