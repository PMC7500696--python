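import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import helixcheck as hx
from helixcheck.geometry import dihedral_angle, superpose_coords, wrap_angle

from conftest import brute_force_dihedral, brute_force_kabsch_rmsd

BB = hx.AtomSelection.parse("*:*:N,CA,C")


def random_rigid_transform(rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.normal(0, 20, 3)
    return rot, trans


def apply_rigid(structure, rot, trans):
    out = structure.copy()
    for m in out.models:
        m.set_coords(m.coords() @ rot.T + trans)
    return out


class TestBackboneDihedrals:
    def test_ideal_helix_round_trip(self, helix10):
        d = hx.backbone_dihedrals(helix10)
        for r in range(2, 11):
            assert d.phi[r] == pytest.approx(-60.0, abs=1e-3)
        for r in range(1, 10):
            assert d.psi[r] == pytest.approx(-45.0, abs=1e-3)
        assert d.phi[1] is None and d.psi[10] is None

    def test_two_residue_chain_has_no_interior_angles(self):
        st = hx.build_ideal_helix(2)
        d = hx.backbone_dihedrals(st)
        assert d.phi[1] is None and d.psi[2] is None
        assert d.phi[2] is not None and d.psi[1] is not None

    def test_agrees_with_brute_force_oracle_on_random_backbone(self, rng):
        # random (but chemically plausible) torsions round-tripped
        for _ in range(20):
            phi = rng.uniform(-180, 175)
            psi = rng.uniform(-180, 175)
            st = hx.build_ideal_helix(8, phi, psi)
            atoms = {r.index: {a.name: a.xyz for a in r.atoms}
                     for r in st.models[0].chains[0].residues}
            d = hx.backbone_dihedrals(st)
            for i in range(2, 8):
                expected = brute_force_dihedral(atoms[i - 1]["C"], atoms[i]["N"],
                                                atoms[i]["CA"], atoms[i]["C"])
                assert d.phi[i] == pytest.approx(expected, abs=1e-9)

    def test_random_point_quadruples_match_oracle(self, rng):
        for _ in range(200):
            pts = rng.normal(0, 5, (4, 3))
            assert dihedral_angle(*pts) == pytest.approx(
                brute_force_dihedral(*pts), abs=1e-9)


class TestSuperposition:
    def test_self_fit_is_identity(self, helix10):
        res = hx.kabsch_superpose(helix10, helix10, BB)
        assert res.rmsd_fit == pytest.approx(0.0, abs=1e-9)
        assert res.rmsd_calc == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_recovers_applied_rotation(self, helix10, rng):
        rot, trans = random_rigid_transform(rng)
        moved = apply_rigid(helix10, rot, trans)
        res = hx.kabsch_superpose(helix10, moved, BB)
        assert res.rmsd_fit == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.rotation, rot.T, atol=1e-6)

    def test_rotation_is_proper_orthonormal(self, helix10, rng):
        jittered = helix10.copy()
        jittered.models[0].set_coords(
            jittered.models[0].coords() + rng.normal(0, 1.0, (49, 3)))
        res = hx.kabsch_superpose(helix10, jittered, BB)
        r = res.rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_svd_oracle_under_jitter(self, rng):
        for _ in range(25):
            ref = rng.normal(0, 10, (200, 3))
            mob = ref + rng.normal(0, 0.5, (200, 3))
            res = superpose_coords(ref, mob)
            assert res.rmsd_fit == pytest.approx(
                brute_force_kabsch_rmsd(ref, mob), abs=1e-9)

    def test_symmetry_of_rmsd(self, rng):
        a = rng.normal(0, 10, (50, 3))
        b = a + rng.normal(0, 1.0, (50, 3))
        assert superpose_coords(a, b).rmsd_fit == pytest.approx(
            superpose_coords(b, a).rmsd_fit, abs=1e-9)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            superpose_coords(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_fit_flagged_degenerate(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        assert superpose_coords(line, line).degenerate


class TestEnsembleRmsd:
    def test_identical_models_give_zero_matrix(self, helix10):
        ens = hx.perturb_ensemble(helix10, 0.0, 5)
        mat, stats = hx.pairwise_ensemble_rmsd(ens, BB)
        np.testing.assert_allclose(mat, 0.0, atol=1e-12)
        assert stats["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_is_symmetric_nonnegative_zero_diagonal(self, helix10):
        ens = hx.perturb_ensemble(helix10, 0.5, 6, seed=3)
        mat, _ = hx.pairwise_ensemble_rmsd(ens, BB)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        assert np.all(mat >= 0) and np.all(np.diag(mat) == 0)

    def test_stats_match_direct_recomputation(self, helix10):
        ens = hx.perturb_ensemble(helix10, 0.7, 8, seed=5)
        mat, stats = hx.pairwise_ensemble_rmsd(ens, BB)
        coords = [BB.coords(ens, i) for i in range(8)]
        expected = []
        for i in range(8):
            for j in range(i + 1, 8):
                expected.append(brute_force_kabsch_rmsd(coords[i], coords[j]))
        assert stats["mean"] == pytest.approx(np.mean(expected), abs=1e-9)
        assert stats["sem"] == pytest.approx(
            np.std(expected, ddof=1) / np.sqrt(len(expected)), abs=1e-9)

    def test_mean_within_3se_of_simulated_expectation(self, helix10):
        # oracle: direct simulation of many perturbed ensembles
        sigma, n_models = 0.5, 10
        sims = []
        for seed in range(150):
            ens = hx.perturb_ensemble(helix10, sigma, n_models, seed=1000 + seed)
            _, stats = hx.pairwise_ensemble_rmsd(ens, BB)
            sims.append(stats["mean"])
        sims = np.array(sims)
        _, stats = hx.pairwise_ensemble_rmsd(
            hx.perturb_ensemble(helix10, sigma, n_models, seed=77), BB)
        se = sims.std(ddof=1)  # spread of the per-ensemble mean statistic
        assert abs(stats["mean"] - sims.mean()) < 3 * se

    def test_rigid_motion_invariance(self, helix10, rng):
        ens = hx.perturb_ensemble(helix10, 0.5, 5, seed=9)
        _, stats = hx.pairwise_ensemble_rmsd(ens, BB)
        rot, trans = random_rigid_transform(rng)
        moved = apply_rigid(ens, rot, trans)
        _, stats2 = hx.pairwise_ensemble_rmsd(moved, BB)
        assert stats2["mean"] == pytest.approx(stats["mean"], abs=1e-9)


class TestRollingRmsd:
    def test_static_trajectory_is_zero(self, helix10):
        traj = hx.synth_trajectory(helix10, 10, 0.0, 0.0)
        series = hx.rolling_rmsd(traj, 2, BB)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)
        assert len(series.values) == 8

    def test_rigid_body_motion_removed(self, helix10, rng):
        models = []
        for _ in range(8):
            rot, trans = random_rigid_transform(rng)
            models.append(apply_rigid(helix10, rot, trans).models[0])
        traj = hx.Structure(models)
        series = hx.rolling_rmsd(traj, 1, BB)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-6)

    def test_matches_frame_by_frame_oracle(self, helix10):
        traj = hx.synth_trajectory(helix10, 12, 0.3, 0.1, seed=4)
        lag = 3
        series = hx.rolling_rmsd(traj, lag, BB)
        coords = [BB.coords(traj, i) for i in range(12)]
        for k, t in enumerate(range(lag, 12)):
            assert series.values[k] == pytest.approx(
                brute_force_kabsch_rmsd(coords[t], coords[t - lag]), abs=1e-9)

    def test_drift_exceeds_jitter_only(self, helix10):
        jitter = hx.synth_trajectory(helix10, 40, 0.2, 0.0, seed=8)
        drift = hx.synth_trajectory(helix10, 40, 0.2, 0.15, seed=8)
        lag = 5
        assert hx.rolling_rmsd(drift, lag, BB).mean > \
            hx.rolling_rmsd(jitter, lag, BB).mean

    def test_nonpositive_lag_rejected(self, helix10):
        traj = hx.synth_trajectory(helix10, 5, 0.1, 0.0)
        with pytest.raises(ValueError):
            hx.rolling_rmsd(traj, 0, BB)


class TestDihedralRmsd:
    def test_structure_at_target_angles_scores_zero(self):
        st = hx.build_ideal_helix(12, -60, -45)
        targets = hx.synth_talos_records(12)
        d = hx.backbone_dihedrals(st)
        assert hx.dihedral_rmsd_to_target(d, targets, range(2, 12)) == \
            pytest.approx(0.0, abs=1e-3)

    def test_wraparound_difference_is_short_way(self):
        # target psi 179, observed -179: the difference is 2 degrees
        assert float(wrap_angle(-179.0 - 179.0)) == pytest.approx(2.0)
        d = hx.DihedralSet(phi={5: -60.0}, psi={5: -179.0})
        targets = [hx.TalosRecord(5, "ALA", -60.0, 179.0, 5, 5, 0, 0.9, 10, "Good")]
        rmsd = hx.dihedral_rmsd_to_target(d, targets, {5})
        assert rmsd == pytest.approx(np.sqrt((0**2 + 2.0**2) / 2), abs=1e-9)

    def test_matches_brute_force_loop(self, rng):
        for _ in range(50):
            resids = range(1, 21)
            d = hx.DihedralSet(
                phi={r: rng.uniform(-180, 180) for r in resids},
                psi={r: rng.uniform(-180, 180) for r in resids})
            targets = [hx.TalosRecord(r, "ALA", rng.uniform(-180, 179.9),
                                      rng.uniform(-180, 179.9), 5, 5, 0, 0.9,
                                      10, "Good") for r in resids]
            tmap = {t.resid: t for t in targets}
            acc = []
            for r in resids:
                for obs, tgt in ((d.phi[r], tmap[r].phi), (d.psi[r], tmap[r].psi)):
                    diff = (obs - tgt) % 360.0
                    if diff > 180.0:
                        diff -= 360.0
                    acc.append(diff ** 2)
            expected = np.sqrt(np.mean(acc))
            assert hx.dihedral_rmsd_to_target(d, targets, resids) == \
                pytest.approx(expected, abs=1e-9)

    def test_invariant_to_full_turns(self):
        d1 = hx.DihedralSet(phi={1: -60.0, 2: -60.0}, psi={1: -45.0, 2: -45.0})
        d2 = hx.DihedralSet(phi={1: 300.0, 2: -60.0}, psi={1: -45.0, 2: 315.0})
        targets = [hx.TalosRecord(r, "ALA", -55.0, -40.0, 5, 5, 0, 0.9, 10,
                                  "Good") for r in (1, 2)]
        assert hx.dihedral_rmsd_to_target(d1, targets, {1, 2}) == \
            pytest.approx(hx.dihedral_rmsd_to_target(d2, targets, {1, 2}),
                          abs=1e-9)

    def test_empty_residue_set_rejected(self):
        d = hx.DihedralSet(phi={1: 0.0}, psi={1: 0.0})
        with pytest.raises(ValueError):
            hx.dihedral_rmsd_to_target(d, [], set())


class TestHelixGeometry:
    def test_translated_copies_are_parallel(self, helix20):
        a = hx.helix_axis(helix20, (1, 20))
        shifted = helix20.copy()
        shifted.models[0].set_coords(shifted.models[0].coords() + [30, 0, 0])
        b = hx.helix_axis(shifted, (1, 20))
        assert hx.interhelix_angle(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_point_inversion_is_antiparallel(self, helix20):
        a = hx.helix_axis(helix20, (1, 20))
        inverted = helix20.copy()
        inverted.models[0].set_coords(-inverted.models[0].coords())
        b = hx.helix_axis(inverted, (1, 20))
        assert hx.interhelix_angle(a, b) == pytest.approx(180.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [0.0, 47.0, 90.0, 135.0])
    def test_bundle_crossing_angle_recovered(self, angle):
        bundle = hx.build_bundle([18, 18], angle)
        a = hx.helix_axis(bundle, (1, 18), chain="A")
        b = hx.helix_axis(bundle, (1, 18), chain="B")
        assert hx.interhelix_angle(a, b) == pytest.approx(angle, abs=2.0)

    def test_supplementary_angle_identity(self, two_chain_complex):
        a = hx.helix_axis(two_chain_complex, (1, 20), chain="A")
        b = hx.helix_axis(two_chain_complex, (1, 20), chain="B")
        flipped = hx.HelixAxis(-b.direction, b.centroid, b.residue_range)
        assert hx.interhelix_angle(a, b) + hx.interhelix_angle(a, flipped) == \
            pytest.approx(180.0, abs=1e-9)

    def test_too_few_residues_rejected(self, helix10):
        with pytest.raises(ValueError):
            hx.helix_axis(helix10, (1, 4))


class TestHelixAssignment:
    def test_ideal_helix_interior_is_helix(self, helix10):
        labels = hx.assign_helix_by_dihedrals(hx.backbone_dihedrals(helix10))
        assert all(labels[r] == "helix" for r in range(2, 10))
        assert labels[1] == "coil" and labels[10] == "coil"

    def test_extended_chain_is_coil(self):
        st = hx.build_ideal_helix(10, -135.0, 135.0)
        labels = hx.assign_helix_by_dihedrals(hx.backbone_dihedrals(st))
        assert set(labels.values()) == {"coil"}

    def test_alternating_residues_fail_run_length(self):
        phis = {r: -60.0 if r % 2 else -135.0 for r in range(1, 11)}
        psis = {r: -45.0 if r % 2 else 135.0 for r in range(1, 11)}
        labels = hx.assign_helix_by_dihedrals(hx.DihedralSet(phis, psis))
        assert set(labels.values()) == {"coil"}

    def test_short_run_below_minimum_is_coil(self):
        phis = {r: -60.0 for r in range(1, 4)}
        psis = {r: -45.0 for r in range(1, 4)}
        labels = hx.assign_helix_by_dihedrals(hx.DihedralSet(phis, psis))
        assert set(labels.values()) == {"coil"}


class TestContourLength:
    def test_zero_counts(self):
        assert hx.contour_length(0, 0) == 0.0

    def test_printed_linker_lengths(self):
        assert hx.contour_length(13, 5) == 59.5
        assert hx.contour_length(57, 52) == 306.0

    def test_linearity(self, rng):
        for _ in range(20):
            a, b = rng.integers(0, 100, 2)
            c, d = rng.integers(0, 100, 2)
            assert hx.contour_length(a + c, b + d) == pytest.approx(
                hx.contour_length(a, b) + hx.contour_length(c, d))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hx.contour_length(-1, 5)
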