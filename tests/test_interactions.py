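"""Contacts, hydrogen bonds, salt bridges, covariance matrices."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mdligand as ml
from mdligand.errors import SelectionError
from mdligand.interactions import detect_hbonds

from conftest import point_topology
from oracles import brute_force_contact_map


def hbond_triple_topology():
    """N donor with one H, plus an O acceptor, as bare atoms."""
    top = point_topology(3, element=["N", "H", "O"], radius=1.5)
    # derive roles from a reference geometry with H bonded to N
    from mdligand.io import derive_hbond_roles

    ref = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.29, 0, 0]])
    roles = derive_hbond_roles(np.array(["N", "H", "O"]), ref)
    top.hbond_roles = roles
    return top


def place_acceptor(distance_A, angle_deg):
    """N at origin, H at 1 Å on +x, acceptor at the given N...O distance and
    D-H...A angle (computed by explicit construction)."""
    n = np.zeros(3)
    h = np.array([0.1, 0.0, 0.0])
    theta = np.deg2rad(angle_deg)
    a_dir = np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    d = distance_A / 10.0
    b = np.dot(h - n, a_dir)
    s = -b + np.sqrt(b * b - (np.dot(h - n, h - n) - d * d))
    return np.array([n, h, h + s * a_dir])


class TestHBondCriterion:
    @pytest.mark.parametrize(
        "distance,angle,bonded",
        [
            (2.9, 180.0, True),
            (3.6, 180.0, False),
            (2.9, 140.0, False),
            (2.9, 155.0, True),
        ],
    )
    def test_constructed_geometries(self, distance, angle, bonded):
        top = hbond_triple_topology()
        coords = place_acceptor(distance, angle)
        records = detect_hbonds(coords, top)
        assert (len(records) == 1) is bonded
        if bonded:
            assert records[0].distance_A == pytest.approx(distance, abs=1e-6)
            assert records[0].angle_deg == pytest.approx(angle, abs=1e-6)

    def test_invariant_under_rigid_transform(self, rng):
        top = hbond_triple_topology()
        coords = place_acceptor(2.9, 165.0)
        rot = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True)
        moved = coords @ rot.as_matrix().T + rng.normal(size=3)
        records = detect_hbonds(moved, top)
        assert len(records) == 1
        assert records[0].distance_A == pytest.approx(2.9, abs=1e-6)
        assert records[0].angle_deg == pytest.approx(165.0, abs=1e-6)


class TestHBondCountSeries:
    def test_stable_bonds_constant_count(self):
        spec = ml.SyntheticSpec(
            n_residues=8, n_frames=100, fluct_sigma=0.01,
            planted_hbonds=[ml.PlantedHBond(1, 6, 1.0)], seed=1,
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        series, dens = ml.hbond_count_series(traj, top)
        np.testing.assert_array_equal(series.values, 1.0)
        assert dens.peak_location == pytest.approx(1.0)
        assert dens.peak_probability == 1.0

    def test_half_fraction_splits_density(self):
        spec = ml.SyntheticSpec(
            n_residues=10, n_frames=1000, fluct_sigma=0.01,
            planted_hbonds=[
                ml.PlantedHBond(1, 6, 1.0),
                ml.PlantedHBond(3, 8, 0.5),
            ],
            seed=2,
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        _, dens = ml.hbond_count_series(traj, top)
        centers = dens.bin_centers[dens.probabilities > 0]
        probs = dens.probabilities[dens.probabilities > 0]
        assert sorted(np.round(centers).astype(int)) == [1, 2]
        se = 3 * np.sqrt(0.25 / 1000)
        assert np.all(np.abs(probs - 0.5) < se)

    def test_no_donors_all_zero(self):
        top = point_topology(4, element="C")
        traj = ml.Trajectory(
            [0.0, 1.0], np.random.default_rng(0).normal(size=(2, 4, 3))
        )
        series, _ = ml.hbond_count_series(traj, top)
        np.testing.assert_array_equal(series.values, 0.0)


class TestContacts:
    def test_always_close_ligand_probability_one(self):
        spec = ml.SyntheticSpec(
            n_residues=6, ligand_rings=1, n_frames=50, fluct_sigma=0.0,
            planted_contacts=[ml.PlantedContact(2, 1.0, distance_in_nm=0.30)],
            seed=0,
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        cmap = ml.contact_probability(
            traj, top,
            ml.SelectionSpec("entity", "protein", "p"),
            ml.SelectionSpec("entity", "ligand", "l"),
            cutoff=0.46,
        )
        row = list(cmap.residues_a).index(2)
        assert cmap.probabilities[row, 0] == 1.0

    def test_planted_fraction_recovered(self, demo):
        top, traj, gt = demo
        eq = ml.discard_burn_in(traj, 100.0)
        cmap = ml.contact_probability(
            eq, top,
            ml.SelectionSpec("entity", "protein", "p"),
            ml.SelectionSpec("entity", "ligand", "l"),
            cutoff=0.54,
        )
        row = list(cmap.residues_a).index(14)
        measured = cmap.probabilities[row, 0]
        true_frac = gt.contact_masks[0][gt.stationary].mean()
        assert measured == pytest.approx(true_frac, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        spec = ml.SyntheticSpec(
            n_residues=5, n_frames=8, fluct_sigma=0.15, seed=6
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        sel = ml.SelectionSpec("entity", "protein", "p")
        cmap = ml.contact_probability(
            traj, top, sel, cutoff=0.46, exclude_neighbors=-1
        )
        heavy = np.flatnonzero(top.heavy_mask())
        oracle = brute_force_contact_map(
            traj.coordinates, top, heavy, heavy, 0.46
        )
        np.testing.assert_array_equal(cmap.probabilities, oracle)

    def test_overlapping_groups_rejected(self, demo):
        top, traj, _ = demo
        sel = ml.SelectionSpec("entity", "protein", "p")
        with pytest.raises(SelectionError):
            ml.contact_probability(traj, top, sel, sel, cutoff=0.46)

    def test_symmetric_map(self, demo):
        top, traj, _ = demo
        sub = ml.Trajectory(traj.times[:20], traj.coordinates[:20])
        cmap = ml.contact_probability(
            sub, top, ml.SelectionSpec("entity", "protein", "p"), cutoff=0.46
        )
        np.testing.assert_allclose(cmap.probabilities, cmap.probabilities.T)
        assert cmap.probabilities.min() >= 0 and cmap.probabilities.max() <= 1


class TestSaltBridge:
    def test_constructed_distance(self):
        spec = ml.SyntheticSpec(
            n_residues=4, residue_plan=["ALA", "ARG", "ALA", "ASP"],
            n_frames=50, fluct_sigma=0.01,
            planted_saltbridge=ml.PlantedSaltBridge(1, 3, 0.18), seed=3,
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        series, dens = ml.saltbridge_distance(traj, top, (1, 3))
        np.testing.assert_allclose(series.values, 0.18, atol=1e-9)
        assert dens.peak_probability == 1.0
        assert dens.peak_location == pytest.approx(0.18, rel=1e-5)

    def test_bimodal_trace(self):
        trace = np.tile([0.18, 0.70], 250)
        spec = ml.SyntheticSpec(
            n_residues=4, residue_plan=["ALA", "LYS", "ALA", "GLU"],
            n_frames=500, fluct_sigma=0.01,
            planted_saltbridge=ml.PlantedSaltBridge(1, 3, trace), seed=4,
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        series, dens = ml.saltbridge_distance(traj, top, (1, 3))
        near = np.isclose(series.values, 0.18, atol=1e-6).mean()
        far = np.isclose(series.values, 0.70, atol=1e-6).mean()
        assert near == far == 0.5

    def test_uncharged_pair_rejected(self, demo):
        top, traj, _ = demo
        with pytest.raises(SelectionError):
            ml.saltbridge_distance(traj, top, (0, 1))


class TestCovariance:
    def test_rho_one_block_unity(self, covariance_run):
        _, top, traj, _ = covariance_run
        corr = ml.covariance_matrix(traj, top, superpose=False)
        idx = {v: i for i, v in enumerate(corr.residue_indices)}
        assert corr.values[idx[10], idx[11]] == pytest.approx(1.0, abs=1e-6)
        assert corr.values[idx[11], idx[12]] == pytest.approx(1.0, abs=1e-6)

    def test_negative_block_recovered(self, covariance_run):
        _, top, traj, _ = covariance_run
        corr = ml.covariance_matrix(traj, top)
        idx = {v: i for i, v in enumerate(corr.residue_indices)}
        assert corr.values[idx[20], idx[21]] == pytest.approx(-0.8, abs=0.05)

    def test_independent_residues_near_zero(self, covariance_run):
        _, top, traj, _ = covariance_run
        corr = ml.covariance_matrix(traj, top)
        idx = {v: i for i, v in enumerate(corr.residue_indices)}
        assert abs(corr.values[idx[30], idx[45]]) < 0.05

    def test_unit_diagonal_and_symmetry(self, covariance_run):
        _, top, traj, _ = covariance_run
        sub = ml.Trajectory(traj.times[:200], traj.coordinates[:200])
        corr = ml.covariance_matrix(sub, top)
        np.testing.assert_allclose(np.diag(corr.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        assert corr.values.min() >= -1 - 1e-12
        assert corr.values.max() <= 1 + 1e-12

    def test_zero_variance_flagged_not_nan(self):
        spec = ml.SyntheticSpec(
            n_residues=5, n_frames=50,
            fluct_sigma=np.array([0.02, 0.02, 0.0, 0.02, 0.02]), seed=5,
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        corr = ml.covariance_matrix(traj, top, superpose=False)
        assert not np.any(np.isnan(corr.values))
        assert not corr.defined[2, 0]
        assert corr.defined[0, 1]
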