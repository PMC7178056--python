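"""Coulomb/LJ terms, Born radii, GB polar energy, nonpolar term, MM/GB-SA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mdligand as ml
from mdligand.energy import (
    COULOMB_K,
    BornRadii,
    born_radii,
    coulomb_energy,
    gb_polar_binding,
    gb_polar_energy,
    lj_energy,
    mmgbsa_frame,
    surf_nonpolar_binding,
)
from mdligand.errors import SelectionError, SingularityError
from mdligand.model import AnalysisConfig, SelectionSpec
from mdligand.parameters import HCT_SCREEN

from conftest import point_topology
from oracles import numeric_descreening_integral


class TestCoulomb:
    def test_unit_charges_closed_form(self):
        """+1e and -1e at 3.320637 Å give exactly -100 kcal/mol."""
        top = point_topology(2, charge=[1.0, -1.0])
        coords = np.array([[0.0, 0, 0], [0.3320637, 0, 0]])
        e = coulomb_energy(coords, top, np.array([0]), np.array([1]))
        assert e == pytest.approx(-100.0, rel=1e-12)

    def test_zero_charge_contributes_nothing(self):
        top = point_topology(2, charge=[0.0, 1.0])
        coords = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        assert coulomb_energy(coords, top, np.array([0]), np.array([1])) == 0.0

    def test_bilinearity_in_charges(self):
        top1 = point_topology(2, charge=[0.5, -0.3])
        top2 = point_topology(2, charge=[1.0, -0.6])
        coords = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        e1 = coulomb_energy(coords, top1, np.array([0]), np.array([1]))
        e2 = coulomb_energy(coords, top2, np.array([0]), np.array([1]))
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_coincident_atoms_rejected(self):
        top = point_topology(2, charge=1.0)
        with pytest.raises(SingularityError):
            coulomb_energy(np.zeros((2, 3)), top, np.array([0]), np.array([1]))


class TestLennardJones:
    def test_minimum_is_minus_epsilon(self):
        sigma, eps = 0.34, 0.086
        top = point_topology(2, sigma=sigma, epsilon=eps)
        r = 2.0 ** (1.0 / 6.0) * sigma
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        e = lj_energy(coords, top, np.array([0]), np.array([1]))
        assert e == pytest.approx(-eps, rel=1e-12)

    def test_zero_at_sigma(self):
        top = point_topology(2, sigma=0.34, epsilon=0.086)
        coords = np.array([[0.0, 0, 0], [0.34, 0, 0]])
        e = lj_energy(coords, top, np.array([0]), np.array([1]))
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_cross_sum_matches_hand_computation(self):
        """3-atom cross sum with Lorentz-Berthelot mixing, done by hand."""
        top = point_topology(3, sigma=[0.30, 0.34, 0.38], epsilon=[0.1, 0.2, 0.15])
        coords = np.array([[0.0, 0, 0], [0.45, 0, 0], [0.0, 0.5, 0]])
        e = lj_energy(coords, top, np.array([0]), np.array([1, 2]))

        def pair(si, sj, ei, ej, r):
            s = 0.5 * (si + sj)
            x6 = (s / r) ** 6
            return 4 * np.sqrt(ei * ej) * (x6 * x6 - x6)

        expected = pair(0.30, 0.34, 0.1, 0.2, 0.45) + pair(0.30, 0.38, 0.1, 0.15, 0.5)
        assert e == pytest.approx(expected, rel=1e-12)


class TestBornRadii:
    def test_isolated_atom_offset_convention(self):
        top = point_topology(1, radius=2.0)
        br = born_radii(np.zeros((1, 3)), top)
        assert br.radii[0] == pytest.approx(2.0 - 0.09, rel=1e-12)

    def test_pair_matches_numeric_descreening_oracle(self):
        """HCT pairwise descreening equals grid quadrature of the
        Coulomb-field 1/r^4 integral over the neighbour's scaled sphere."""
        top = point_topology(2, radius=[2.0, 1.8])
        rho0 = 2.0 - 0.09
        sj = HCT_SCREEN["C"] * (1.8 - 0.09)
        for d_A in (3.2, 4.5, 6.0):
            coords = np.array([[0.0, 0, 0], [d_A / 10.0, 0, 0]])
            br = born_radii(coords, top)
            integral = numeric_descreening_integral(rho0, sj, d_A)
            r_num = 1.0 / (1.0 / rho0 - integral)
            assert br.radii[0] == pytest.approx(r_num, rel=2e-3)
            assert br.radii[0] > rho0  # burial grows the effective radius

    def test_invariant_under_rigid_motion(self, rng):
        top = point_topology(4, radius=[1.5, 1.7, 2.0, 1.6])
        coords = rng.normal(size=(4, 3)) * 0.3
        base = born_radii(coords, top).radii
        rot = Rotation.from_euler("zyx", rng.uniform(0, 360, 3), degrees=True)
        moved = coords @ rot.as_matrix().T + rng.normal(size=3)
        np.testing.assert_allclose(born_radii(moved, top).radii, base, rtol=1e-10)


class TestGBPolar:
    def test_born_ion_closed_form(self):
        """Self energy of a single ion matches the Born equation."""
        top = point_topology(1, charge=1.0, radius=2.0)
        radii = BornRadii(np.array([0]), np.array([2.0]))
        g = gb_polar_energy(np.zeros((1, 3)), top, radii)
        expected = -0.5 * COULOMB_K * (1 - 1 / 78.5) / 2.0
        assert g == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-81.96, abs=0.01)

    def test_zero_charges_zero_energy(self):
        top = point_topology(3, charge=0.0)
        coords = np.random.default_rng(0).normal(size=(3, 3))
        br = born_radii(coords, top)
        assert gb_polar_energy(coords, top, br) == 0.0

    def test_two_ion_large_separation_expansion(self):
        """At large r, GB tends to the sum of Born self energies plus the
        screened Coulomb cross term."""
        top = point_topology(2, charge=[1.0, -1.0], radius=2.0)
        r_A = 80.0
        coords = np.array([[0.0, 0, 0], [r_A / 10.0, 0, 0]])
        br = born_radii(coords, top)
        g = gb_polar_energy(coords, top, br)
        fac = 1 - 1 / 78.5
        self_terms = 2 * (-0.5 * COULOMB_K * fac / (2.0 - 0.09))
        cross = -COULOMB_K * fac * (1.0 * -1.0) / r_A
        assert g == pytest.approx(self_terms + cross, rel=0.01)

    def test_binding_decomposition_sums(self, rng):
        top = point_topology(6, charge=[0.3, -0.3, 0.2, -0.2, 0.1, -0.1],
                             radius=1.7)
        coords = rng.normal(size=(6, 3)) * 0.25
        rec, lig = np.array([0, 1, 2]), np.array([3, 4, 5])
        dg, per_atom = gb_polar_binding(coords, top, rec, lig)
        assert per_atom.sum() == pytest.approx(dg, abs=1e-12)


class TestNonpolar:
    def test_isolated_sphere_gamma_area(self):
        top = point_topology(1, radius=1.9)
        e = ml.surf_nonpolar(np.zeros((1, 3)), top, gamma=0.0072)
        exact = 0.0072 * 4 * np.pi * 3.3 ** 2
        assert e == pytest.approx(exact, rel=0.01)
        assert exact == pytest.approx(0.985, abs=0.01)

    def test_distant_binding_term_zero(self):
        top = point_topology(2, radius=1.7)
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        dg, _ = surf_nonpolar_binding(
            coords, top, np.array([0]), np.array([1])
        )
        assert abs(dg) < 1e-9

    def test_burial_on_contact_negative(self):
        top = point_topology(2, radius=1.7)
        coords = np.array([[0.0, 0, 0], [0.35, 0, 0]])
        dg, _ = surf_nonpolar_binding(
            coords, top, np.array([0]), np.array([1])
        )
        assert dg < -1e-3


class TestMMGBSA:
    def test_component_identity_and_closure(self, demo):
        top, traj, _ = demo
        rec = ml.resolve_selection(SelectionSpec("entity", "protein", "p"), top)
        lig = ml.resolve_selection(SelectionSpec("entity", "ligand", "l"), top)
        comps, share = mmgbsa_frame(
            traj.coordinates[150], top, rec, lig, AnalysisConfig()
        )
        total = comps["elec"] + comps["vdw"] + comps["polar"] + comps["surf"]
        assert comps["total"] == pytest.approx(total, abs=1e-6)
        assert share.sum() == pytest.approx(comps["total"], abs=1e-3)

    def test_noninteracting_limit(self):
        """Ligand far away with zero net charge and no burial: all four
        binding components vanish."""
        spec = ml.SyntheticSpec(
            n_residues=4, ligand_rings=1, n_frames=3, fluct_sigma=0.0,
            ligand_offset_nm=(0.0, 120.0, 0.0),
            ligand_charges={"O1": -0.3, "CT1": 0.3},
        )
        top = ml.build_topology(spec)
        traj, _ = ml.generate_trajectory(top, spec)
        bd = ml.mmgbsa_trajectory(
            traj, top,
            SelectionSpec("entity", "protein", "p"),
            SelectionSpec("entity", "ligand", "l"),
        )
        assert abs(bd.means["total"]) < 1e-3

    def test_trajectory_mean_matches_frame_calls(self, demo):
        top, traj, _ = demo
        single = ml.Trajectory(traj.times[200:201], traj.coordinates[200:201])
        bd = ml.mmgbsa_trajectory(
            single, top,
            SelectionSpec("entity", "protein", "p"),
            SelectionSpec("entity", "ligand", "l"),
        )
        rec = ml.resolve_selection(SelectionSpec("entity", "protein", "p"), top)
        lig = ml.resolve_selection(SelectionSpec("entity", "ligand", "l"), top)
        comps, _ = mmgbsa_frame(
            traj.coordinates[200], top, rec, lig, AnalysisConfig()
        )
        for key in ("elec", "vdw", "polar", "surf", "total"):
            assert bd.means[key] == pytest.approx(comps[key], abs=1e-9)

    def test_per_residue_closure(self, demo):
        top, traj, _ = demo
        sub = ml.Trajectory(traj.times[150:160], traj.coordinates[150:160])
        bd = ml.mmgbsa_trajectory(
            sub, top,
            SelectionSpec("entity", "protein", "p"),
            SelectionSpec("entity", "ligand", "l"),
            frame_stride=2,
        )
        assert sum(bd.per_residue.values()) == pytest.approx(
            bd.means["total"], abs=1e-3
        )

    def test_overlapping_selections_rejected(self, demo):
        top, traj, _ = demo
        sel = SelectionSpec("entity", "protein", "p")
        with pytest.raises(SelectionError):
            ml.mmgbsa_trajectory(traj, top, sel, sel)

    def test_rigid_invariance_of_frame_energy(self, demo, rng):
        top, traj, _ = demo
        rec = ml.resolve_selection(SelectionSpec("entity", "protein", "p"), top)
        lig = ml.resolve_selection(SelectionSpec("entity", "ligand", "l"), top)
        cfg = AnalysisConfig(sasa_sphere_points=960)
        base, _ = mmgbsa_frame(traj.coordinates[150], top, rec, lig, cfg)
        rot = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True)
        moved = traj.coordinates[150] @ rot.as_matrix().T + rng.normal(size=3)
        after, _ = mmgbsa_frame(moved, top, rec, lig, cfg)
        for key in ("elec", "vdw", "polar"):
            assert after[key] == pytest.approx(base[key], abs=1e-6)
        # SASA uses a fixed sphere-point lattice, so the surface term is
        # rigid-invariant only up to quadrature resolution
        assert after["surf"] == pytest.approx(base["surf"], abs=0.05)


class TestRanking:
    def test_threshold_and_order(self):
        bd = ml.EnergyBreakdown(
            np.array([0]), np.array([0.0]),
            *(np.zeros(1) for _ in range(5)),
            per_residue={"ALA1": -2.5, "GLY2": -0.3, "SER3": -1.1, "LIG": -4.0},
            per_residue_index={"ALA1": 0, "GLY2": 1, "SER3": 2, "LIG": -1},
        )
        ranked = ml.rank_binding_residues(bd, -1.0)
        assert [r for r, _ in ranked] == ["ALA1", "SER3"]

    def test_strict_threshold_empty(self):
        bd = ml.EnergyBreakdown(
            np.array([0]), np.array([0.0]),
            *(np.zeros(1) for _ in range(5)),
            per_residue={"ALA1": -2.5, "SER3": -1.1},
            per_residue_index={"ALA1": 0, "SER3": 2},
        )
        assert ml.rank_binding_residues(bd, -10.0) == []

    def test_planted_binder_ranked_first(self, demo):
        top, traj, gt = demo
        eq = ml.discard_burn_in(traj, 100.0)
        bd = ml.mmgbsa_trajectory(
            eq, top,
            SelectionSpec("entity", "protein", "p"),
            SelectionSpec("entity", "ligand", "l"),
            frame_stride=16,
        )
        ranked = ml.rank_binding_residues(bd, -1.0)
        assert ranked
        top_label = ranked[0][0]
        expected = top.residues[gt.planted_binding_residue].label
        assert top_label == expected
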