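"""Nonbonded energies, GB solvation, SASA and the binding decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import allodyn
from allodyn.energetics import (
    KE_KCAL_A_MOL_E2,
    ForceFieldParameters,
    binding_total,
    coulomb_energy,
    gb_energy,
    gb_polar,
    lj_energy,
    nonpolar_solvation,
    sasa,
    sphere_points,
)
from allodyn.errors import AnalysisError


def make_params(n, charge=0.0, rmin2=1.9, eps=0.1, born=1.7, **globals_):
    return ForceFieldParameters(
        charge=np.full(n, float(charge)),
        lj_rmin_half=np.full(n, float(rmin2)),
        lj_eps=np.full(n, float(eps)),
        born_radius=np.full(n, float(born)),
        **globals_,
    )


class TestLennardJones:
    def test_minimum_is_minus_epsilon_at_rmin(self):
        p = make_params(2, rmin2=1.9, eps=0.25)
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0]])  # r = Rmin_ij = 1.9 + 1.9
        assert lj_energy(coords, [0], [1], p) == pytest.approx(-0.25, abs=1e-12)

    def test_vanishes_at_large_separation(self):
        p = make_params(2)
        coords = np.array([[0.0, 0, 0], [1e6, 0, 0]])
        assert abs(lj_energy(coords, [0], [1], p)) < 1e-12

    def test_matches_pairwise_hand_summation(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 6, (5, 3))
        p = ForceFieldParameters(
            charge=np.zeros(5),
            lj_rmin_half=rng.uniform(1.5, 2.1, 5),
            lj_eps=rng.uniform(0.05, 0.3, 5),
            born_radius=np.full(5, 1.7),
        )
        ia, ib = [0, 1, 2], [3, 4]
        expected = 0.0
        for i in ia:
            for j in ib:
                r = np.linalg.norm(coords[i] - coords[j])
                rmin = p.lj_rmin_half[i] + p.lj_rmin_half[j]
                eps = np.sqrt(p.lj_eps[i] * p.lj_eps[j])
                expected += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert lj_energy(coords, ia, ib, p) == pytest.approx(expected, abs=1e-10)

    def test_overlapping_atoms_named_in_error(self):
        p = make_params(2)
        coords = np.array([[0.0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(AnalysisError, match="overlap"):
            lj_energy(coords, [0], [1], p)


class TestCoulomb:
    def test_unit_charges_at_ke_angstrom_give_one(self):
        p = make_params(2, charge=1.0)
        coords = np.array([[0.0, 0, 0], [KE_KCAL_A_MOL_E2, 0, 0]])
        assert coulomb_energy(coords, [0], [1], p) == pytest.approx(1.0, abs=1e-12)

    def test_opposite_charges_direct_substitution(self):
        p = ForceFieldParameters(
            charge=np.array([1.0, -1.0]),
            lj_rmin_half=np.full(2, 1.9),
            lj_eps=np.full(2, 0.1),
            born_radius=np.full(2, 1.7),
        )
        coords = np.array([[0.0, 0, 0], [3.320637, 0, 0]])
        assert coulomb_energy(coords, [0], [1], p) == pytest.approx(-100.0, abs=1e-9)

    def test_neutral_group_gives_zero(self):
        p = make_params(3, charge=0.0)
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0]])
        assert coulomb_energy(coords, [0], [1, 2], p) == 0.0


class TestGeneralizedBorn:
    def test_zero_when_dielectrics_equal(self):
        p = make_params(4, charge=0.7, eps_interior=80.0, eps_solvent=80.0)
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 8, (4, 3))
        assert gb_polar(coords, [0, 1], [2, 3], p) == pytest.approx(0.0, abs=1e-12)
        assert gb_energy(coords, [0, 1, 2, 3], p) == pytest.approx(0.0, abs=1e-12)

    def test_born_self_energy_of_single_ion(self):
        """q = 1 e, a = 2 A: E = -k_e (1 - 1/80) q^2 / (2a)."""
        p = make_params(1, charge=1.0, born=2.0)
        expected = -KE_KCAL_A_MOL_E2 * (1 - 1 / 80) * 1.0 / (2 * 2.0)
        assert gb_energy(np.zeros((1, 3)), [0], p) == pytest.approx(expected, abs=1e-10)

    def test_large_separation_approaches_screened_coulomb(self):
        a = 2.0
        r = 100.0 * a
        p = make_params(2, charge=1.0, born=a)
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        screened = -KE_KCAL_A_MOL_E2 * (1 - 1 / 80) / r
        assert gb_polar(coords, [0], [1], p) == pytest.approx(screened, rel=0.01)


class TestSasa:
    def test_isolated_atom_equals_sphere_area(self):
        """r = 1.6 A, probe 1.4 A: SASA = 4 pi (3.0)^2 = 113.097 A^2."""
        out = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4, n_points=960)
        assert out[0] == pytest.approx(4 * np.pi * 3.0**2, rel=0.005)

    def test_coincident_identical_atoms_tie_rule(self):
        """Exactly coincident equal spheres do not occlude each other (strict
        inequality in the radius test); verified against the per-point oracle."""
        coords = np.zeros((2, 3))
        radii = np.array([1.6, 1.6])
        out = sasa(coords, radii, probe=1.4, n_points=240)
        pts = sphere_points(240) * 3.0  # points of atom 0 lie ON the twin sphere
        d2 = (pts**2).sum(axis=1)
        exposed = ~(d2 < 3.0**2 - 1e-6)  # oracle: strictly-inside radius test
        assert exposed.all()
        np.testing.assert_allclose(out, 4 * np.pi * 3.0**2 * exposed.mean(), atol=1e-9)

    def test_caged_atom_is_fully_buried(self):
        """An atom surrounded by 12 tight icosahedral neighbours has zero SASA,
        as confirmed by the same point-in-sphere oracle."""
        phi = (1 + np.sqrt(5)) / 2
        ico = np.array(
            [[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
             [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
             [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]], float
        )
        ico = ico / np.linalg.norm(ico[0]) * 2.0  # cage at 2.0 A
        coords = np.vstack([[0.0, 0.0, 0.0], ico])
        radii = np.full(13, 1.6)
        out = sasa(coords, radii, probe=1.4, n_points=240)
        pts = sphere_points(240) * 3.0
        buried = np.zeros(240, bool)
        for c in ico:
            buried |= np.linalg.norm(pts - c, axis=1) < 3.0
        assert buried.all()
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            sasa(np.zeros((1, 3)), np.array([1.6]), n_points=6)

    def test_agrees_with_independent_library_implementation(self):
        """Cross-check against biotite's Shrake-Rupley on a small cluster."""
        import biotite.structure as struc

        coords = np.array([[0, 0, 0], [2.5, 0, 0], [0, 2.5, 0], [5, 5, 5]], float)
        radii = np.full(4, 1.6)
        arr = struc.AtomArray(4)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 4)
        arr.res_id = np.arange(1, 5)
        arr.res_name = np.array(["ALA"] * 4)
        arr.atom_name = np.array(["CA"] * 4)
        arr.chain_id = np.array(["A"] * 4)
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=960)
        ours = sasa(coords, radii, probe=1.4, n_points=960)
        np.testing.assert_allclose(ours, ref, rtol=0.01)


class TestNonpolarSolvation:
    def test_zero_sasa_species_contributes_offset(self):
        # complex SASA == A SASA, B SASA 0: only B's offset survives with sign -b
        assert nonpolar_solvation(100.0, 100.0, 0.0) == pytest.approx(-0.92)

    def test_printed_formula_substitution(self):
        """gamma*100 + b = 0.00542*100 + 0.92 = 1.462 kcal/mol per species."""
        val = nonpolar_solvation(100.0, 0.0, 0.0)
        assert val + 0.92 * 2 == pytest.approx(0.00542 * 100 + 0.92, abs=1e-12)

    def test_zero_parameters_give_zero(self):
        assert nonpolar_solvation(123.0, 45.0, 6.0, gamma=0.0, b=0.0) == 0.0


@pytest.fixture(scope="module")
def decomposition(path_fixture):
    fitted, truth, params, reference = path_fixture
    ff = ForceFieldParameters.from_table(params, fitted.topology)
    sub = allodyn.Ensemble(fitted.frames[:40], fitted.topology)
    return allodyn.binding_decomposition(sub, "chain A", "chain P", ff, stride=8,
                                         n_sphere_points=120)


class TestBindingDecomposition:
    def test_summation_identities_hold_exactly(self, decomposition):
        df = decomposition.frames
        np.testing.assert_allclose(df["solv"], df["polar"] + df["nonpolar"], atol=1e-10)
        np.testing.assert_allclose(df["mm"], df["vdw"] + df["ele"] + df["internal"], atol=1e-10)
        np.testing.assert_allclose(df["binding"], df["mm"] + df["solv"], atol=1e-10)
        assert (df["internal"] == 0.0).all()

    def test_per_residue_rows_sum_to_totals(self, decomposition):
        per = decomposition.per_residue
        mean = decomposition.mean
        for term in ("vdw", "ele", "polar", "nonpolar"):
            assert per[f"{term}_mean"].sum() == pytest.approx(mean[term], abs=1e-6)
        assert per["binding_mean"].sum() == pytest.approx(mean["binding"], abs=1e-6)

    def test_charged_contact_residue_dominates_electrostatics(self, path_fixture):
        """With the D590/R+2 salt bridge as the only charged pair, D590 carries
        essentially the whole receptor-side electrostatic share."""
        fitted, truth, params, reference = path_fixture
        charged = params.copy()
        od1 = fitted.topology.atom_index("A", 590, "OD1")
        ne = fitted.topology.atom_index("P", 2, "NE")
        keep = {fitted.topology.atoms[od1].serial, fitted.topology.atoms[ne].serial}
        charged.loc[~charged["serial"].isin(keep), "charge_e"] = 0.0
        ff = ForceFieldParameters.from_table(charged, fitted.topology)
        sub = allodyn.Ensemble(fitted.frames[:16], fitted.topology)
        dec = allodyn.binding_decomposition(sub, "chain A", "chain P", ff, stride=4,
                                            n_sphere_points=120)
        per = dec.per_residue
        share = per[per.index.str.startswith("A:")]["ele_mean"].abs()
        assert share["A:590"] / share.sum() > 0.9

    def test_swapping_partners_preserves_binding_energy(self, path_fixture):
        fitted, truth, params, reference = path_fixture
        ff = ForceFieldParameters.from_table(params, fitted.topology)
        sub = allodyn.Ensemble(fitted.frames[:8], fitted.topology)
        a = allodyn.binding_decomposition(sub, "chain A", "chain P", ff, stride=4, n_sphere_points=120)
        b = allodyn.binding_decomposition(sub, "chain P", "chain A", ff, stride=4, n_sphere_points=120)
        np.testing.assert_allclose(a.frames["binding"], b.frames["binding"], atol=1e-9)

    def test_cross_energies_rigid_invariant(self, toy_structure, toy_params):
        ff = ForceFieldParameters.from_table(toy_params, toy_structure)
        coords = toy_structure.coordinates
        ia = allodyn.resolve_selection(toy_structure, "chain A")
        ib = allodyn.resolve_selection(toy_structure, "chain P")
        R = Rotation.random(random_state=2).as_matrix()
        moved = coords @ R.T + np.array([7.0, -3.0, 11.0])
        for fn in (lj_energy, coulomb_energy, gb_polar):
            assert fn(coords, ia, ib, ff) == pytest.approx(fn(moved, ia, ib, ff), abs=1e-9)

    def test_overlapping_selections_rejected(self, path_fixture):
        fitted, _, params, _ = path_fixture
        ff = ForceFieldParameters.from_table(params, fitted.topology)
        with pytest.raises(AnalysisError):
            allodyn.binding_decomposition(fitted, "chain A", "chain A", ff)


class TestAggregation:
    def test_component_sum_path(self):
        """Summing component terms through the aggregation path reproduces the
        total binding energy with the internal term held at zero."""
        assert binding_total(-2.21, -88.93, -0.62, 88.90) == pytest.approx(-2.86, abs=5e-3)
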