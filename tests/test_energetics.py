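import numpy as np
import pandas as pd
import pytest

from conftest import bead, static_trajectory
from ppidyn.energetics import (
    COULOMB_KCAL,
    ForceFieldParameters,
    binding_energy,
    effective_born_radii,
    gb_polar,
    mm_terms,
    nonpolar_term,
    per_residue_decomposition,
)
from ppidyn.structio import StructureModel, TrajectoryEnsemble


def params(charges, radii=None, eps=None, rmin_half=None, **kw):
    n = len(charges)
    return ForceFieldParameters(
        np.asarray(charges, float),
        np.asarray(radii if radii is not None else [2.0] * n, float),
        np.asarray(eps if eps is not None else [0.1] * n, float),
        np.asarray(rmin_half if rmin_half is not None else [2.0] * n, float),
        **kw,
    )


class TestMmTerms:
    def test_coulomb_closed_form(self):
        xyz = np.array([[0, 0, 0], [3.32, 0, 0]], float)
        p = params([1.0, -1.0], eps=[0.0, 0.0])
        _, e_ele = mm_terms(xyz, p, [0], [1])
        assert e_ele == pytest.approx(-COULOMB_KCAL / 3.32, abs=1e-9)
        assert e_ele == pytest.approx(-100.02, abs=1e-2)

    def test_lj_minimum_is_minus_epsilon(self):
        # at r = r_min the well depth is exactly −ε
        xyz = np.array([[0, 0, 0], [4.0, 0, 0]], float)
        p = params([0.0, 0.0], eps=[0.25, 0.25], rmin_half=[2.0, 2.0])
        e_vdw, e_ele = mm_terms(xyz, p, [0], [1])
        assert e_vdw == pytest.approx(-0.25, abs=1e-12)
        assert e_ele == 0.0

    def test_distant_groups_negligible(self):
        xyz = np.array([[0, 0, 0], [1e4, 0, 0]], float)
        p = params([1.0, 1.0])
        e_vdw, e_ele = mm_terms(xyz, p, [0], [1])
        assert abs(e_vdw) <= 1e-6
        assert abs(e_ele) <= COULOMB_KCAL / 1e4 + 1e-9

    def test_solute_dielectric_scales_coulomb(self):
        xyz = np.array([[0, 0, 0], [3.0, 0, 0]], float)
        p1 = params([1.0, -1.0], eps=[0, 0])
        p2 = params([1.0, -1.0], eps=[0, 0], solute_dielectric=2.0)
        assert mm_terms(xyz, p2, [0], [1])[1] == pytest.approx(
            mm_terms(xyz, p1, [0], [1])[1] / 2.0
        )

    def test_overlapping_groups_error(self):
        xyz = np.zeros((2, 3))
        with pytest.raises(ValueError):
            mm_terms(xyz, params([0.0, 0.0]), [0, 1], [1])


class TestGbPolar:
    def test_born_ion_exact(self):
        xyz = np.zeros((1, 3))
        p = params([1.0], radii=[2.0])
        expect = -(COULOMB_KCAL / 2.0) * (1 - 1 / 80.0) * (1 / 2.0)
        assert gb_polar(xyz, p) == pytest.approx(expect, abs=1e-9)
        assert gb_polar(xyz, p) == pytest.approx(-81.98, abs=1e-2)

    def test_isolated_atom_effective_radius_is_intrinsic(self):
        r = effective_born_radii(np.zeros((1, 3)), np.array([1.7]))
        assert r[0] == pytest.approx(1.7, abs=1e-12)

    def test_neutral_system_zero(self):
        xyz = np.random.default_rng(0).normal(size=(5, 3))
        p = params([0.0] * 5)
        assert gb_polar(xyz, p) == 0.0

    def test_distant_ions_approach_additivity(self):
        # the Still cross term decays as (1−1/ε)k/r; at 10⁴ Å it is < 0.05
        d = 1e4
        xyz = np.array([[0, 0, 0], [d, 0, 0]], float)
        p = params([1.0, 1.0], radii=[2.0, 3.0])
        singles = (
            gb_polar(np.zeros((1, 3)), params([1.0], radii=[2.0]))
            + gb_polar(np.zeros((1, 3)), params([1.0], radii=[3.0]))
        )
        assert gb_polar(xyz, p) == pytest.approx(singles, abs=0.05)

    def test_rigid_transform_invariance(self, rng):
        xyz = rng.normal(0, 3, size=(6, 3))
        q = rng.normal(size=6)
        p = params(q, radii=rng.uniform(1.2, 2.2, 6))
        theta = 1.1
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = (R @ xyz.T).T + np.array([10.0, -4.0, 2.0])
        assert gb_polar(moved, p) == pytest.approx(gb_polar(xyz, p), abs=1e-9)

    def test_burial_grows_effective_radius(self):
        xyz = np.array([[0, 0, 0], [3.0, 0, 0]], float)
        r = effective_born_radii(xyz, np.array([1.7, 1.7]))
        assert np.all(r > 1.7)


class TestNonpolar:
    def test_zero_sasa_gives_offset(self):
        p = params([0.0])
        assert nonpolar_term(0.0, p) == pytest.approx(0.92, abs=1e-12)

    def test_linear_evaluation(self):
        p = params([0.0])
        assert nonpolar_term(1000.0, p) == pytest.approx(6.34, abs=1e-9)

    def test_zero_coefficients(self):
        p = params([0.0], gamma=0.0, b_offset=0.0)
        assert nonpolar_term(12345.0, p) == 0.0

    def test_negative_sasa_errors(self):
        with pytest.raises(ValueError):
            nonpolar_term(-1.0, params([0.0]))


def _charged_pair_complex():
    atoms = [
        bead("CA", 1, "A", [0, 0, 0], element="C"),
        bead("OD1", 1, "A", [0, 2, 0], element="O", resname="ASP"),
        bead("CA", 1, "B", [0, 7, 0], element="C"),
        bead("NZ", 1, "B", [0, 5, 0], element="N", resname="LYS"),
    ]
    model = StructureModel(atoms)
    p = params([0.0, -1.0, 0.0, 1.0], radii=[1.7, 1.5, 1.7, 1.55],
               eps=[0.1, 0.0, 0.1, 0.0], rmin_half=[2.0, 1.5, 2.0, 1.5])
    return model, p


class TestBindingEnergy:
    def test_internal_term_is_exactly_zero(self):
        model, p = _charged_pair_complex()
        traj = static_trajectory(model, 3)
        bd = binding_energy(traj, p, ["A"], ["B"])
        assert bd.e_int == (0.0, 0.0)

    def test_accounting_identities(self):
        model, p = _charged_pair_complex()
        traj = static_trajectory(model, 2)
        bd = binding_energy(traj, p, ["A"], ["B"])
        assert bd.e_mm[0] == pytest.approx(bd.e_vdw[0] + bd.e_ele[0] + bd.e_int[0], abs=1e-9)
        assert bd.g_sol[0] == pytest.approx(bd.e_polar[0] + bd.e_nonpolar[0], abs=1e-9)
        assert bd.g_binding[0] == pytest.approx(bd.e_mm[0] + bd.g_sol[0], abs=1e-9)

    def test_uncharged_noncontacting_pair_reduces_to_nonpolar(self):
        # far-apart neutral chains: ΔG must equal γ·ΔSASA − b exactly
        # (two b offsets subtract one), with ΔSASA = 0 here
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("CA", 1, "B", [0, 100, 0], element="C"),
        ]
        model = StructureModel(atoms)
        p = params([0.0, 0.0], eps=[0.0, 0.0])
        traj = static_trajectory(model, 2)
        bd = binding_energy(traj, p, ["A"], ["B"])
        assert bd.g_binding[0] == pytest.approx(-0.92, abs=1e-6)

    def test_opposite_charges_sign_pattern(self):
        model, p = _charged_pair_complex()
        traj = static_trajectory(model, 2)
        bd = binding_energy(traj, p, ["A"], ["B"])
        assert bd.e_ele[0] < 0  # Coulomb attraction
        assert bd.e_polar[0] > 0  # desolvation penalty opposes binding

    def test_overlapping_groups_error(self):
        model, p = _charged_pair_complex()
        traj = static_trajectory(model, 1)
        with pytest.raises(ValueError):
            binding_energy(traj, p, ["A", "B"], ["B"])


class TestPerResidueDecomposition:
    def test_only_interacting_rows_nonzero(self):
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("CA", 2, "A", [100, 0, 0], element="C"),
            bead("CA", 1, "B", [0, 6, 0], element="C"),
            bead("CA", 2, "B", [100, 200, 0], element="C"),
        ]
        model = StructureModel(atoms)
        p = params([1.0, 0.0, -1.0, 0.0], eps=[0.0] * 4)
        traj = static_trajectory(model, 1)
        df = per_residue_decomposition(traj, p, ["A"], ["B"], points=240)
        ele = df.set_index(["chain", "resnum"])["ele"]
        assert abs(ele[("A", 1)]) > 1.0
        assert abs(ele[("B", 1)]) > 1.0
        assert ele[("A", 2)] == pytest.approx(0.0, abs=1e-6)

    def test_rows_sum_to_total(self, rng):
        model, p = _charged_pair_complex()
        frames = model.coordinates[None] + rng.normal(0, 0.1, size=(3, 4, 3))
        traj = TrajectoryEnsemble(model, frames)
        bd = binding_energy(traj, p, ["A"], ["B"], points=480)
        df = per_residue_decomposition(traj, p, ["A"], ["B"], points=480)
        assert df["total"].sum() == pytest.approx(bd.g_binding[0], abs=0.05)

    def test_planted_salt_pair_dominates(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            atoms = [
                bead("CA", i + 1, "A", [4.0 * i, 0, 0], element="C") for i in range(4)
            ] + [
                bead("OD1", 2, "A", [4.0, 2.5, 0], element="O", resname="ASP"),
            ] + [
                bead("CA", i + 1, "B", [4.0 * i, 8, 0], element="C") for i in range(4)
            ] + [
                bead("NZ", 2, "B", [4.0, 5.5, 0], element="N", resname="LYS"),
            ]
            model = StructureModel(atoms)
            charges = [0, 0, 0, 0, -1.0, 0, 0, 0, 0, 1.0]
            p = params(charges, radii=[1.7] * 4 + [1.5] + [1.7] * 4 + [1.55],
                       eps=[0.1] * 4 + [0.0] + [0.1] * 4 + [0.0],
                       rmin_half=[2.0] * 4 + [1.5] + [2.0] * 4 + [1.5])
            frames = model.coordinates[None] + rng.normal(0, 0.05, size=(4, 10, 3))
            traj = TrajectoryEnsemble(model, frames)
            df = per_residue_decomposition(traj, p, ["A"], ["B"], points=240)
            ranked = df.sort_values("total")
            top2 = {(r.chain, r.resnum) for r in ranked.head(2).itertuples()}
            assert top2 == {("A", 2), ("B", 2)}
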