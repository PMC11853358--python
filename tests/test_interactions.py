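import numpy as np
import pytest

from conftest import bead, static_trajectory
from oracles import two_sphere_buried_area
from ppidyn.interactions import (
    classify_interface,
    contact_occupancy,
    hydrogen_bonds,
    interface_area,
    salt_bridges,
    sasa,
)
from ppidyn.structio import StructureModel, TrajectoryEnsemble


def _single_atom(radius_element="S"):
    return StructureModel([bead("S", 1, "A", [0, 0, 0], element="S")])


class TestSasa:
    def test_isolated_sphere_analytic(self):
        m = StructureModel([bead("CA", 1, "A", [0, 0, 0], element="C")])  # r = 1.7
        res = sasa(m, probe=1.4, points=960)
        expect = 4 * np.pi * (1.7 + 1.4) ** 2
        assert res.total == pytest.approx(expect, rel=0.01)

    def test_quadrature_is_exact_for_free_sphere(self):
        # no occlusion: every quadrature point is exposed, so the area is
        # exactly 4π(r+p)² regardless of point count
        m = StructureModel([bead("CA", 1, "A", [0, 0, 0], element="C")])
        assert sasa(m, points=60).total == pytest.approx(4 * np.pi * 3.1**2, rel=1e-12)

    def test_engulfed_atom_zero(self):
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("BIG", 2, "A", [0, 0, 0.1], element="C", intrinsic_radius=20.0),
        ]
        m = StructureModel(atoms)
        res = sasa(m)
        assert res.per_atom[0] == 0.0

    def test_zero_probe_limit(self):
        m = StructureModel([bead("N", 1, "A", [0, 0, 0], element="N")])  # r = 1.55
        res = sasa(m, probe=0.0)
        assert res.total == pytest.approx(4 * np.pi * 1.55**2, rel=0.01)

    def test_doubling_points_converged(self):
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("CA", 2, "A", [2.5, 0, 0], element="C"),
            bead("CA", 3, "A", [1.2, 2.0, 0], element="C"),
        ]
        m = StructureModel(atoms)
        a = sasa(m, points=960).total
        b = sasa(m, points=1920).total
        assert abs(a - b) / b < 0.005

    def test_missing_radius_names_atom(self):
        m = StructureModel([bead("XX", 7, "A", [0, 0, 0], element="XX")])
        with pytest.raises(ValueError, match="A:7:XX"):
            sasa(m)


class TestInterfaceArea:
    def test_far_apart_chains_zero(self, toy_complex):
        traj = static_trajectory(toy_complex, 2)
        series = interface_area(traj, ["A"], ["B"], points=240)
        assert np.allclose(series.areas, 0.0, atol=1e-6)

    def test_symmetric_in_groups(self):
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("CA", 1, "B", [4.0, 0, 0], element="C"),
        ]
        m = StructureModel(atoms)
        traj = static_trajectory(m, 3)
        s1 = interface_area(traj, ["A"], ["B"], points=480)
        s2 = interface_area(traj, ["B"], ["A"], points=480)
        assert np.allclose(s1.areas, s2.areas, atol=1e-9)

    def test_two_sphere_cap_closed_form(self):
        # two single-atom chains in contact: the buried area equals half the
        # sum of the spherical caps cut by the intersection plane
        d = 4.0
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("CA", 1, "B", [d, 0, 0], element="C"),
        ]
        m = StructureModel(atoms)
        traj = static_trajectory(m, 1)
        series = interface_area(traj, ["A"], ["B"], points=4000)
        R = 1.7 + 1.4
        cap1, cap2 = two_sphere_buried_area(R, R, d)
        expect = 0.5 * (cap1 + cap2)
        assert series.areas[0] == pytest.approx(expect, rel=0.02)

    def test_monotone_under_separation(self):
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("CA", 2, "A", [3.0, 0, 0], element="C"),
            bead("CA", 1, "B", [0, 4.5, 0], element="C"),
            bead("CA", 2, "B", [3.0, 4.5, 0], element="C"),
        ]
        m = StructureModel(atoms)
        base = m.coordinates
        frames = []
        for pull in np.linspace(0, 6, 7):
            x = base.copy()
            x[2:, 1] += pull
            frames.append(x)
        traj = TrajectoryEnsemble(m, np.asarray(frames))
        series = interface_area(traj, ["A"], ["B"], points=960)
        assert np.all(np.diff(series.areas) <= 1e-9)

    def test_overlapping_groups_error(self, toy_complex):
        traj = static_trajectory(toy_complex, 1)
        with pytest.raises(ValueError):
            interface_area(traj, ["A"], ["A"])

    def test_histogram_probabilities_sum_to_one(self, toy_complex, rng):
        frames = toy_complex.coordinates[None] + rng.normal(0, 0.1, size=(6, 8, 3))
        traj = TrajectoryEnsemble(toy_complex, frames)
        series = interface_area(traj, ["A"], ["B"], points=120)
        _, probs = series.histogram(bins=5)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)


def _pair_model():
    atoms = [
        bead("CA", 1, "A", [0, 0, 0], element="C"),
        bead("CA", 1, "B", [0, 10, 0], element="C"),
    ]
    return StructureModel(atoms)


def _schedule_traj(model, on_frames, n_frames, d_on=3.0, d_off=9.0, atom=1):
    base = model.coordinates
    frames = []
    for f in range(n_frames):
        x = base.copy()
        x[atom, 1] = d_on if f in on_frames else d_off
        frames.append(x)
    return TrajectoryEnsemble(model, np.asarray(frames))


class TestContactOccupancy:
    def test_seven_of_ten_is_stable_at_boundary(self):
        m = _pair_model()
        traj = _schedule_traj(m, set(range(7)), 10, d_on=4.0)
        recs = contact_occupancy(traj, group_a=["A"], group_b=["B"], cutoff=4.5)
        assert len(recs) == 1
        assert recs[0].occupancy == pytest.approx(0.70)
        # the ≥ threshold is inclusive: exactly 70% counts as stable
        assert recs[0].stable

    def test_never_in_contact_zero(self):
        m = _pair_model()
        traj = _schedule_traj(m, set(), 10)
        recs = contact_occupancy(
            traj, pairs=[(("A", 1), ("B", 1))], cutoff=4.5
        )
        assert recs[0].count == 0

    def test_planted_schedule_exact(self):
        m = _pair_model()
        on = set(np.random.default_rng(5).permutation(500)[:375])
        traj = _schedule_traj(m, on, 500, d_on=4.0)
        recs = contact_occupancy(traj, group_a=["A"], group_b=["B"])
        assert recs[0].count == 375
        assert recs[0].occupancy == 0.75

    def test_occupancy_times_frames_integer(self, rng):
        m = _pair_model()
        on = set(rng.permutation(200)[:77])
        traj = _schedule_traj(m, on, 200, d_on=4.0)
        recs = contact_occupancy(traj, group_a=["A"], group_b=["B"])
        for r in recs:
            assert r.occupancy * r.n_frames == pytest.approx(round(r.occupancy * r.n_frames), abs=1e-9)

    def test_ca_mode_excludes_sidechain_contacts(self):
        atoms = [
            bead("CA", 1, "A", [0, 0, 0], element="C"),
            bead("CB", 1, "A", [0, 2, 0], element="C"),
            bead("CA", 1, "B", [0, 6, 0], element="C"),
            bead("CB", 1, "B", [0, 4, 0], element="C"),
        ]
        m = StructureModel(atoms)
        traj = static_trajectory(m, 2)
        heavy = contact_occupancy(traj, group_a=["A"], group_b=["B"], cutoff=4.5)
        ca_only = contact_occupancy(traj, group_a=["A"], group_b=["B"], cutoff=4.5, mode="ca")
        assert heavy and heavy[0].occupancy == 1.0
        assert not ca_only or all(r.count == 0 for r in ca_only)


def _hbond_model():
    atoms = [
        bead("CA", 1, "A", [0, 0, 0], element="C", resname="PHE"),
        bead("N", 1, "A", [1.5, 0, 0], element="N", resname="PHE"),
        bead("CA", 5, "B", [1.5, 8, 0], element="C", resname="TYR"),
        bead("OH", 5, "B", [1.5, 5, 0], element="O", resname="TYR"),
    ]
    return StructureModel(atoms)


class TestHydrogenBonds:
    def test_ideal_pair_full_occupancy(self):
        m = _hbond_model()
        base = m.coordinates.copy()
        base[3] = [1.5, 2.9, 0]  # N–OH at 2.9 Å
        traj = TrajectoryEnsemble(m, np.repeat(base[None], 4, axis=0))
        recs = hydrogen_bonds(traj)
        assert len(recs) == 1
        assert recs[0].occupancy == 1.0

    def test_beyond_cutoff_absent(self):
        m = _hbond_model()
        base = m.coordinates.copy()
        base[3] = [1.5, 5.0, 0]
        traj = TrajectoryEnsemble(m, np.repeat(base[None], 4, axis=0))
        assert hydrogen_bonds(traj) == []

    def test_planted_632_of_500_exact(self):
        m = _hbond_model()
        rng = np.random.default_rng(11)
        on = set(rng.permutation(500)[:316])
        frames = []
        for f in range(500):
            x = m.coordinates.copy()
            x[3] = [1.5, 2.9 if f in on else 8.0, 0]
            frames.append(x)
        traj = TrajectoryEnsemble(m, np.asarray(frames))
        recs = hydrogen_bonds(traj)
        assert len(recs) == 1
        assert recs[0].count == 316
        assert recs[0].occupancy == pytest.approx(0.632)

    def test_angle_criterion_with_hydrogens(self):
        # linear D–H···A passes; a 90° geometry fails the 135° criterion
        def build(angle_deg):
            theta = np.deg2rad(angle_deg)
            atoms = [
                bead("N", 1, "A", [0, 0, 0], element="N", resname="PHE"),
                bead("H", 1, "A", [1.0, 0, 0], element="H", resname="PHE"),
                bead(
                    "OH", 5, "B",
                    [1.0 - 1.9 * np.cos(theta), 1.9 * np.sin(theta), 0],
                    element="O", resname="TYR",
                ),
            ]
            m = StructureModel(atoms)
            return TrajectoryEnsemble(m, m.coordinates[None])

        assert len(hydrogen_bonds(build(180.0))) == 1
        assert hydrogen_bonds(build(90.0)) == []


def _saltbridge_model():
    atoms = [
        bead("CA", 1, "A", [0, 0, 0], element="C", resname="ASP"),
        bead("OD1", 1, "A", [1.5, 0, 0], element="O", resname="ASP"),
        bead("CA", 9, "B", [1.5, 8, 0], element="C", resname="LYS"),
        bead("NZ", 9, "B", [1.5, 3, 0], element="N", resname="LYS"),
    ]
    return StructureModel(atoms)


class TestSaltBridges:
    def test_close_pair_full_occupancy(self):
        m = _saltbridge_model()
        traj = static_trajectory(m, 5)  # OD1–NZ at 3.0 Å
        recs = salt_bridges(traj)
        assert len(recs) == 1
        assert recs[0].occupancy == 1.0
        assert recs[0].stable

    def test_distant_pair_absent(self):
        m = _saltbridge_model()
        base = m.coordinates.copy()
        base[3] = [1.5, 8.0, 0]
        traj = TrajectoryEnsemble(m, np.repeat(base[None], 3, axis=0))
        assert salt_bridges(traj) == []

    def test_planted_778_of_500_exact(self):
        m = _saltbridge_model()
        rng = np.random.default_rng(3)
        on = set(rng.permutation(500)[:389])
        frames = []
        for f in range(500):
            x = m.coordinates.copy()
            x[3] = [1.5, 3.0 if f in on else 9.0, 0]
            frames.append(x)
        traj = TrajectoryEnsemble(m, np.asarray(frames))
        recs = salt_bridges(traj)
        assert recs[0].count == 389
        assert recs[0].occupancy == pytest.approx(0.778)


class TestClassifyInterface:
    def test_one_planted_pair_per_type(self):
        atoms = [
            # salt bridge: ASP A1 – LYS B1
            bead("CA", 1, "A", [0, 0, 0], element="C", resname="ASP"),
            bead("OD1", 1, "A", [0, 2, 0], element="O", resname="ASP"),
            bead("CA", 1, "B", [0, 8, 0], element="C", resname="LYS"),
            bead("NZ", 1, "B", [0, 5.5, 0], element="N", resname="LYS"),
            # hydrogen bond: PHE A2 (backbone N) – TYR B2 (OH)
            bead("CA", 2, "A", [20, 0, 0], element="C", resname="PHE"),
            bead("N", 2, "A", [20, 2, 0], element="N", resname="PHE"),
            bead("CA", 2, "B", [20, 8, 0], element="C", resname="TYR"),
            bead("OH", 2, "B", [20, 4.9, 0], element="O", resname="TYR"),
            # hydrophobic: LEU A3 – ILE B3
            bead("CA", 3, "A", [40, 0, 0], element="C", resname="LEU"),
            bead("CD1", 3, "A", [40, 2, 0], element="C", resname="LEU"),
            bead("CA", 3, "B", [40, 8, 0], element="C", resname="ILE"),
            bead("CD1", 3, "B", [40, 6, 0], element="C", resname="ILE"),
        ]
        m = StructureModel(atoms)
        traj = static_trajectory(m, 4)
        recs = classify_interface(traj, ["A"], ["B"])
        by_type = {}
        for r in recs:
            by_type.setdefault(r.interaction_type, []).append(r)
        assert set(by_type) == {"saltbridge", "hbond", "hydrophobic"}
        assert len(by_type["saltbridge"]) == 1
        assert by_type["saltbridge"][0].resnum_a in (1,)
        assert len(by_type["hydrophobic"]) == 1
        assert all(r.occupancy == 1.0 for r in recs)

    def test_far_pair_absent(self):
        atoms = [
            bead("CA", 3, "A", [0, 0, 0], element="C", resname="LEU"),
            bead("CD1", 3, "A", [0, 2, 0], element="C", resname="LEU"),
            bead("CA", 3, "B", [0, 12, 0], element="C", resname="ILE"),
            bead("CD1", 3, "B", [0, 9, 0], element="C", resname="ILE"),
        ]
        m = StructureModel(atoms)
        traj = static_trajectory(m, 2)
        assert classify_interface(traj, ["A"], ["B"]) == []
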