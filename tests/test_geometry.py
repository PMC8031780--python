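"""Geometric descriptors: axes, distances, angles, circle fits, pore ring."""

import math

import numpy as np
import pytest

from secgeom.config import default_config
from secgeom.geometry import (
    CircleFitError,
    DegenerateGeometryError,
    HelixSpec,
    MembraneFrame,
    angle_between,
    angle_to_in_plane_x,
    angle_to_normal,
    circle_fit,
    descriptor_suite,
    helix_axis,
    helix_endpoint,
    pore_ring_radius,
    region_pair_distance,
    theta_ctm4_ntm1,
)
from secgeom.io import AtomRecord, RegionSpec, StructureModel
from secgeom.synthetic import BundleBlueprint, HelixBlueprint, make_bundle, make_ideal_helix

from conftest import channel_blueprint, random_rotation


class TestHelixAxis:
    def test_endpoint_matches_brute_force_com(self):
        helix = make_ideal_helix(12, chain_id="A", first_residue=1)
        cas = [a for a in helix.atoms if a.name == "CA"]
        expected = np.mean([a.position for a in cas[:4]], axis=0)
        got = helix_endpoint(helix, HelixSpec("h", "A", 1, 12), "N")
        assert np.linalg.norm(got - expected) < 0.5  # mass vs geometric: tiny for all-Cα
        np.testing.assert_allclose(
            helix_endpoint(helix, HelixSpec("h", "A", 1, 12), "N", "geometric"),
            expected,
            atol=1e-12,
        )

    def test_eight_residues_use_disjoint_windows(self):
        helix = make_ideal_helix(8, chain_id="A", first_residue=1)
        n = helix_endpoint(helix, HelixSpec("h", "A", 1, 8), "N")
        c = helix_endpoint(helix, HelixSpec("h", "A", 1, 8), "C")
        assert np.linalg.norm(n - c) > 3.0

    @pytest.mark.parametrize("n_residues", [11, 15, 22])
    def test_built_axis_recovered(self, n_residues):
        helix = make_ideal_helix(n_residues, axis=(0, 0, 1), chain_id="A", first_residue=1)
        ax = helix_axis(helix, HelixSpec("h", "A", 1, n_residues))
        assert math.acos(min(1.0, ax @ np.array([0, 0, 1.0]))) < 0.02

    def test_rotation_equivariance(self, rng):
        r = random_rotation(rng)
        helix = make_ideal_helix(15, chain_id="A", first_residue=1)
        spec = HelixSpec("h", "A", 1, 15)
        ax = helix_axis(helix, spec)
        ax_rot = helix_axis(helix.transformed(r, np.zeros(3)), spec)
        np.testing.assert_allclose(ax_rot, r @ ax, atol=1e-9)

    def test_reversed_numbering_flips_sign(self):
        helix = make_ideal_helix(15, chain_id="A", first_residue=1)
        reversed_atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                       16 - a.residue_number, a.insertion_code, a.position)
            for a in helix.atoms
        ]
        flipped = StructureModel(1, reversed_atoms)
        spec = HelixSpec("h", "A", 1, 15)
        np.testing.assert_allclose(
            helix_axis(flipped, spec), -helix_axis(helix, spec), atol=1e-9
        )

    def test_degenerate_axis_raises(self):
        atoms = []
        for i in range(8):
            atoms.append(AtomRecord(i + 1, "CA", "C", "ALA", "A", i + 1, "",
                                    np.array([float(i % 4), 0.0, 0.0])))
        with pytest.raises(DegenerateGeometryError):
            helix_axis(StructureModel(1, atoms), HelixSpec("h", "A", 1, 8))


class TestDistances:
    def test_matches_enumeration_oracle(self, channel_bundle):
        model, truth = channel_bundle
        a = RegionSpec("nTM2", "A", 83, 86)
        b = RegionSpec("nTM10", "A", 447, 450)
        cas = {n: [x.position for x in model.atoms
                   if x.name == "CA" and n[0] <= x.residue_number <= n[1]]
               for n in [(83, 86), (447, 450)]}
        oracle = 0.1 * np.linalg.norm(
            np.mean(cas[(83, 86)], axis=0) - np.mean(cas[(447, 450)], axis=0)
        )
        assert abs(region_pair_distance(model, a, b, "geometric") - oracle) < 1e-9
        assert abs(region_pair_distance(model, a, b) - truth["d_TM2_TM10"]) < 1e-9

    def test_parallel_helices_at_prescribed_separation(self):
        bp = BundleBlueprint(helices=(
            HelixBlueprint("TM2", "A", 83, 22, (0, 0, 1), (0, 0, 0)),
            HelixBlueprint("TM10", "A", 447, 22, (0, 0, 1), (19.6, 0, 0)),
        ))
        model, _ = make_bundle(bp)
        d = region_pair_distance(
            model, RegionSpec("a", "A", 83, 86), RegionSpec("b", "A", 447, 450)
        )
        assert abs(d - 1.96) < 1e-6

    def test_metric_properties(self, channel_bundle, rng):
        model, _ = channel_bundle
        specs = [
            RegionSpec("a", "A", 83, 86),
            RegionSpec("b", "A", 181, 184),
            RegionSpec("c", "A", 292, 295),
        ]
        d = lambda x, y: region_pair_distance(model, x, y)
        assert d(specs[0], specs[0]) == 0.0
        assert abs(d(specs[0], specs[1]) - d(specs[1], specs[0])) < 1e-12
        assert d(specs[0], specs[2]) <= d(specs[0], specs[1]) + d(specs[1], specs[2]) + 1e-12


class TestAngles:
    @pytest.mark.parametrize(
        "axis,expected",
        [((1, 0, 0), 0.0), ((0, 0, 1), 90.0), ((-1, 0, 0), 180.0), ((0, 1, 0), 90.0)],
    )
    def test_in_plane_reference(self, axis, expected):
        assert abs(angle_to_in_plane_x(np.array(axis, float)) - expected) < 1e-9

    def test_normal_reference(self):
        assert abs(angle_to_normal(np.array([0, 0, 1.0]))) < 1e-9
        assert abs(angle_to_normal(np.array([1.0, 0, 0])) - 90.0) < 1e-9

    def test_normal_and_plane_angles_are_complementary(self, rng):
        for _ in range(20):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            a_n = angle_to_normal(v)
            # angle to the membrane plane itself (projection-based oracle)
            proj = v - v[2] * np.array([0, 0, 1.0])
            if np.linalg.norm(proj) < 1e-12:
                continue
            a_p = angle_between(v, proj)
            assert abs(min(a_n, 180 - a_n) + a_p - 90.0) < 1e-6

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateGeometryError):
            angle_between(np.zeros(3), np.array([1.0, 0, 0]))


class TestThetaCTM4NTM1:
    def _bundle(self):
        bp = BundleBlueprint(helices=(
            HelixBlueprint("TM4", "A", 151, 21, (0, 0, 1), (0, 0, 0)),
            HelixBlueprint("TM1", "A", 30, 20, (0, math.sin(1.0), math.cos(1.0)), (10, 0, 0)),
        ))
        return make_bundle(bp)[0]

    def test_collinear_local_axes_give_zero(self):
        bp = BundleBlueprint(helices=(
            HelixBlueprint("TM4", "A", 151, 22, (0, 0, 1), (0, 0, 0)),
            HelixBlueprint("TM1", "A", 30, 22, (0, 0, 1), (10, 0, 0)),
        ))
        model, _ = make_bundle(bp)
        ang = theta_ctm4_ntm1(
            model, HelixSpec("TM4", "A", 151, 172), HelixSpec("TM1", "A", 30, 51),
            convention="full_axes",
        )
        assert ang < 1.0

    @pytest.mark.parametrize("convention", ["local_turns", "axis_to_com_line", "full_axes"])
    def test_conventions_in_range_and_equivariant(self, convention, rng):
        model = self._bundle()
        tm4 = HelixSpec("TM4", "A", 151, 171)
        tm1 = HelixSpec("TM1", "A", 30, 49)
        ang = theta_ctm4_ntm1(model, tm4, tm1, convention)
        assert 0.0 <= ang <= 180.0
        r = random_rotation(rng)
        ang_rot = theta_ctm4_ntm1(model.transformed(r, rng.uniform(-5, 5, 3)), tm4, tm1, convention)
        assert abs(ang - ang_rot) < 1e-6

    def test_full_axes_matches_prescribed_tilt(self):
        model = self._bundle()
        ang = theta_ctm4_ntm1(
            model, HelixSpec("TM4", "A", 151, 171), HelixSpec("TM1", "A", 30, 49), "full_axes"
        )
        assert abs(ang - math.degrees(1.0)) < 1.5


class TestCircleFit:
    def test_three_point_circumscribed_exact(self):
        # circle centred (2, -1), radius 5
        angs = [0.3, 1.7, 4.0]
        pts = np.array([[2 + 5 * math.cos(a), -1 + 5 * math.sin(a)] for a in angs])
        centre, r = circle_fit(pts)
        np.testing.assert_allclose(centre, [2, -1], atol=1e-9)
        assert abs(r - 5) < 1e-9

    def test_unit_cross_exact(self):
        centre, r = circle_fit(np.array([[0, 1], [1, 0], [0, -1], [-1, 0]], float))
        np.testing.assert_allclose(centre, [0, 0], atol=1e-12)
        assert abs(r - 1) < 1e-12

    def test_collinear_raises(self):
        with pytest.raises(CircleFitError):
            circle_fit(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float))

    def test_noisy_fit_beats_grid_search_oracle(self, rng):
        for _ in range(5):
            n = 40
            c0 = rng.uniform(-3, 3, 2)
            r0 = rng.uniform(3, 8)
            ang = rng.uniform(0, 2 * math.pi, n)
            pts = c0 + np.column_stack([r0 * np.cos(ang), r0 * np.sin(ang)])
            pts += rng.normal(0, 0.05, pts.shape)
            centre, r = circle_fit(pts)

            def algebraic_residual(cx, cy, rr):
                return np.sum((np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) ** 2 - rr**2) ** 2)

            best = algebraic_residual(centre[0], centre[1], r)
            grid = 0.2
            for cx in np.linspace(centre[0] - grid, centre[0] + grid, 50):
                for cy in np.linspace(centre[1] - grid, centre[1] + grid, 50):
                    d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
                    rr2 = d2.mean()  # optimal algebraic radius for fixed centre
                    assert best <= np.sum((d2 - rr2) ** 2) + 1e-9

    def test_agrees_with_geometric_fit_at_small_noise(self, rng):
        from scipy.optimize import least_squares

        c0, r0 = np.array([1.0, 2.0]), 6.0
        ang = rng.uniform(0, 2 * math.pi, 100)
        pts = c0 + np.column_stack([r0 * np.cos(ang), r0 * np.sin(ang)])
        pts += rng.normal(0, 0.01, pts.shape)
        centre, r = circle_fit(pts)

        def geo_res(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        sol = least_squares(geo_res, [*centre, r]).x
        assert np.linalg.norm(sol[:2] - centre) < 1e-3
        assert abs(sol[2] - r) < 1e-3


class TestPoreRing:
    def _ring_model(self, radius=6.0, z_jitter=0.3):
        rng = np.random.default_rng(3)
        atoms = []
        # two Cα per ring window, residues chosen inside the four ring regions
        nums = [83, 84, 181, 182, 292, 293, 447, 448]
        for i, num in enumerate(nums):
            th = 2 * math.pi * i / len(nums)
            pos = np.array([radius * math.cos(th), radius * math.sin(th),
                            rng.uniform(-z_jitter, z_jitter)])
            atoms.append(AtomRecord(i + 1, "CA", "C", "ALA", "A", num, "", pos))
        return StructureModel(1, atoms)

    def _ring_regions(self):
        return [RegionSpec(n, "A", lo, lo + 3)
                for n, lo in [("nTM2", 83), ("nTM5", 181), ("nTM7", 292), ("nTM10", 447)]]

    def test_exact_circle_recovered(self):
        model = self._ring_model()
        r = pore_ring_radius(model, self._ring_regions())
        assert abs(r - 0.600) < 1e-6

    def test_contact_cutoff_monotone(self, channel_bundle):
        model, _ = channel_bundle
        radii_sets = []
        for cutoff in (0.3, 0.5, 0.8, 1.2):
            # count the points entering the fit via an enumeration of Cα contacts
            ring = [a.position for a in model.atoms
                    if a.name == "CA" and any(lo <= a.residue_number <= lo + 3
                                              for lo in (83, 181, 292, 447))]
            allca = [a.position for a in model.atoms if a.name == "CA"]
            n_pts = sum(
                min(np.linalg.norm(p - q) for q in ring) <= cutoff * 10 for p in allca
            )
            radii_sets.append(n_pts)
        assert radii_sets == sorted(radii_sets)

    def test_rigid_motion_invariance_with_corotated_frame(self, channel_bundle, rng):
        model, _ = channel_bundle
        r0 = pore_ring_radius(model, self._ring_regions())
        r = random_rotation(rng)
        moved = model.transformed(r, rng.uniform(-30, 30, 3))
        frame = MembraneFrame().rotated(r)
        assert abs(pore_ring_radius(moved, self._ring_regions(), frame=frame) - r0) < 1e-9


class TestDescriptorSuite:
    def test_missing_chain_reported_not_fabricated(self, channel_bundle):
        model, _ = channel_bundle  # Sec61-like chain A only
        cfg = default_config()
        values, missing = descriptor_suite(model, cfg)
        names = {v.name for v in values}
        assert "d_nTM2_nTM10" in names
        assert {"IS1", "IS2", "IS3", "IS4"} <= set(missing)
        assert names.isdisjoint(missing)

    def test_values_match_enumeration_truth(self, channel_bundle):
        model, truth = channel_bundle
        cfg = default_config()
        values, _ = descriptor_suite(model, cfg)
        got = {v.name: v.value for v in values}
        for a, b, key in [("TM2", "TM10", "d_nTM2_nTM10"), ("TM5", "TM7", "d_nTM5_nTM7")]:
            assert abs(got[key] - truth[f"d_{a}_{b}"]) < 1e-9

    def test_units_and_ranges(self, channel_bundle):
        model, _ = channel_bundle
        values, _ = descriptor_suite(model, default_config())
        for v in values:
            if v.unit == "nm":
                assert v.value >= 0
            else:
                assert 0 <= v.value <= 180
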