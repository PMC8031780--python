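"""Replica statistics: windows, means, densities, RMSD/Rg/RMSF, enrichment."""

import itertools
import math

import numpy as np
import pytest

from secgeom.ensemble import (
    DescriptorSeries,
    Predicate,
    ReplicaEnsemble,
    distribution,
    hypergeom_upper_tail,
    kabsch_superpose,
    pearson,
    radius_of_gyration,
    replica_hypergeom,
    replica_mean_se,
    rmsd_series,
    rmsf,
    select_window,
)
from secgeom.io import AtomRecord, StructureModel, Trajectory
from secgeom.synthetic import SeriesBlueprint, make_descriptor_series, make_ideal_helix

from conftest import random_rotation


def _series(values, state="free", rid="R1", t0=0.0, dt=1.0):
    values = np.asarray(values, float)
    return DescriptorSeries("d", rid, state, t0 + dt * np.arange(len(values)), values)


class TestWindow:
    def test_inclusive_endpoint_count(self):
        s = _series(np.zeros(1001))  # 0..1000 ns at 1 ns
        w = select_window(s, 950.0, 1000.0)
        assert len(w) == 51

    def test_full_window_is_identity(self):
        s = _series(np.arange(10.0))
        w = select_window(s, -1, 100)
        np.testing.assert_array_equal(w.values, s.values)

    def test_window_mean_matches_enumeration(self):
        vals = np.sin(np.arange(100) / 7.0)
        s = _series(vals)
        w = select_window(s, 20, 40)
        assert abs(w.values.mean() - np.mean([vals[i] for i in range(20, 41)])) < 1e-12

    def test_disjoint_window_raises(self):
        with pytest.raises(ValueError):
            select_window(_series(np.zeros(5)), 100, 200)


class TestReplicaMeanSE:
    def test_closed_form(self):
        series = [_series(np.full(10, v), rid=f"R{v}") for v in (1, 2, 3, 4, 5)]
        ens = ReplicaEnsemble(series)
        mean, se = replica_mean_se(ens, "free")
        assert mean == 3.0
        assert abs(se - math.sqrt(2.5) / math.sqrt(5)) < 1e-12

    def test_identical_replicas_zero_se(self):
        ens = ReplicaEnsemble([_series(np.ones(5), rid=f"R{i}") for i in range(3)])
        assert replica_mean_se(ens, "free")[1] == 0.0

    def test_single_replica_raises(self):
        ens = ReplicaEnsemble([_series(np.ones(5))])
        with pytest.raises(ValueError):
            replica_mean_se(ens, "free")

    def test_ou_parameter_recovery(self):
        bp = SeriesBlueprint(seed=11)
        ens = make_descriptor_series(bp)
        for state, mu in (("bound", bp.mean_bound), ("free", bp.mean_free)):
            mean, se = replica_mean_se(ens, state)
            assert abs(mean - mu) <= 3 * max(se, 1e-6)


class TestDistribution:
    def test_histogram_normalised_and_uniformish(self, rng):
        v = rng.uniform(0, 1, 20000)
        centers, dens = distribution(v, mode="histogram", bin_width=0.05)
        assert abs(np.sum(dens) * 0.05 - 1.0) < 1e-6
        assert np.all(np.abs(dens - 1.0) < 0.15)

    def test_kde_integrates_to_one(self, rng):
        v = rng.normal(5, 0.3, 2000)
        grid = np.linspace(0, 10, 20001)
        g, dens = distribution(v, grid=grid)
        assert abs(np.trapezoid(dens, g) - 1.0) < 1e-6

    def test_kde_mode_near_gaussian_mean(self, rng):
        v = rng.normal(1.8, 0.05, 5000)
        g, dens = distribution(v)
        bw = 0.05 * (len(v) ** (-0.2))
        assert abs(g[np.argmax(dens)] - 1.8) < 3 * bw

    def test_degenerate_series_warns(self):
        with pytest.warns(UserWarning):
            g, dens = distribution(np.full(20, 2.0))
        assert dens.max() > 0


class TestSuperposition:
    def test_identity(self, rng):
        x = rng.uniform(-10, 10, (20, 3))
        r, t, d = kabsch_superpose(x, x)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-9)
        assert d < 1e-12

    def test_rigid_copy_zero_rmsd(self, rng):
        x = rng.uniform(-10, 10, (20, 3))
        rot = random_rotation(rng)
        y = x @ rot.T + rng.uniform(-5, 5, 3)
        assert kabsch_superpose(y, x)[2] < 1e-9

    def test_beats_random_rotations(self, rng):
        x = rng.uniform(-5, 5, (12, 3))
        y = rng.uniform(-5, 5, (12, 3))
        _, _, best = kabsch_superpose(x, y)
        yc = y - y.mean(axis=0)
        xc = x - x.mean(axis=0)
        for _ in range(1000):
            rot = random_rotation(rng)
            d = np.sqrt(((xc @ rot.T - yc) ** 2).sum(axis=1).mean()) * 0.1
            assert best <= d + 1e-12

    def test_matches_independent_svd_kabsch(self, rng):
        x = rng.uniform(-8, 8, (30, 3))
        y = rng.uniform(-8, 8, (30, 3))
        _, _, got = kabsch_superpose(x, y)
        # hand-rolled SVD route as the oracle
        xc, yc = x - x.mean(0), y - y.mean(0)
        u, s, vt = np.linalg.svd(xc.T @ yc)
        d = np.sign(np.linalg.det(u @ vt))
        rot = (u @ np.diag([1, 1, d]) @ vt).T
        oracle = np.sqrt(((xc @ rot.T - yc) ** 2).sum(axis=1).mean()) * 0.1
        assert abs(got - oracle) < 1e-9


def _toy_traj(rng, n_frames=4, n_atoms=24):
    base = rng.uniform(-10, 10, (n_atoms, 3))
    atoms = [
        AtomRecord(i + 1, "CA", "C", "ALA", "A", i + 1, "", base[i]) for i in range(n_atoms)
    ]
    ref = StructureModel(1, atoms)
    frames = [ref]
    for f in range(1, n_frames):
        frames.append(ref.with_coords(base + rng.normal(0, 0.5, base.shape)))
        frames[-1].model_id = f + 1
    return Trajectory(frames=frames, times=np.arange(n_frames, dtype=float))


class TestTrajectoryMeasures:
    def test_rmsd_zero_for_identical_and_translated(self, rng):
        traj = _toy_traj(rng, n_frames=1)
        ref = traj.frames[0]
        frames = [ref, ref.with_coords(ref.coords() + [3.0, -2.0, 1.0])]
        frames[1].model_id = 2
        t = Trajectory(frames=frames, times=np.array([0.0, 1.0]))
        s = rmsd_series(t, ref)
        assert np.all(s.values < 1e-9)

    def test_rmsd_invariant_under_global_rotation(self, rng):
        traj = _toy_traj(rng)
        ref = traj.frames[0]
        base = rmsd_series(traj, ref).values
        rot = random_rotation(rng)
        moved = Trajectory(
            frames=[f.transformed(rot, np.array([5.0, 5, 5])) for f in traj.frames],
            times=traj.times,
        )
        np.testing.assert_allclose(rmsd_series(moved, ref).values, base, atol=1e-9)

    def test_rg_closed_forms(self, rng):
        single = StructureModel(1, [AtomRecord(1, "CA", "C", "ALA", "A", 1, "", np.zeros(3))])
        assert radius_of_gyration(single) == 0.0
        pair = StructureModel(1, [
            AtomRecord(1, "CA", "C", "ALA", "A", 1, "", np.zeros(3)),
            AtomRecord(2, "CA", "C", "ALA", "A", 2, "", np.array([2.0, 0, 0])),
        ])
        assert abs(radius_of_gyration(pair) - 0.1) < 1e-12
        # random cloud vs direct enumeration (equal masses)
        cloud = rng.uniform(-5, 5, (50, 3))
        model = StructureModel(1, [
            AtomRecord(i + 1, "CA", "C", "ALA", "A", i + 1, "", cloud[i]) for i in range(50)
        ])
        com = cloud.mean(axis=0)
        oracle = 0.1 * math.sqrt(((cloud - com) ** 2).sum(axis=1).mean())
        assert abs(radius_of_gyration(model) - oracle) < 1e-12

    def test_rmsf_static_zero_and_localisation(self, rng):
        helix = make_ideal_helix(30)
        frames = [StructureModel(i + 1, helix.atoms) for i in range(4)]
        static = Trajectory(frames=frames, times=np.arange(4.0))
        assert np.all(rmsf(static) < 1e-12)
        # one mobile atom in a rigid scaffold
        coords = helix.coords()
        moving = []
        for i in range(6):
            c = coords.copy()
            c[40] += [0.0, 0.0, 3.0 * math.sin(i)]
            m = helix.with_coords(c)
            m.model_id = i + 1
            moving.append(m)
        vals = rmsf(Trajectory(frames=moving, times=np.arange(6.0)))
        assert vals[40] > 0.05
        others = np.delete(vals, 40)
        assert others.max() < 0.2 * vals[40]

    def test_rmsf_matches_enumeration_on_toy(self, rng):
        traj = _toy_traj(rng, n_frames=3, n_atoms=12)
        got = rmsf(traj)
        # independent re-implementation with explicit loops
        ref = traj.frames[0].coords()
        aligned = []
        for f in traj.frames:
            x = f.coords()
            xc, rc = x - x.mean(0), ref - ref.mean(0)
            u, s, vt = np.linalg.svd(x.T @ xc * 0 + xc.T @ rc)
            d = np.sign(np.linalg.det(u @ vt))
            rot = (u @ np.diag([1, 1, d]) @ vt).T
            aligned.append(xc @ rot.T + ref.mean(0))
        mean1 = np.mean(aligned, axis=0)
        aligned2 = []
        for f in traj.frames:
            x = f.coords()
            xc, mc = x - x.mean(0), mean1 - mean1.mean(0)
            u, s, vt = np.linalg.svd(xc.T @ mc)
            d = np.sign(np.linalg.det(u @ vt))
            rot = (u @ np.diag([1, 1, d]) @ vt).T
            aligned2.append(xc @ rot.T + mean1.mean(0))
        mean2 = np.mean(aligned2, axis=0)
        oracle = 0.1 * np.sqrt(np.mean(np.sum((np.array(aligned2) - mean2) ** 2, axis=2), axis=0))
        np.testing.assert_allclose(got, oracle, atol=1e-9)


class TestPearson:
    def test_exact_correlations(self):
        x = np.arange(10.0)
        assert abs(pearson(x, x) - 1.0) < 1e-12
        assert abs(pearson(x, -x) + 1.0) < 1e-12

    def test_bivariate_normal_recovery(self, rng):
        n, rho = 2000, 0.8
        a = rng.standard_normal(n)
        b = rho * a + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        assert abs(pearson(a, b) - rho) < 0.05

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


def _brute_force_upper_tail(population, marked, draws, observed):
    """Exhaustive enumeration over all C(N, n) draws."""
    hits = total = 0
    for combo in itertools.combinations(range(population), draws):
        total += 1
        if sum(1 for i in combo if i < marked) >= observed:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_printed_five_of_five(self):
        res = hypergeom_upper_tail(10, 5, 5, 5)
        assert abs(res.p_upper - 1 / 252) < 1e-12

    def test_boundary_k_zero_is_one(self):
        assert hypergeom_upper_tail(10, 4, 5, 0).p_upper == 1.0

    @pytest.mark.parametrize("population", [5, 8, 11])
    def test_matches_enumeration(self, population):
        for marked in range(population + 1):
            for draws in range(1, population + 1):
                for observed in range(0, min(marked, draws) + 1):
                    p = hypergeom_upper_tail(population, marked, draws, observed).p_upper
                    oracle = _brute_force_upper_tail(population, marked, draws, observed)
                    assert abs(p - oracle) < 1e-9

    def test_monotone_in_observed(self):
        ps = [hypergeom_upper_tail(10, 6, 5, k).p_upper for k in range(6)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)


class TestReplicaHypergeom:
    def test_separated_states_give_printed_p(self):
        ens = make_descriptor_series(SeriesBlueprint(seed=3))
        res = replica_hypergeom(ens, Predicate(1.80, "lt"), "free")
        assert (res.population, res.marked, res.draws, res.observed) == (10, 5, 5, 5)
        assert abs(res.p_upper - 1 / 252) < 1e-12

    def test_vacuous_predicate_warns_p_one(self):
        ens = make_descriptor_series(SeriesBlueprint(seed=3))
        with pytest.warns(UserWarning):
            res = replica_hypergeom(ens, Predicate(-1000, "lt"), "free")
        assert res.p_upper == 1.0

    def test_single_state_raises(self):
        ens = make_descriptor_series(SeriesBlueprint(seed=3))
        only_free = ReplicaEnsemble([s for s in ens.series if s.state == "free"])
        with pytest.raises(ValueError):
            replica_hypergeom(only_free, Predicate(1.8, "lt"), "free")
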