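"""Replica-ensemble statistics for per-frame descriptor series.

Turns per-frame descriptor values from replicated trajectories into the
quantities used to compare two simulation states (channel bound to its
partner protein vs. free): time-window selection, per-replica means with the
standard error over replicas, probability distributions, Kabsch-superposed
RMSD, radius of gyration, per-residue RMSF, Pearson correlation, and the
replica-level hypergeometric enrichment test.

The hypergeometric test asks whether the replicas whose windowed mean
satisfies a threshold predicate concentrate in one state: with N total
replicas of which K satisfy the predicate, drawing the n replicas of the
focal state and observing k successes, the one-sided upper-tail p-value is

    p = sum_{j=k}^{min(K,n)} C(K,j) C(N-K,n-j) / C(N,n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .io import RegionSpec, StructureModel, Trajectory, select

__all__ = [
    "DescriptorSeries",
    "ReplicaEnsemble",
    "HypergeomResult",
    "Predicate",
    "select_window",
    "replica_mean_se",
    "distribution",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rmsf",
    "pearson",
    "hypergeom_upper_tail",
    "replica_hypergeom",
]

State = Literal["bound", "free"]
NM_PER_ANGSTROM = 0.1


@dataclass(frozen=True)
class DescriptorSeries:
    """Per-frame values of one descriptor in one replica."""

    descriptor: str
    replica_id: str
    state: State
    times: np.ndarray    # ns, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 1:
            raise ValueError("times/values must be equal-length 1-D arrays with >=1 sample")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ReplicaEnsemble:
    """All replicas of one descriptor, across both states."""

    series: list[DescriptorSeries]

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("empty ensemble")
        names = {s.descriptor for s in self.series}
        if len(names) > 1:
            raise ValueError(f"mixed descriptors in ensemble: {sorted(names)}")
        ids = [(s.state, s.replica_id) for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate (state, replica_id) in ensemble")

    @property
    def descriptor(self) -> str:
        return self.series[0].descriptor

    def of_state(self, state: State) -> list[DescriptorSeries]:
        return [s for s in self.series if s.state == state]


@dataclass(frozen=True)
class HypergeomResult:
    """Counts and upper-tail p of one replica-enrichment test."""

    population: int   # N
    marked: int       # K
    draws: int        # n
    observed: int     # k
    p_upper: float


@dataclass(frozen=True)
class Predicate:
    """Threshold predicate on a replica's windowed mean."""

    threshold: float
    direction: Literal["lt", "le", "gt", "ge"]

    def __call__(self, value: float) -> bool:
        return {
            "lt": value < self.threshold,
            "le": value <= self.threshold,
            "gt": value > self.threshold,
            "ge": value >= self.threshold,
        }[self.direction]


def select_window(series: DescriptorSeries, t_start: float, t_end: float) -> DescriptorSeries:
    """Samples with time in [t_start, t_end], endpoints inclusive."""
    mask = (series.times >= t_start) & (series.times <= t_end)
    if not mask.any():
        raise ValueError(
            f"window [{t_start}, {t_end}] ns does not overlap series "
            f"[{series.times[0]}, {series.times[-1]}] ns"
        )
    return DescriptorSeries(
        series.descriptor, series.replica_id, series.state, series.times[mask], series.values[mask]
    )


def replica_mean_se(
    ensemble: ReplicaEnsemble,
    state: State,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Mean of per-replica (windowed) means and its standard error.

    SE = sample standard deviation of the replica means / sqrt(R).
    """
    series = ensemble.of_state(state)
    if len(series) < 2:
        raise ValueError(f"state {state!r} needs >=2 replicas for a standard error")
    if window is not None:
        series = [select_window(s, *window) for s in series]
    means = np.array([s.values.mean() for s in series])
    return float(means.mean()), float(means.std(ddof=1) / math.sqrt(len(means)))


def distribution(
    values: np.ndarray | Sequence[float],
    mode: Literal["kde", "histogram"] = "kde",
    grid: np.ndarray | None = None,
    bin_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised probability density of a sample.

    Default is a Gaussian kernel density with Silverman bandwidth (the
    smooth-curve presentation); ``histogram`` mode uses an explicit bin
    width.  A degenerate constant sample yields a single-bin delta-like
    density with a warning.
    """
    import warnings

    v = np.asarray(values, dtype=float).ravel()
    if v.size < 10:
        raise ValueError("distribution needs >=10 samples")
    if np.ptp(v) < 1e-12:
        warnings.warn("degenerate constant series: delta-like density")
        width = max(abs(v[0]) * 1e-6, 1e-6)
        g = np.array([v[0] - width, v[0], v[0] + width])
        d = np.array([0.0, 1.0 / width, 0.0])
        return g, d
    if mode == "kde":
        kde = stats.gaussian_kde(v, bw_method="silverman")
        if grid is None:
            pad = 3.0 * kde.factor * v.std(ddof=1)
            grid = np.linspace(v.min() - pad, v.max() + pad, 512)
        return grid, kde(grid)
    if mode == "histogram":
        if bin_width is None:
            raise ValueError("histogram mode requires bin_width")
        lo = math.floor(v.min() / bin_width) * bin_width
        hi = math.ceil(v.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        dens, edges = np.histogram(v, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, dens
    raise ValueError(f"unknown mode {mode!r}")


def state_average_distribution(
    ensemble: ReplicaEnsemble,
    state: State,
    window: tuple[float, float] | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Per-replica densities on a common grid plus their pointwise average."""
    series = ensemble.of_state(state)
    if not series:
        raise ValueError(f"no replicas in state {state!r}")
    if window is not None:
        series = [select_window(s, *window) for s in series]
    if grid is None:
        allv = np.concatenate([s.values for s in series])
        pad = 0.1 * max(np.ptp(allv), 1e-9)
        grid = np.linspace(allv.min() - pad, allv.max() + pad, 512)
    curves = [distribution(s.values, grid=grid)[1] for s in series]
    return grid, np.mean(curves, axis=0), curves


# ---------------------------------------------------------------------------
# superposition-based measures
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd_nm) with the proper rotation
    (det = +1) minimising the coordinate RMSD; apply as ``x @ R.T + t``.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3 or mob.shape[0] < 3:
        raise ValueError("need matching (n>=3, 3) coordinate arrays")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    r = rot.as_matrix()
    t = rc - mc @ r.T
    moved = mob @ r.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return r, t, rmsd * NM_PER_ANGSTROM


def _selected_coords(model: StructureModel, selection: RegionSpec | None) -> np.ndarray:
    if selection is None:
        return model.coords()
    return np.array([a.position for a in select(model, selection)])


def rmsd_series(
    traj: Trajectory,
    reference: StructureModel,
    selection: RegionSpec | None = None,
    descriptor: str = "rmsd",
    replica_id: str = "R1",
    state: State = "free",
) -> DescriptorSeries:
    """Per-frame superposed RMSD (nm) against a reference model."""
    ref = _selected_coords(reference, selection)
    vals = [kabsch_superpose(_selected_coords(f, selection), ref)[2] for f in traj.frames]
    return DescriptorSeries(descriptor, replica_id, state, traj.times, np.array(vals))


def radius_of_gyration(model: StructureModel, selection: RegionSpec | None = None) -> float:
    """Mass-weighted radius of gyration about the COM, in nm."""
    atoms = select(model, selection) if selection is not None else model.atoms
    if not atoms:
        raise ValueError("empty selection for radius of gyration")
    xyz = np.array([a.position for a in atoms])
    m = np.array([a.mass for a in atoms])
    com = (xyz * m[:, None]).sum(axis=0) / m.sum()
    rg2 = (m * ((xyz - com) ** 2).sum(axis=1)).sum() / m.sum()
    return float(math.sqrt(rg2)) * NM_PER_ANGSTROM


def rmsf(traj: Trajectory, selection: RegionSpec | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-average, in nm.

    Frames are first superposed on the first frame, the time-average
    structure is computed, every frame is re-superposed on that average
    (one iteration), and the RMSF is taken about the refreshed average.
    """
    if len(traj.frames) < 2:
        raise ValueError("rmsf needs >=2 frames")
    coords = np.array([_selected_coords(f, selection) for f in traj.frames])
    ref = coords[0]
    aligned = np.empty_like(coords)
    for i, x in enumerate(coords):
        r, t, _ = kabsch_superpose(x, ref)
        aligned[i] = x @ r.T + t
    mean1 = aligned.mean(axis=0)
    for i, x in enumerate(coords):
        r, t, _ = kabsch_superpose(x, mean1)
        aligned[i] = x @ r.T + t
    mean2 = aligned.mean(axis=0)
    msf = ((aligned - mean2) ** 2).sum(axis=2).mean(axis=0)
    return np.sqrt(msf) * NM_PER_ANGSTROM


def pearson(x: np.ndarray | Sequence[float], y: np.ndarray | Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs equal-length inputs with >=3 samples")
    if x.std() < 1e-15 or y.std() < 1e-15:
        raise ValueError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# replica hypergeometric test
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(population: int, marked: int, draws: int, observed: int) -> HypergeomResult:
    """Upper-tail hypergeometric probability P(X >= observed)."""
    if not (0 <= marked <= population and 0 <= draws <= population):
        raise ValueError("invalid hypergeometric counts")
    if not (0 <= observed <= min(marked, draws)):
        raise ValueError("observed must lie in [0, min(marked, draws)]")
    p = float(stats.hypergeom.sf(observed - 1, population, marked, draws))
    return HypergeomResult(population, marked, draws, observed, min(p, 1.0))


def replica_hypergeom(
    ensemble: ReplicaEnsemble,
    predicate: Predicate,
    focal_state: State,
    window: tuple[float, float] | None = None,
    statistic: Callable[[np.ndarray], float] = np.mean,
) -> HypergeomResult:
    """Replica-level enrichment of a windowed-mean threshold in one state.

    N = all replicas of both states, K = replicas whose windowed statistic
    satisfies the predicate, n = replicas of the focal state, k = focal
    replicas satisfying it.  A vacuous predicate (K = 0) returns p = 1 with
    a warning.
    """
    import warnings

    states_present = {s.state for s in ensemble.series}
    if len(states_present) < 2:
        raise ValueError("replica_hypergeom needs both states present")
    series = ensemble.series
    if window is not None:
        series = [select_window(s, *window) for s in series]
    flags = [(s.state, predicate(float(statistic(s.values)))) for s in series]
    population = len(flags)
    marked = sum(f for _, f in flags)
    draws = sum(1 for st, _ in flags if st == focal_state)
    observed = sum(1 for st, f in flags if st == focal_state and f)
    if marked == 0:
        warnings.warn("predicate satisfied by no replica; p = 1")
        return HypergeomResult(population, 0, draws, 0, 1.0)
    return hypergeom_upper_tail(population, marked, draws, observed)
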