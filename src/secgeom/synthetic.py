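"""Seeded generators for every input class the pipeline analyses.

All generators are deterministic under a fixed seed and return, alongside the
structures or series, ground-truth values computed by direct enumeration from
the generated coordinates with plain NumPy — never through the measurement
code they are meant to test.

Peptide geometry is poly-alanine backbone (N, CA, C, O) built from internal
coordinates (standard bond lengths/angles, prescribed φ/ψ), sufficient for
Cα-based descriptors and hydrogen-bond-based secondary structure.  No lipid,
solvent or physically realistic dynamics are emulated; descriptor time series
use an Ornstein–Uhlenbeck process as the minimal autocorrelated stationary
model consistent with windowed-mean analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .docking import GateDefinition, Pose
from .ensemble import DescriptorSeries, ReplicaEnsemble
from .io import AtomRecord, RegionSpec, StructureModel, Trajectory

__all__ = [
    "HelixBlueprint",
    "BundleBlueprint",
    "SeriesBlueprint",
    "build_chain",
    "make_ideal_helix",
    "make_bundle",
    "make_beta_hairpin",
    "make_sheet_with_tails",
    "make_descriptor_series",
    "make_pose_set",
]

# Ideal backbone internal coordinates (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_CA_C_O = 120.8

ALPHA_PHI_PSI = (-57.0, -47.0)
BETA_PHI_PSI = (-139.0, 135.0)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from A-B-C internal coords."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(
    phi_psi: Sequence[tuple[float, float]],
    chain_id: str = "A",
    first_residue: int = 1,
    residue_name: str = "ALA",
    serial_start: int = 1,
) -> StructureModel:
    """Backbone-complete peptide from per-residue (φ, ψ), ω = 180°.

    φ of the first residue and ψ of the last are still consumed positionally
    but only interior torsions shape the chain.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    # seed atoms of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_res):
        prev = backbone[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, 180.0)  # ω
        phi_i = phi_psi[i][0]
        c_i = _place_atom(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_i)
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: dihedral N-CA-C-O = psi + 180
    for i, res in enumerate(backbone):
        psi = phi_psi[i][1]
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)

    atoms: list[AtomRecord] = []
    serial = serial_start
    for i, res in enumerate(backbone):
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name=residue_name,
                    chain_id=chain_id,
                    residue_number=first_residue + i,
                    insertion_code="",
                    position=res[name],
                )
            )
            serial += 1
    return StructureModel(model_id=1, atoms=atoms)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(u @ v)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, math.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    return _axis_angle(axis, math.atan2(s, c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    kx, ky, kz = axis
    k = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _ca_positions(model: StructureModel) -> np.ndarray:
    return np.array([a.position for a in model.atoms if a.name == "CA"])


def _ls_axis(ca: np.ndarray) -> np.ndarray:
    """Least-squares line direction through points, oriented first→last."""
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _screw_axis(ca: np.ndarray) -> np.ndarray:
    """Exact axis of a periodic discrete helix from its Cα trace.

    Successive bond differences u_i = d_{i+1} − d_i are purely transverse to
    the screw axis, so every cross product u_i × u_{i+1} points along it.
    """
    d = np.diff(ca, axis=0)
    u = np.diff(d, axis=0)
    crosses = np.cross(u[:-1], u[1:])
    axis = crosses.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return _ls_axis(ca)
    axis /= norm
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def make_ideal_helix(
    n_residues: int,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    phase: float = 0.0,
    chain_id: str = "A",
    first_residue: int = 1,
) -> StructureModel:
    """Canonical α-helix (φ = −57°, ψ = −47°) with its screw axis along
    ``axis`` and its Cα centroid at ``origin`` (Å).

    ``phase`` (degrees) rotates the helix about its own axis.
    """
    if n_residues < 4:
        raise ValueError("helix needs at least 4 residues")
    target = np.asarray(axis, dtype=float)
    target = target / np.linalg.norm(target)
    model = build_chain([ALPHA_PHI_PSI] * n_residues, chain_id, first_residue)
    ca = _ca_positions(model)
    raw_axis = _screw_axis(ca)
    r1 = _rotation_between(raw_axis, np.array([0.0, 0.0, 1.0]))
    r_phase = _axis_angle(np.array([0.0, 0.0, 1.0]), math.radians(phase))
    r2 = _rotation_between(np.array([0.0, 0.0, 1.0]), target)
    rot = r2 @ r_phase @ r1
    centroid = ca.mean(axis=0)
    coords = (model.coords() - centroid) @ rot.T + np.asarray(origin, dtype=float)
    return model.with_coords(coords)


@dataclass(frozen=True)
class HelixBlueprint:
    name: str
    chain_id: str
    first_residue: int
    n_residues: int
    axis: tuple[float, float, float]
    origin: tuple[float, float, float]   # Å
    phase: float = 0.0


@dataclass(frozen=True)
class BundleBlueprint:
    """Prescribed helix bundle plus an optional global rigid transform."""

    helices: tuple[HelixBlueprint, ...]
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.helices:
            raise ValueError("blueprint has no helices")
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for h in self.helices:
            rng = (h.first_residue, h.first_residue + h.n_residues - 1)
            for lo, hi in by_chain.get(h.chain_id, []):
                if rng[0] <= hi and lo <= rng[1]:
                    raise ValueError(f"overlapping residue ranges on chain {h.chain_id}")
            by_chain.setdefault(h.chain_id, []).append(rng)
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))


def make_bundle(blueprint: BundleBlueprint, turn_length: int = 4) -> tuple[StructureModel, dict[str, float]]:
    """Assemble a multi-helix model and its enumeration ground truth.

    The ground-truth dict contains, per helix pair, the distance (nm) between
    the COMs of the N-terminal-turn Cα atoms (key ``d_<a>_<b>``), and per
    helix the realised axis direction angles against z and x (degrees, keys
    ``theta_z_<name>``/``theta_x_<name>``), all computed directly from the
    generated coordinates by plain array arithmetic.
    """
    models = [
        make_ideal_helix(h.n_residues, h.axis, h.origin, h.phase, h.chain_id, h.first_residue)
        for h in blueprint.helices
    ]
    atoms: list[AtomRecord] = []
    serial = 1
    for m in models:
        for a in m.atoms:
            atoms.append(
                AtomRecord(serial, a.name, a.element, a.residue_name, a.chain_id,
                           a.residue_number, a.insertion_code, a.position)
            )
            serial += 1
    model = StructureModel(1, atoms).transformed(blueprint.rotation, blueprint.translation)

    # ground truth by direct enumeration on the final coordinates
    truth: dict[str, float] = {}
    r, t = blueprint.rotation, blueprint.translation
    turn_coms: dict[str, np.ndarray] = {}
    for h, m in zip(blueprint.helices, models):
        ca = _ca_positions(m) @ r.T + t
        turn_coms[h.name] = ca[:turn_length].mean(axis=0)
        end_n = ca[:turn_length].mean(axis=0)
        end_c = ca[-turn_length:].mean(axis=0)
        ax = end_c - end_n
        ax = ax / np.linalg.norm(ax)
        truth[f"theta_z_{h.name}"] = math.degrees(math.acos(float(np.clip(ax[2], -1, 1))))
        truth[f"theta_x_{h.name}"] = math.degrees(math.acos(float(np.clip(ax[0], -1, 1))))
    names = [h.name for h in blueprint.helices]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            truth[f"d_{a}_{b}"] = 0.1 * float(np.linalg.norm(turn_coms[a] - turn_coms[b]))
    return model, truth


# ---------------------------------------------------------------------------
# β-sheet constructions
# ---------------------------------------------------------------------------

def _register_strand(
    strand1: StructureModel,
    pair_residues1: Sequence[int],
    strand2: StructureModel,
) -> StructureModel:
    """Rigidly place strand2 antiparallel against given residues of strand1.

    Position is found by minimising the deviation of the inter-strand
    N···O distances of the target register from 2.9 Å; several deterministic
    starting placements are tried and the best optimum kept.
    """
    def backbone_of(model: StructureModel) -> dict[int, dict[str, np.ndarray]]:
        out: dict[int, dict[str, np.ndarray]] = {}
        for a in model.atoms:
            out.setdefault(a.residue_number, {})[a.name] = a.position
        return out

    bb1 = backbone_of(strand1)
    bb2 = backbone_of(strand2)
    res2 = sorted(bb2)
    if len(res2) != len(pair_residues1):
        raise ValueError("partner strand length must equal the paired window")
    # antiparallel register: first residue of strand2 pairs the last paired residue
    pairs = list(zip(sorted(pair_residues1), reversed(res2)))
    # narrow pairs (mutual CO···HN bonds) alternate along the register
    narrow = pairs[::2]

    x2 = np.array([bb2[r][n] for r in res2 for n in ("N", "CA", "C", "O")])
    names2 = [(r, n) for r in res2 for n in ("N", "CA", "C", "O")]

    def fit_from(x2_start: np.ndarray) -> tuple[float, dict[tuple[int, str], np.ndarray]]:
        centre = x2_start.mean(axis=0)

        def transformed(params: np.ndarray) -> np.ndarray:
            rx, ry, rz, tx, ty, tz = params
            rot = (
                _axis_angle(np.array([0.0, 0.0, 1.0]), rz)
                @ _axis_angle(np.array([0.0, 1.0, 0.0]), ry)
                @ _axis_angle(np.array([1.0, 0.0, 0.0]), rx)
            )
            return (x2_start - centre) @ rot.T + centre + np.array([tx, ty, tz])

        def objective(params: np.ndarray) -> float:
            pos2 = dict(zip(names2, transformed(params)))
            cost = 0.0
            for r1, r2 in narrow:
                cost += (np.linalg.norm(bb1[r1]["O"] - pos2[(r2, "N")]) - 2.9) ** 2
                cost += (np.linalg.norm(bb1[r1]["N"] - pos2[(r2, "O")]) - 2.9) ** 2
            # keep Cα spacing near sheet geometry to avoid collapsed solutions
            for r1, r2 in pairs:
                cost += 0.2 * (np.linalg.norm(bb1[r1]["CA"] - pos2[(r2, "CA")]) - 4.9) ** 2
            return cost

        res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                       options={"maxiter": 5000, "xatol": 1e-7, "fatol": 1e-12})
        return float(res.fun), dict(zip(names2, transformed(res.x)))

    def start_cost(x2_start: np.ndarray) -> float:
        pos2 = dict(zip(names2, x2_start))
        cost = 0.0
        for r1, r2 in narrow:
            cost += (np.linalg.norm(bb1[r1]["O"] - pos2[(r2, "N")]) - 2.9) ** 2
            cost += (np.linalg.norm(bb1[r1]["N"] - pos2[(r2, "O")]) - 2.9) ** 2
        for r1, r2 in pairs:
            cost += 0.2 * (np.linalg.norm(bb1[r1]["CA"] - pos2[(r2, "CA")]) - 4.9) ** 2
        return cost

    # deterministic multi-start: flip about each lab axis, shifted placements;
    # refine only the most promising starts
    ca1 = np.array([bb1[r]["CA"] for r in pair_residues1])
    u = ca1[-1] - ca1[0]
    u /= np.linalg.norm(u)
    centre2 = x2.mean(axis=0)
    starts: list[tuple[float, np.ndarray]] = []
    for flip_axis in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])):
        rot0 = _axis_angle(flip_axis, math.pi)
        perp = np.cross(u, flip_axis)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, np.array([0.57, 0.57, 0.59]))
        perp /= np.linalg.norm(perp)
        for offset in (4.5, 5.0, -4.5, -5.0):
            start = (x2 - centre2) @ rot0.T + ca1.mean(axis=0) + offset * perp
            starts.append((start_cost(start), start))
    starts.sort(key=lambda sc: sc[0])
    best: tuple[float, dict[tuple[int, str], np.ndarray]] | None = None
    for _, start in starts[:3]:
        cand = fit_from(start)
        if best is None or cand[0] < best[0]:
            best = cand
        if best[0] < 1e-8:
            break

    assert best is not None
    final = best[1]
    atoms = []
    for a in strand2.atoms:
        atoms.append(a.moved_to(final[(a.residue_number, a.name)]))
    return StructureModel(strand2.model_id, atoms)


def make_beta_hairpin(
    n_per_strand: int = 6,
    chain_ids: tuple[str, str] = ("A", "B"),
    first_residues: tuple[int, int] = (1, 1),
    single_strand: bool = False,
) -> StructureModel:
    """Two hydrogen-bond-registered antiparallel β-strands (or one strand).

    ``single_strand=True`` returns just the extended strand — a strand with
    no partner, which must carry no sheet code.
    """
    s1 = build_chain([BETA_PHI_PSI] * n_per_strand, chain_ids[0], first_residues[0])
    if single_strand:
        return s1
    s2 = build_chain(
        [BETA_PHI_PSI] * n_per_strand, chain_ids[1], first_residues[1], serial_start=len(s1.atoms) + 1
    )
    paired = list(range(first_residues[0], first_residues[0] + n_per_strand))
    s2 = _register_strand(s1, paired, s2)
    return StructureModel(1, s1.atoms + s2.atoms)


def make_sheet_with_tails(
    region_first: int = 200,
    region_last: int = 212,
    paired_first: int = 203,
    paired_last: int = 209,
    chain_id: str = "A",
    partner_chain: str = "D",
    partner_first: int = 204,
) -> StructureModel:
    """A residue window in which only a sub-window is β-sheet.

    The full window is built extended; a partner strand is registered
    antiparallel against ``paired_first..paired_last`` only, so only those
    residues acquire sheet hydrogen bonding while the tails stay coil.  The
    C-terminal paired residue loses its edge bridge, so with the defaults
    (paired 203–209) exactly 6 of the 13 window residues are assigned sheet
    code — the β content the lumenal interaction-site window shows in the
    channel–partner complex.
    """
    n = region_last - region_first + 1
    main = build_chain([BETA_PHI_PSI] * n, chain_id, region_first)
    n_pair = paired_last - paired_first + 1
    partner = build_chain(
        [BETA_PHI_PSI] * n_pair, partner_chain, partner_first, serial_start=len(main.atoms) + 1
    )
    partner = _register_strand(main, list(range(paired_first, paired_last + 1)), partner)
    return StructureModel(1, main.atoms + partner.atoms)


# ---------------------------------------------------------------------------
# descriptor time series (Ornstein–Uhlenbeck)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesBlueprint:
    """Two-state replica ensemble of an autocorrelated stationary descriptor.

    Defaults emulate the study conditions of the pore-ring diagonal: five
    1-μs replicas per state sampled every 0.1 ns over an analysis window,
    state means 1.89 nm (bound) and 1.71 nm (free) separated by 2σ
    (σ = 0.09 nm), relaxation time 1 ns.
    """

    descriptor: str = "d_nTM2_nTM10"
    mean_bound: float = 1.89
    mean_free: float = 1.71
    stdev: float = 0.09
    tau_ns: float = 1.0
    n_frames: int = 501
    dt_ns: float = 0.1
    t_start_ns: float = 950.0
    n_replicas: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stdev < 0 or self.tau_ns <= 0:
            raise ValueError("stdev must be >= 0 and tau positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def make_descriptor_series(blueprint: SeriesBlueprint) -> ReplicaEnsemble:
    """Seeded OU ensemble with the prescribed per-state stationary law.

    Uses the exact discretisation x_{t+1} = μ + (x_t − μ) a + σ √(1−a²) ξ
    with a = exp(−dt/τ); each replica starts at its stationary mean.
    """
    rng = np.random.default_rng(blueprint.seed)
    a = math.exp(-blueprint.dt_ns / blueprint.tau_ns)
    times = blueprint.t_start_ns + blueprint.dt_ns * np.arange(blueprint.n_frames)
    series: list[DescriptorSeries] = []
    for state, mu in (("bound", blueprint.mean_bound), ("free", blueprint.mean_free)):
        for ri in range(blueprint.n_replicas):
            x = np.empty(blueprint.n_frames)
            x[0] = mu if blueprint.stdev == 0 else rng.normal(mu, blueprint.stdev)
            noise = rng.standard_normal(blueprint.n_frames - 1)
            scale = blueprint.stdev * math.sqrt(1 - a * a)
            for i in range(1, blueprint.n_frames):
                x[i] = mu + (x[i - 1] - mu) * a + scale * noise[i - 1]
            series.append(
                DescriptorSeries(blueprint.descriptor, f"R{ri + 1}", state, times, x)  # type: ignore[arg-type]
            )
    return ReplicaEnsemble(series)


# ---------------------------------------------------------------------------
# docking pose sets
# ---------------------------------------------------------------------------

def _min_heavy_distance(xa: np.ndarray, xb: np.ndarray) -> float:
    return float(np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2).min())


def make_pose_set(
    receptor: StructureModel,
    gate: GateDefinition,
    n_poses: int,
    n_contacting: int,
    seed: int,
    substrate: str = "peptide",
    group: Literal["SRP_dependent", "SRP_independent"] = "SRP_independent",
    peptide_length: int = 10,
) -> tuple[list[Pose], list[bool]]:
    """Pose set with an exact number of gate-contacting poses.

    Contacting poses are placed with minimum heavy-atom distance to the gate
    windows in [0.2, 0.3] nm; the rest beyond 0.5 nm.  Returns the poses and
    the ground-truth contact flags (in pose order), the latter fixed by
    construction.  Deterministic under ``seed``.
    """
    if not 0 <= n_contacting <= n_poses:
        raise ValueError("need 0 <= n_contacting <= n_poses")
    from .io import select as _select

    gate_xyz = np.array(
        [a.position for spec in (gate.ctm2, gate.ntm7) for a in _select(receptor, spec)
         if not a.is_hydrogen]
    )
    rng = np.random.default_rng(seed)
    poses: list[Pose] = []
    flags: list[bool] = []
    for idx in range(n_poses):
        contacting = idx < n_contacting
        target_nm = rng.uniform(0.2, 0.3) if contacting else rng.uniform(0.8, 2.0)
        target = target_nm * 10.0  # Å
        # anchor on a random gate atom; random outward direction and orientation
        anchor = gate_xyz[rng.integers(len(gate_xyz))]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        helix_axis = rng.standard_normal(3)
        helix_axis /= np.linalg.norm(helix_axis)
        peptide = make_ideal_helix(
            peptide_length, axis=helix_axis, origin=(0, 0, 0), chain_id="P", first_residue=1
        )
        pep_xyz = peptide.coords()

        def min_dist_at(t: float) -> float:
            return _min_heavy_distance(pep_xyz + anchor + t * direction, gate_xyz)

        # bracket [t_lo, t_hi] with f(t_lo) < target <= f(t_hi), then bisect;
        # the min distance grows monotonically once the peptide clears the gate
        t_lo, t_hi = 0.0, 10.0
        while min_dist_at(t_lo) >= target:
            t_lo -= 1.0  # back through the anchor helix until inside the target shell
        while min_dist_at(t_hi) < target:
            t_hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (t_lo + t_hi)
            if min_dist_at(mid) < target:
                t_lo = mid
            else:
                t_hi = mid
        t_star = 0.5 * (t_lo + t_hi)
        placed = peptide.with_coords(pep_xyz + anchor + t_star * direction)
        achieved = _min_heavy_distance(placed.coords(), gate_xyz)
        if abs(achieved - target) > 0.05:
            raise RuntimeError("pose placement failed to reach target distance")
        placed.model_id = idx + 1
        poses.append(
            Pose(substrate=substrate, run_id=idx // 10 + 1, rank=idx % 10 + 1,
                 peptide=placed, group=group)
        )
        flags.append(contacting)
    # shuffle deterministically so contacting poses are not a prefix
    order = rng.permutation(n_poses)
    poses = [poses[i] for i in order]
    flags = [flags[i] for i in order]
    return poses, flags
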