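"""Conformational descriptors of a transmembrane helix bundle.

All descriptors are defined on a single :class:`~secgeom.io.StructureModel`:

* helix endpoints and axes — the endpoint of a transmembrane helix is the
  centre of mass of the Cα atoms of its terminal helical turn (four residues
  by default), and the helix axis joins the two endpoints (N→C);
* centre-of-mass distances between residue windows (lateral-gate and
  pore-ring diagonals, interaction-site contact distances), reported in nm;
* tilt angles of helix axes against the membrane normal or the in-plane x
  direction, in degrees over [0°, 180°] (orientation-signed, no folding);
* the pore-ring radius: ring Cα atoms plus their contact Cα atoms projected
  on the membrane plane and fitted with an algebraic least-squares circle.

Models are assumed to be membrane-oriented (normal along +z) unless an
explicit :class:`MembraneFrame` is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import (
    AtomRecord,
    RegionSpec,
    SelectionError,
    StructureModel,
    center_of_mass,
    select,
)

__all__ = [
    "HelixSpec",
    "MembraneFrame",
    "DescriptorValue",
    "DegenerateGeometryError",
    "CircleFitError",
    "helix_endpoint",
    "helix_axis",
    "region_pair_distance",
    "angle_between",
    "angle_to_in_plane_x",
    "angle_to_normal",
    "theta_ctm4_ntm1",
    "circle_fit",
    "pore_ring_radius",
    "descriptor_suite",
]

NM_PER_ANGSTROM = 0.1


class DegenerateGeometryError(ValueError):
    """Raised when an axis or angle is undefined (coincident points, zero vector)."""


class CircleFitError(ValueError):
    """Raised when a circle cannot be fitted (fewer than 3 non-collinear points)."""


@dataclass(frozen=True)
class HelixSpec:
    """A helix as a residue window plus the terminal-turn length."""

    name: str
    chain_id: str
    first_residue: int
    last_residue: int
    turn_length: int = 4

    def __post_init__(self) -> None:
        if self.turn_length < 3:
            raise ValueError(f"{self.name}: turn_length must be >= 3")
        if self.last_residue - self.first_residue + 1 < 2 * self.turn_length:
            raise ValueError(
                f"{self.name}: helix must span at least two turns "
                f"({2 * self.turn_length} residues)"
            )

    def terminal_region(self, end: Literal["N", "C"]) -> RegionSpec:
        if end == "N":
            lo, hi = self.first_residue, self.first_residue + self.turn_length - 1
        elif end == "C":
            lo, hi = self.last_residue - self.turn_length + 1, self.last_residue
        else:
            raise ValueError("end must be 'N' or 'C'")
        return RegionSpec(f"{self.name}:{end}", self.chain_id, lo, hi, "calpha")


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane normal and in-plane x reference direction (unit vectors)."""

    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    in_plane_x: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        x = np.asarray(self.in_plane_x, dtype=float)
        if not math.isclose(np.linalg.norm(n), 1.0, abs_tol=1e-9):
            raise ValueError("normal must be a unit vector")
        if not math.isclose(np.linalg.norm(x), 1.0, abs_tol=1e-9):
            raise ValueError("in_plane_x must be a unit vector")
        if abs(float(n @ x)) > 1e-9:
            raise ValueError("in_plane_x must be orthogonal to normal")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "in_plane_x", x)

    def in_plane_y(self) -> np.ndarray:
        return np.cross(self.normal, self.in_plane_x)

    def rotated(self, rotation: np.ndarray) -> "MembraneFrame":
        r = np.asarray(rotation, dtype=float)
        return MembraneFrame(normal=r @ self.normal, in_plane_x=r @ self.in_plane_x)


@dataclass(frozen=True)
class DescriptorValue:
    """One named descriptor measurement."""

    name: str
    value: float
    unit: Literal["nm", "degree"]
    frame_time: float | None = None


# ---------------------------------------------------------------------------
# helix endpoints, axes and angles
# ---------------------------------------------------------------------------

def helix_endpoint(
    model: StructureModel,
    helix: HelixSpec,
    end: Literal["N", "C"],
    weighting: Literal["mass", "geometric"] = "mass",
) -> np.ndarray:
    """Endpoint of a helix: COM of the Cα atoms of its terminal turn, Å."""
    atoms = select(model, helix.terminal_region(end))
    return center_of_mass(atoms, weighting)


def helix_axis(
    model: StructureModel,
    helix: HelixSpec,
    weighting: Literal["mass", "geometric"] = "mass",
) -> np.ndarray:
    """Unit vector along the helix, oriented from the N to the C endpoint."""
    n = helix_endpoint(model, helix, "N", weighting)
    c = helix_endpoint(model, helix, "C", weighting)
    d = c - n
    norm = np.linalg.norm(d)
    if norm < 1e-6:
        raise DegenerateGeometryError(f"{helix.name}: endpoints coincide")
    return d / norm


def region_pair_distance(
    model: StructureModel,
    a: RegionSpec,
    b: RegionSpec,
    weighting: Literal["mass", "geometric"] = "mass",
) -> float:
    """Distance between the COMs of two residue windows, in nm."""
    ca = center_of_mass(select(model, a), weighting)
    cb = center_of_mass(select(model, b), weighting)
    return float(np.linalg.norm(ca - cb)) * NM_PER_ANGSTROM


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, range [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("zero-length vector in angle computation")
    cosang = float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def angle_to_in_plane_x(axis: np.ndarray, frame: MembraneFrame | None = None) -> float:
    """Angle of an axis to the in-plane x direction, degrees in [0, 180].

    No absolute value is taken: an axis anti-parallel to x reads 180°, which
    is what lets the tilt of a lateral-gate helix exceed 90°.
    """
    frame = frame or MembraneFrame()
    return angle_between(axis, frame.in_plane_x)


def angle_to_normal(axis: np.ndarray, frame: MembraneFrame | None = None) -> float:
    """Angle of an axis to the membrane normal, degrees in [0, 180]."""
    frame = frame or MembraneFrame()
    return angle_between(axis, frame.normal)


ThetaConvention = Literal["local_turns", "axis_to_com_line", "full_axes"]


def theta_ctm4_ntm1(
    model: StructureModel,
    tm4: HelixSpec,
    tm1: HelixSpec,
    convention: ThetaConvention = "local_turns",
    weighting: Literal["mass", "geometric"] = "mass",
) -> float:
    """Orientation of the C-terminal turn of TM4 relative to the N-terminal
    turn of TM1, in degrees.

    The printed definition names only the two turn windows, so three
    candidate conventions are implemented:

    ``local_turns``
        angle between the local C-end axis of TM4 (COM of the last turn minus
        COM of the preceding turn) and the local N-end axis of TM1 (COM of
        the second turn minus COM of the first turn); both point N→C.
    ``axis_to_com_line``
        angle between the full TM4 axis and the line joining the two turn
        COMs (cTM4 → nTM1).
    ``full_axes``
        angle between the full TM4 and TM1 helix axes.
    """
    t = tm4.turn_length
    ctm4 = center_of_mass(
        select(model, RegionSpec("cTM4", tm4.chain_id, tm4.last_residue - t + 1, tm4.last_residue)),
        weighting,
    )
    ntm1 = center_of_mass(
        select(model, RegionSpec("nTM1", tm1.chain_id, tm1.first_residue, tm1.first_residue + t - 1)),
        weighting,
    )
    if convention == "local_turns":
        prev4 = center_of_mass(
            select(
                model,
                RegionSpec("cTM4-prev", tm4.chain_id, tm4.last_residue - 2 * t + 1, tm4.last_residue - t),
            ),
            weighting,
        )
        next1 = center_of_mass(
            select(
                model,
                RegionSpec("nTM1-next", tm1.chain_id, tm1.first_residue + t, tm1.first_residue + 2 * t - 1),
            ),
            weighting,
        )
        return angle_between(ctm4 - prev4, next1 - ntm1)
    if convention == "axis_to_com_line":
        return angle_between(helix_axis(model, tm4, weighting), ntm1 - ctm4)
    if convention == "full_axes":
        return angle_between(helix_axis(model, tm4, weighting), helix_axis(model, tm1, weighting))
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# pore-ring radius
# ---------------------------------------------------------------------------

def circle_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares (Kåsa) circle fit of planar points.

    Solves ``2 a x + 2 b y + c = x^2 + y^2`` for the centre ``(a, b)`` and
    ``r = sqrt(c + a^2 + b^2)``.  Closed-form and deterministic; exact on
    points that lie on a circle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CircleFitError("circle fit needs at least 3 planar points")
    a = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a, rhs, rcond=None)
    if rank < 3:
        raise CircleFitError("points are collinear or degenerate")
    center = sol[:2]
    r2 = sol[2] + center @ center
    if r2 <= 0:
        raise CircleFitError("degenerate circle fit (non-positive radius)")
    return center, float(math.sqrt(r2))


def _calpha_table(model: StructureModel) -> tuple[list[AtomRecord], np.ndarray]:
    cas = [a for a in model.atoms if a.name == "CA" and not a.is_hydrogen]
    return cas, np.array([a.position for a in cas], dtype=float) if cas else np.empty((0, 3))


def pore_ring_radius(
    model: StructureModel,
    ring_regions: Sequence[RegionSpec],
    contact_cutoff: float = 0.5,
    frame: MembraneFrame | None = None,
) -> float:
    """Radius of the pore-ring region, in nm.

    Cα atoms of the ring windows (N-terminal turns of TM2, TM5, TM7, TM10)
    plus every other Cα within ``contact_cutoff`` (nm) of any ring Cα are
    projected on the membrane plane and fitted with a least-squares circle.
    """
    frame = frame or MembraneFrame()
    ring_atoms: list[AtomRecord] = []
    for spec in ring_regions:
        ring_atoms.extend(a for a in select(model, spec) if a.name == "CA")
    if not ring_atoms:
        raise SelectionError("pore ring selection empty")
    ring_xyz = np.array([a.position for a in ring_atoms])
    ring_keys = {(a.chain_id, a.residue_number, a.insertion_code) for a in ring_atoms}

    all_ca, all_xyz = _calpha_table(model)
    cutoff_angstrom = contact_cutoff / NM_PER_ANGSTROM
    picked = list(ring_atoms)
    if len(all_ca):
        d = np.linalg.norm(all_xyz[:, None, :] - ring_xyz[None, :, :], axis=2)
        near = d.min(axis=1) <= cutoff_angstrom
        for a, hit in zip(all_ca, near):
            if hit and (a.chain_id, a.residue_number, a.insertion_code) not in ring_keys:
                picked.append(a)

    xyz = np.array([a.position for a in picked])
    basis = np.column_stack([frame.in_plane_x, frame.in_plane_y()])
    planar = xyz @ basis
    _, radius = circle_fit(planar)
    return radius * NM_PER_ANGSTROM


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def descriptor_suite(model: StructureModel, config) -> tuple[list[DescriptorValue], list[str]]:
    """Evaluate every configured descriptor on one model.

    Returns ``(values, missing)``: descriptors whose regions are absent from
    the model (e.g. a structure without the Sec63 chain) are listed by name in
    ``missing`` rather than fabricated.

    ``config`` is a :class:`~secgeom.config.RunConfig`.
    """
    values: list[DescriptorValue] = []
    missing: list[str] = []
    t = model.frame_time

    def attempt(name: str, unit: str, fn) -> None:
        try:
            values.append(DescriptorValue(name, float(fn()), unit, t))
        except (SelectionError, DegenerateGeometryError, CircleFitError):
            missing.append(name)

    r = config.regions
    h = config.helices
    frame = config.frame

    for name, (a, b) in config.distance_pairs.items():
        attempt(name, "nm", lambda a=a, b=b: region_pair_distance(model, r[a], r[b]))
    if "TM2" in h:
        attempt("theta_TM2", "degree", lambda: angle_to_in_plane_x(helix_axis(model, h["TM2"]), frame))
    if "TM7" in h:
        attempt("theta_TM7", "degree", lambda: angle_to_in_plane_x(helix_axis(model, h["TM7"]), frame))
    if "plug" in h:
        attempt("theta_plug", "degree", lambda: angle_to_normal(helix_axis(model, h["plug"]), frame))
    if "TM4" in h and "TM1" in h:
        attempt(
            "theta_cTM4nTM1",
            "degree",
            lambda: theta_ctm4_ntm1(model, h["TM4"], h["TM1"], config.theta_convention),
        )
    if config.ring_region_names:
        attempt(
            "pore_ring_radius",
            "nm",
            lambda: pore_ring_radius(
                model,
                [r[n] for n in config.ring_region_names],
                config.pore_contact_cutoff,
                frame,
            ),
        )
    return values, missing
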