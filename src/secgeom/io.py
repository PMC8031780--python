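"""Coordinate I/O and residue-range selection.

Structures, trajectory frames and docking pose sets all arrive as (multi-model)
PDB files.  Frames of a molecular-dynamics trajectory are represented as MODEL
blocks of one file; the atom topology must be identical across frames.

Internal length unit is the PDB-native ångström.  Descriptor-level functions
convert to nm at the reporting boundary (see :mod:`secgeom.geometry`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "RegionSpec",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select",
    "center_of_mass",
    "atomic_mass",
]


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class SelectionError(ValueError):
    """Raised when a residue-range selection resolves to zero atoms."""


_ELEMENT_CACHE: dict[str, float] = {}


def atomic_mass(element: str) -> float:
    """Standard atomic mass (u) for an element symbol."""
    key = element.strip().capitalize()
    if key not in _ELEMENT_CACHE:
        el = gemmi.Element(key)
        if el.name == "X" and key not in ("X",):
            raise ValueError(f"unknown element symbol {element!r}")
        _ELEMENT_CACHE[key] = el.weight
    return _ELEMENT_CACHE[key]


def _element_from_name(name: str, residue_name: str) -> str:
    """Derive the element from a PDB atom name by column convention."""
    name = name.strip()
    if not name:
        return ""
    # Atom names beginning with a digit (e.g. 1HB) are hydrogens.
    if name[0].isdigit():
        return "H"
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE"):
        # two-letter elements only occur in hetero/ion context
        if residue_name.strip().upper() in (name[:2].upper(), "CLA", "SOD"):
            return name[:2].capitalize()
    return name[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a PDB model."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial} has invalid position {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def mass(self) -> float:
        return atomic_mass(self.element or _element_from_name(self.name, self.residue_name))

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass
class StructureModel:
    """A single coordinate frame: an ordered sequence of atoms."""

    model_id: int
    atoms: list[AtomRecord]
    frame_time: float | None = None  # ns

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return StructureModel(self.model_id, atoms, self.frame_time)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[AtomRecord]]]:
        """Iterate residues in file order as ((chain, resnum, icode), atoms)."""
        current_key: tuple[str, int, str] | None = None
        bucket: list[AtomRecord] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code)
            if key != current_key:
                if bucket:
                    yield current_key, bucket  # type: ignore[misc]
                current_key, bucket = key, []
            bucket.append(a)
        if bucket:
            yield current_key, bucket  # type: ignore[misc]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly move every atom: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return self.with_coords(self.coords() @ rotation.T + translation)


@dataclass
class Trajectory:
    """Ordered frames with identical atom topology."""

    frames: list[StructureModel]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]  # ns

    def __post_init__(self) -> None:
        if not self.frames:
            raise PDBParseError("trajectory has no frames")
        n0 = len(self.frames[0])
        for f in self.frames[1:]:
            if len(f) != n0:
                raise ValueError("frames differ in atom count")
        if self.times is None:
            self.times = np.array(
                [f.frame_time if f.frame_time is not None else float(i) for i, f in enumerate(self.frames)]
            )
        else:
            self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


AtomSubset = Literal["calpha", "backbone", "heavy", "all"]

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class RegionSpec:
    """A named residue window on one chain, filtered to an atom subset."""

    label: str
    chain_id: str
    first_residue: int
    last_residue: int
    atom_subset: AtomSubset = "calpha"

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(f"{self.label}: first_residue > last_residue")
        if self.atom_subset not in ("calpha", "backbone", "heavy", "all"):
            raise ValueError(f"{self.label}: unknown atom_subset {self.atom_subset!r}")


def _subset_keeps(atom: AtomRecord, subset: AtomSubset) -> bool:
    if subset == "all":
        return True
    if subset == "heavy":
        return not atom.is_hydrogen
    if subset == "backbone":
        return atom.name in _BACKBONE_NAMES and not atom.is_hydrogen
    return atom.name == "CA" and not atom.is_hydrogen


def select(model: StructureModel, spec: RegionSpec) -> list[AtomRecord]:
    """Atoms of ``model`` matching a region spec, in file order.

    Missing residues inside the window are tolerated (cryo-EM entries have
    gaps) and produce a warning; an empty result raises ``SelectionError``.
    """
    out = [
        a
        for a in model.atoms
        if a.chain_id == spec.chain_id
        and spec.first_residue <= a.residue_number <= spec.last_residue
        and _subset_keeps(a, spec.atom_subset)
    ]
    if not out:
        raise SelectionError(
            f"selection {spec.label!r} (chain {spec.chain_id}, residues "
            f"{spec.first_residue}-{spec.last_residue}, {spec.atom_subset}) matched no atoms"
        )
    present = {a.residue_number for a in out}
    expected = spec.last_residue - spec.first_residue + 1
    if len(present) < expected:
        logger.warning(
            "selection %s: %d of %d residues present in model",
            spec.label,
            len(present),
            expected,
        )
    return out


def center_of_mass(
    atoms: Sequence[AtomRecord] | np.ndarray,
    weighting: Literal["mass", "geometric"] = "mass",
) -> np.ndarray:
    """Mass-weighted (default) or unweighted mean position, Å."""
    if len(atoms) == 0:
        raise ValueError("center_of_mass of empty atom set")
    coords = np.array([a.position for a in atoms], dtype=float)
    if weighting == "geometric":
        return coords.mean(axis=0)
    masses = np.array([a.mass for a in atoms], dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    """Cheap sanity pass so malformed coordinate lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}:{lineno}: truncated {rec} record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise PDBParseError(f"{path}:{lineno}: unparsable coordinates") from exc


def read_pdb(path: str | Path, times: Sequence[float] | None = None) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Each MODEL record becomes one frame; a file without MODEL records yields a
    single frame.  Atom order is preserved.  ``times`` optionally attaches
    frame times in ns (default: the frame index).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    frames: list[StructureModel] = []
    for mi, gm in enumerate(st):
        atoms: list[AtomRecord] = []
        for chain in gm:
            for res in chain:
                for at in res:
                    el = at.element.name if at.element.name != "X" else _element_from_name(at.name, res.name)
                    atoms.append(
                        AtomRecord(
                            serial=at.serial,
                            name=at.name,
                            element=el,
                            residue_name=res.name,
                            chain_id=chain.name,
                            residue_number=res.seqid.num,
                            insertion_code=(res.seqid.icode or "").strip(),
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            is_hydrogen=at.is_hydrogen(),
                        )
                    )
        if atoms:
            try:
                num = int(gm.name) if hasattr(gm, "name") else mi + 1
            except (TypeError, ValueError):
                num = mi + 1
            frames.append(StructureModel(model_id=num, atoms=atoms))
    if not frames:
        raise PDBParseError(f"{path}: no atoms found")
    if times is not None:
        times = np.asarray(times, dtype=float)
        for f, t in zip(frames, times):
            f.frame_time = float(t)
    return Trajectory(frames=frames, times=times)


def _to_gemmi(traj: Trajectory) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "secgeom"
    for frame in traj.frames:
        gm = gemmi.Model(frame.model_id)
        chain_map: dict[str, gemmi.Chain] = {}
        res_key = None
        gres = None
        for a in frame.atoms:
            if a.chain_id not in chain_map:
                chain_map[a.chain_id] = gemmi.Chain(a.chain_id)
                gm.add_chain(chain_map[a.chain_id])
                res_key = None
            chain = gm[a.chain_id]
            key = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
            if key != res_key:
                gres = gemmi.Residue()
                gres.name = a.residue_name
                gres.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                chain.add_residue(gres)
                res_key = key
            gat = gemmi.Atom()
            gat.name = a.name
            gat.element = gemmi.Element(a.element or _element_from_name(a.name, a.residue_name))
            gat.pos = gemmi.Position(*a.position)
            gat.occ = a.occupancy
            gat.serial = a.serial
            chain[len(chain) - 1].add_atom(gat)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a standards-conforming multi-model PDB file.

    ``read_pdb(write_pdb(t))`` preserves atom identity exactly and coordinates
    to PDB precision (1e-3 Å).
    """
    if not traj.frames:
        raise ValueError("cannot write empty trajectory")
    st = _to_gemmi(traj)
    opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    Path(path).write_text(st.make_pdb_string(opts))
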