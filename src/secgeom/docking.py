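"""Contact analysis of docked signal-peptide poses against the lateral gate.

A pose set is the final docked conformations of one substrate's hydrophobic
core (several independent runs, top-ranked solutions each).  A pose contacts
the lateral gate when at least one of its residues lies within a cutoff
(default 0.3 nm) of the gate windows on the channel: the C-terminal half of
the first gate helix (cTM2) and the N-terminal half of the second (nTM7).
Residue–residue distance is the minimum over heavy-atom pairs.

Group enrichment (signal anchors of SRP-dependent substrates vs. cleavable
signal sequences of SRP-independent ones) reuses the upper-tail
hypergeometric test of :mod:`secgeom.ensemble` over all poses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .ensemble import HypergeomResult, hypergeom_upper_tail
from .io import AtomRecord, RegionSpec, StructureModel, select

__all__ = [
    "Pose",
    "GateDefinition",
    "ContactSummary",
    "residue_min_distance",
    "pose_contacts_gate",
    "contact_percentage",
    "group_enrichment",
    "pose_rmsd",
    "write_pose_set",
    "read_pose_set",
]

NM_PER_ANGSTROM = 0.1
Group = Literal["SRP_dependent", "SRP_independent"]

_EXCLUDED_RESIDUES = {"HOH", "WAT", "TIP", "TIP3", "SOL"}


@dataclass(frozen=True)
class Pose:
    """One docked peptide conformation."""

    substrate: str
    run_id: int
    rank: int
    peptide: StructureModel
    group: Group

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if len(self.peptide) == 0:
            raise ValueError("peptide model is empty")


@dataclass(frozen=True)
class GateDefinition:
    """The two lateral-gate windows and the contact cutoff (nm)."""

    ctm2: RegionSpec
    ntm7: RegionSpec
    cutoff: float = 0.3
    mode: Literal["either", "both"] = "either"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class ContactSummary:
    substrate: str
    n_poses: int
    n_contacting: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.n_contacting / self.n_poses


def _heavy(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    return [
        a
        for a in atoms
        if not a.is_hydrogen and a.residue_name.strip().upper() not in _EXCLUDED_RESIDUES
    ]


def residue_min_distance(
    res_a: Sequence[AtomRecord], res_b: Sequence[AtomRecord]
) -> float:
    """Minimum heavy-atom pairwise distance between two residues, nm."""
    ha, hb = _heavy(res_a), _heavy(res_b)
    if not ha or not hb:
        raise ValueError("residue without heavy atoms")
    xa = np.array([a.position for a in ha])
    xb = np.array([b.position for b in hb])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return float(d.min()) * NM_PER_ANGSTROM


def _region_residue_coords(model: StructureModel, spec: RegionSpec) -> list[np.ndarray]:
    atoms = _heavy(select(model, spec))
    byres: dict[tuple[str, int, str], list[np.ndarray]] = {}
    for a in atoms:
        byres.setdefault((a.chain_id, a.residue_number, a.insertion_code), []).append(a.position)
    return [np.array(v) for v in byres.values()]


def _min_distance_to_region(peptide: StructureModel, coords_by_res: list[np.ndarray]) -> float:
    """Min over (peptide residue, region residue) of residue-residue distance, nm."""
    best = math.inf
    for _, atoms in peptide.residues():
        heavy = _heavy(atoms)
        if not heavy:
            continue
        xp = np.array([a.position for a in heavy])
        for xr in coords_by_res:
            d = np.linalg.norm(xp[:, None, :] - xr[None, :, :], axis=2).min()
            best = min(best, float(d))
    if not math.isfinite(best):
        raise ValueError("peptide has no heavy atoms")
    return best * NM_PER_ANGSTROM


def pose_contacts_gate(
    pose: Pose, receptor: StructureModel, gate: GateDefinition
) -> bool:
    """True when the pose touches the lateral gate under the cutoff.

    Default mode ``either`` requires proximity to cTM2 **or** nTM7 (the pose
    occupies the inter-helix volume if it approaches either flank); ``both``
    demands contact with each window.
    """
    d2 = _min_distance_to_region(pose.peptide, _region_residue_coords(receptor, gate.ctm2))
    d7 = _min_distance_to_region(pose.peptide, _region_residue_coords(receptor, gate.ntm7))
    hits = (d2 <= gate.cutoff, d7 <= gate.cutoff)
    return all(hits) if gate.mode == "both" else any(hits)


def contact_percentage(
    poses: Sequence[Pose], receptor: StructureModel, gate: GateDefinition
) -> ContactSummary:
    """Fraction of one substrate's poses contacting the gate."""
    if not poses:
        raise ValueError("empty pose set")
    substrates = {p.substrate for p in poses}
    if len(substrates) > 1:
        raise ValueError(f"mixed substrates: {sorted(substrates)}")
    n_hit = sum(pose_contacts_gate(p, receptor, gate) for p in poses)
    return ContactSummary(substrate=poses[0].substrate, n_poses=len(poses), n_contacting=n_hit)


def group_enrichment(
    summaries: Sequence[tuple[ContactSummary, Group]], focal_group: Group
) -> HypergeomResult:
    """Pose-level enrichment of gate contacts in one substrate group.

    N = all poses, K = all contacting poses, n = poses of the focal group,
    k = contacting poses of the focal group; upper-tail hypergeometric p.
    """
    groups = {g for _, g in summaries}
    if len(groups) < 2:
        raise ValueError("group_enrichment needs >=2 groups")
    population = sum(s.n_poses for s, _ in summaries)
    marked = sum(s.n_contacting for s, _ in summaries)
    draws = sum(s.n_poses for s, g in summaries if g == focal_group)
    observed = sum(s.n_contacting for s, g in summaries if g == focal_group)
    return hypergeom_upper_tail(population, marked, draws, observed)


def write_pose_set(poses: Sequence[Pose], directory) -> "object":
    """Write poses as one multi-model PDB per substrate plus a manifest CSV.

    Returns the manifest as a DataFrame with columns
    (substrate, group, run_id, rank, file, model).
    """
    import pandas as pd
    from pathlib import Path

    from .io import Trajectory, write_pdb

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    by_substrate: dict[str, list[Pose]] = {}
    for p in poses:
        by_substrate.setdefault(p.substrate, []).append(p)
    for substrate, group_poses in by_substrate.items():
        fname = f"poses_{substrate}.pdb"
        frames = []
        for i, p in enumerate(group_poses):
            frame = StructureModel(i + 1, p.peptide.atoms)
            frames.append(frame)
            rows.append(
                {"substrate": substrate, "group": p.group, "run_id": p.run_id,
                 "rank": p.rank, "file": fname, "model": i + 1}
            )
        write_pdb(Trajectory(frames=frames), directory / fname)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_pose_set(manifest_path) -> list[Pose]:
    """Load poses from a manifest CSV written by :func:`write_pose_set`."""
    import pandas as pd
    from pathlib import Path

    from .io import read_pdb

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cache: dict[str, list[StructureModel]] = {}
    poses = []
    for row in df.itertuples():
        if row.file not in cache:
            cache[row.file] = read_pdb(base / row.file).frames
        poses.append(
            Pose(substrate=str(row.substrate), run_id=int(row.run_id), rank=int(row.rank),
                 peptide=cache[row.file][int(row.model) - 1], group=str(row.group))  # type: ignore[arg-type]
        )
    return poses


def pose_rmsd(
    pose_a: Pose,
    pose_b: Pose,
    atoms: Literal["backbone", "calpha", "heavy"] = "backbone",
    superpose: bool = False,
) -> float:
    """RMSD between two poses over shared residues, in Å.

    Poses docked against the same rigid receptor share its frame, so no
    re-superposition is applied by default; ``superpose=True`` fits the
    rigid-body optimum first.
    """
    subset = {"backbone": {"N", "CA", "C", "O"}, "calpha": {"CA"}}.get(atoms)

    def table(p: Pose) -> dict[tuple[tuple[str, int, str], str], np.ndarray]:
        out = {}
        for key, group in p.peptide.residues():
            for a in _heavy(group):
                if subset is None or a.name in subset:
                    out[(key, a.name)] = a.position
        return out

    ta, tb = table(pose_a), table(pose_b)
    shared = sorted(set(ta) & set(tb))
    if not shared:
        raise ValueError("poses share no residues/atoms")
    xa = np.array([ta[k] for k in shared])
    xb = np.array([tb[k] for k in shared])
    if superpose:
        from .ensemble import kabsch_superpose

        _, _, rmsd_nm = kabsch_superpose(xa, xb)
        return rmsd_nm / NM_PER_ANGSTROM
    return float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))
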