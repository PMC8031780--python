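"""Kabsch–Sander secondary-structure assignment.

Implements the dictionary-of-protein-secondary-structure algorithm from
backbone hydrogen bonding: an electrostatic bond energy between each
amide (N–H) donor and carbonyl (C=O) acceptor,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   kcal/mol,

with a bond assigned when E < -0.5 kcal/mol; n-turn detection (n = 3, 4, 5),
parallel/antiparallel bridge detection, ladders merged across β-bulges into
sheets, and the 8-state code {H, G, I, E, B, T, S, C}.

Amide hydrogens are constructed when absent: 1.0 Å from N along the
normalised sum of the unit vectors N−C(prev) and N−O(prev); prolines do not
donate.  Chain breaks (residue-number gaps, missing backbone atoms, or a
peptide C–N distance beyond 2.5 Å) terminate hydrogen-bond patterns.

Residues with incomplete backbone (missing any of N, CA, C, O) are coded C
and flagged rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AtomRecord, RegionSpec, StructureModel

__all__ = [
    "SSAssignment",
    "place_amide_hydrogen",
    "hbond_energy",
    "assign_ss",
    "beta_fraction",
]

# Kabsch–Sander electrostatic model constants
_Q1Q2F = 0.084 * 332.0          # kcal/mol * Å
_EBOND = -0.5                   # bond threshold, kcal/mol
_EMIN = -9.9                    # clash energy, kcal/mol
_MIN_DIST = 0.5                 # Å, closer than this is a clash
_CA_SEARCH = 9.0                # Å, donor/acceptor Cα pre-filter
_PEPTIDE_BOND_MAX = 2.5         # Å, C(i)-N(i+1) continuity check

ResidueKey = tuple[str, int, str]


@dataclass
class _Residue:
    key: ResidueKey
    name: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None
    o: np.ndarray | None = None
    h: np.ndarray | None = None
    complete: bool = False
    chain_pos: int = -1          # index within its continuous run; -1 = not in a run

    @property
    def is_proline(self) -> bool:
        return self.name.strip().upper() == "PRO"


def _collect_residues(model: StructureModel) -> list[_Residue]:
    out: list[_Residue] = []
    for (chain, num, icode), atoms in model.residues():
        if all(a.is_hydrogen for a in atoms):
            continue
        res = _Residue(key=(chain, num, icode), name=atoms[0].residue_name)
        for a in atoms:
            nm = a.name.strip().upper()
            if nm == "N":
                res.n = a.position
            elif nm == "CA":
                res.ca = a.position
            elif nm == "C":
                res.c = a.position
            elif nm == "O":
                res.o = a.position
            elif nm in ("H", "HN", "H1") and res.h is None:
                res.h = a.position
        res.complete = all(v is not None for v in (res.n, res.ca, res.c, res.o))
        out.append(res)
    return out


def _split_runs(residues: list[_Residue]) -> list[list[int]]:
    """Indices of continuous peptide runs (no gaps, complete backbone)."""
    runs: list[list[int]] = []
    current: list[int] = []
    for i, res in enumerate(residues):
        ok = res.complete
        contiguous = False
        if ok and current:
            prev = residues[current[-1]]
            same_chain = prev.key[0] == res.key[0]
            step = res.key[1] - prev.key[1]
            bonded = (
                same_chain
                and step == 1
                and float(np.linalg.norm(res.n - prev.c)) <= _PEPTIDE_BOND_MAX
            )
            contiguous = bonded
        if ok and contiguous:
            current.append(i)
        else:
            if len(current) >= 2:
                runs.append(current)
            current = [i] if ok else []
    if len(current) >= 2:
        runs.append(current)
    return runs


def place_amide_hydrogen(model: StructureModel) -> StructureModel:
    """Return a copy of ``model`` with constructed backbone amide hydrogens.

    Hydrogens already present are kept.  Chain-start residues and prolines
    are skipped (no donor H).
    """
    residues = _collect_residues(model)
    runs = _split_runs(residues)
    new_h: dict[ResidueKey, np.ndarray] = {}
    for run in runs:
        for prev_i, i in zip(run, run[1:]):
            res, prev = residues[i], residues[prev_i]
            if res.h is not None or res.is_proline:
                continue
            pos = _construct_h(res.n, prev.c, prev.o)
            if pos is not None:
                new_h[res.key] = pos

    if not new_h:
        return model
    atoms: list[AtomRecord] = []
    serial = max((a.serial for a in model.atoms), default=0)
    for key, group in model.residues():
        atoms.extend(group)
        if key in new_h:
            serial += 1
            a0 = group[0]
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name="H",
                    element="H",
                    residue_name=a0.residue_name,
                    chain_id=a0.chain_id,
                    residue_number=a0.residue_number,
                    insertion_code=a0.insertion_code,
                    position=new_h[key],
                    is_hydrogen=True,
                )
            )
    return StructureModel(model.model_id, atoms, model.frame_time)


def _construct_h(n: np.ndarray, c_prev: np.ndarray, o_prev: np.ndarray) -> np.ndarray | None:
    u1 = n - c_prev
    u2 = n - o_prev
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 < 1e-9 or n2 < 1e-9:
        return None
    d = u1 / n1 + u2 / n2
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        return None
    return n + d / nd


def hbond_energy(
    donor: Mapping[str, np.ndarray] | _Residue,
    acceptor: Mapping[str, np.ndarray] | _Residue,
) -> float:
    """Kabsch–Sander H-bond energy, kcal/mol.

    ``donor`` provides N and H positions, ``acceptor`` C and O.  A pairwise
    distance below 0.5 Å is a clash and returns the floor energy -9.9.
    """
    if isinstance(donor, _Residue):
        dn, dh = donor.n, donor.h
    else:
        dn, dh = donor["N"], donor["H"]
    if isinstance(acceptor, _Residue):
        ac, ao = acceptor.c, acceptor.o
    else:
        ac, ao = acceptor["C"], acceptor["O"]
    if dn is None or dh is None or ac is None or ao is None:
        raise ValueError("donor needs N,H and acceptor needs C,O")
    r_on = float(np.linalg.norm(ao - dn))
    r_ch = float(np.linalg.norm(ac - dh))
    r_oh = float(np.linalg.norm(ao - dh))
    r_cn = float(np.linalg.norm(ac - dn))
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return _EMIN
    e = _Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, _EMIN)


@dataclass
class SSAssignment:
    """Per-residue 8-state codes plus the accepted H-bond partner table."""

    keys: list[ResidueKey]
    codes: list[str]                       # one of H G I E B T S C per residue
    incomplete: list[bool]
    # acceptor partners per donor residue: key -> up to 2 (acceptor_key, energy)
    donated: dict[ResidueKey, list[tuple[ResidueKey, float]]] = field(default_factory=dict)

    def code_of(self, key: ResidueKey) -> str | None:
        try:
            return self.codes[self.keys.index(key)]
        except ValueError:
            return None

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.codes:
            out[c] = out.get(c, 0) + 1
        return out


def assign_ss(model: StructureModel) -> SSAssignment:
    """Assign Kabsch–Sander secondary structure to every residue of a model."""
    model = place_amide_hydrogen(model)
    residues = _collect_residues(model)
    runs = _split_runs(residues)
    for run in runs:
        for pos, i in enumerate(run):
            residues[i].chain_pos = pos
    run_of: dict[int, int] = {}
    for ri, run in enumerate(runs):
        for i in run:
            run_of[i] = ri

    nres = len(residues)
    # --- H-bond table: bond[i][j] means CO of residue index i accepts the
    # amide H of residue index j.  DSSP keeps the two best acceptors per donor.
    donated: dict[int, list[tuple[float, int]]] = {i: [] for i in range(nres)}
    cas = np.array([r.ca if r.ca is not None else [1e6, 1e6, 1e6] for r in residues])
    eligible = [i for i in range(nres) if i in run_of]
    for j in eligible:  # donor
        dres = residues[j]
        if dres.h is None or dres.is_proline:
            continue
        d2 = np.linalg.norm(cas[eligible] - cas[j], axis=1)
        for a_idx, i in enumerate(eligible):  # acceptor
            if i == j or d2[a_idx] > _CA_SEARCH:
                continue
            # the donor's own preceding residue cannot be its acceptor
            if run_of[i] == run_of[j] and residues[j].chain_pos - residues[i].chain_pos == 1:
                continue
            e = hbond_energy(dres, residues[i])
            if e < _EBOND:
                donated[j].append((e, i))
    for j in donated:
        donated[j] = sorted(donated[j])[:2]

    bond = {(i, j) for j, lst in donated.items() for _, i in lst}

    def hb(i: int | None, j: int | None) -> bool:
        return i is not None and j is not None and (i, j) in bond

    # --- n-turns within runs
    turns: dict[int, dict[int, bool]] = {3: {}, 4: {}, 5: {}}
    for run in runs:
        for p, i in enumerate(run):
            for n in (3, 4, 5):
                if p + n < len(run):
                    turns[n][i] = hb(i, run[p + n])

    codes = ["C"] * nres

    def set_code(i: int, code: str) -> None:
        if codes[i] == "C":
            codes[i] = code

    # --- helices: two consecutive n-turns; priority H, then strands, then G, I
    def mark_helix(n: int, code: str) -> None:
        for run in runs:
            for p in range(1, len(run)):
                i_prev, i = run[p - 1], run[p]
                if turns[n].get(i_prev) and turns[n].get(i):
                    for q in range(p, min(p + n, len(run))):
                        set_code(run[q], code)

    mark_helix(4, "H")

    # --- bridges
    def neighbors(i: int) -> tuple[int | None, int | None]:
        run = runs[run_of[i]]
        p = residues[i].chain_pos
        prv = run[p - 1] if p - 1 >= 0 else None
        nxt = run[p + 1] if p + 1 < len(run) else None
        return prv, nxt

    par_bridges: list[tuple[int, int]] = []
    anti_bridges: list[tuple[int, int]] = []
    for i in eligible:
        im, ip = neighbors(i)
        for j in eligible:
            if j <= i + 2:
                continue
            if run_of[i] == run_of[j] and residues[j].chain_pos - residues[i].chain_pos <= 2:
                continue
            jm, jp = neighbors(j)
            if (hb(im, j) and hb(j, ip)) or (hb(jm, i) and hb(i, jp)):
                par_bridges.append((i, j))
            if (hb(i, j) and hb(j, i)) or (hb(im, jp) and hb(jm, ip)):
                anti_bridges.append((i, j))

    def build_ladders(bridges: list[tuple[int, int]], anti: bool) -> list[list[tuple[int, int]]]:
        ladders: list[list[tuple[int, int]]] = []
        for br in sorted(bridges):
            placed = False
            for lad in ladders:
                li, lj = lad[-1]
                if br[0] == li + 1 and br[1] == (lj - 1 if anti else lj + 1):
                    lad.append(br)
                    placed = True
                    break
            if not placed:
                ladders.append([br])
        return ladders

    def strand_ranges(lad: list[list[tuple[int, int]]]) -> tuple[tuple[int, int], tuple[int, int]]:
        i_vals = [b[0] for grp in lad for b in grp]
        j_vals = [b[1] for grp in lad for b in grp]
        return (min(i_vals), max(i_vals)), (min(j_vals), max(j_vals))

    def merge_bulges(ladders: list[list[tuple[int, int]]]) -> list[list[list[tuple[int, int]]]]:
        """Group ladders linked by β-bulges (gap ≤1 on one strand, ≤4 on the other)."""
        groups = [[lad] for lad in ladders]
        merged = True
        while merged:
            merged = False
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    (ai, aj) = strand_ranges(groups[a])
                    (bi, bj) = strand_ranges(groups[b])
                    gap_i = max(bi[0] - ai[1], ai[0] - bi[1]) - 1
                    gap_j = max(bj[0] - aj[1], aj[0] - bj[1]) - 1
                    if gap_i < 0 or gap_j < 0:
                        continue
                    if (gap_i <= 1 and gap_j <= 4) or (gap_i <= 4 and gap_j <= 1):
                        groups[a].extend(groups[b])
                        del groups[b]
                        merged = True
                        break
                if merged:
                    break
        return groups

    all_ladders = [(lad, False) for lad in build_ladders(par_bridges, anti=False)]
    all_ladders += [(lad, True) for lad in build_ladders(anti_bridges, anti=True)]

    extended: set[int] = set()
    single: set[int] = set()
    groups = merge_bulges([lad for lad, _ in all_ladders])
    for grp in groups:
        n_bridges = sum(len(lad) for lad in grp)
        (i_lo, i_hi), (j_lo, j_hi) = strand_ranges(grp)
        members = set(range(i_lo, i_hi + 1)) | set(range(j_lo, j_hi + 1))
        if n_bridges >= 2:
            extended |= members
        else:
            single |= members
    for i in sorted(extended):
        set_code(i, "E")
    for i in sorted(single - extended):
        set_code(i, "B")

    mark_helix(3, "G")
    mark_helix(5, "I")

    # --- turns: interior residues of isolated n-turns
    for n in (3, 4, 5):
        for i, has in turns[n].items():
            if has:
                run = runs[run_of[i]]
                p = residues[i].chain_pos
                for q in range(p + 1, min(p + n, len(run))):
                    set_code(run[q], "T")

    # --- bends
    for run in runs:
        for p in range(2, len(run) - 2):
            i = run[p]
            if codes[i] != "C":
                continue
            u = residues[i].ca - residues[run[p - 2]].ca
            v = residues[run[p + 2]].ca - residues[i].ca
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-9 or nv < 1e-9:
                continue
            ang = math.degrees(math.acos(float(np.clip(u @ v / (nu * nv), -1, 1))))
            if ang > 70.0:
                codes[i] = "S"

    donated_keys = {
        residues[j].key: [(residues[i].key, e) for e, i in lst]
        for j, lst in donated.items()
        if lst
    }
    return SSAssignment(
        keys=[r.key for r in residues],
        codes=codes,
        incomplete=[not r.complete for r in residues],
        donated=donated_keys,
    )


def beta_fraction(ss: SSAssignment, region: RegionSpec, include_bridge: bool = False) -> float:
    """Percentage of region residues in β-sheet conformation.

    Counts code E (plus isolated bridges B when ``include_bridge``) over the
    residues of the window that carry an assigned code.
    """
    wanted = {"E", "B"} if include_bridge else {"E"}
    n_total = 0
    n_beta = 0
    for key, code, inc in zip(ss.keys, ss.codes, ss.incomplete):
        chain, num, _ = key
        if chain == region.chain_id and region.first_residue <= num <= region.last_residue:
            if inc:
                continue
            n_total += 1
            if code in wanted:
                n_beta += 1
    if n_total == 0:
        raise ValueError(f"region {region.label}: no assignable residues")
    return 100.0 * n_beta / n_total
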