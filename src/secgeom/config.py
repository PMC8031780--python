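"""Declarative run configuration: chains, helix windows, region windows.

The shipped default encodes the yeast Sec61/Sbh1/Sss1/Sec63 definitions in
author numbering: pore-ring diagonals between the N-terminal turns of
TM2/TM5/TM7/TM10, the middle-turn TM2–TM4 distance, the four Sec63/Sbh1
interaction sites IS1–IS4, the plug helix Y64–A71 and the lateral-gate
windows cTM2 (I91–T98) / nTM7 (T291–A298).

Chain identifiers vary between deposited entries, so the chain mapping is a
parameter; descriptor windows are expressed against protein names and
resolved to chains when the config is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .geometry import HelixSpec, MembraneFrame, ThetaConvention
from .io import RegionSpec, StructureModel

__all__ = ["RunConfig", "default_config", "load_config", "guess_chain_mapping", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration fails fail-fast validation."""


@dataclass
class RunConfig:
    """Everything a descriptor run needs, validated before computation."""

    chains: dict[str, str]                      # protein name -> chain id
    helices: dict[str, HelixSpec]
    regions: dict[str, RegionSpec]
    distance_pairs: dict[str, tuple[str, str]]  # descriptor -> (region, region)
    ring_region_names: list[str] = field(default_factory=list)
    frame: MembraneFrame = field(default_factory=MembraneFrame)
    theta_convention: ThetaConvention = "local_turns"
    pore_contact_cutoff: float = 0.5            # nm
    window: tuple[float, float] | None = None   # (t_start, t_end) ns
    gate_cutoff: float = 0.3                    # nm
    seed: int = 0

    def validate_against(self, model: StructureModel) -> list[str]:
        """Collect (not raise) the names of descriptors whose chains are absent."""
        present = set(model.chains())
        problems = []
        for name, spec in self.regions.items():
            if spec.chain_id not in present:
                problems.append(f"region {name}: chain {spec.chain_id!r} absent")
        for name, h in self.helices.items():
            if h.chain_id not in present:
                problems.append(f"helix {name}: chain {h.chain_id!r} absent")
        return problems


_DEFAULT_CHAINS = {"Sec61": "A", "Sbh1": "B", "Sss1": "C", "Sec63": "D"}

# Helix windows, author numbering of the yeast proteins.  The terminal turns
# of TM2/TM5/TM7/TM10 coincide with the pore-ring windows; the TM4 C-turn and
# TM1 N-turn are the theta_cTM4nTM1 windows.
_HELICES: dict[str, tuple[str, int, int]] = {
    "TM1": ("Sec61", 30, 49),
    "TM2": ("Sec61", 83, 98),
    "TM4": ("Sec61", 151, 171),
    "TM5": ("Sec61", 181, 200),
    "TM7": ("Sec61", 292, 311),
    "TM10": ("Sec61", 447, 466),
    "plug": ("Sec61", 64, 71),
}

# label -> (protein, first, last, atom_subset)
_REGIONS: dict[str, tuple[str, int, int, str]] = {
    "nTM2": ("Sec61", 83, 86, "calpha"),
    "nTM5": ("Sec61", 181, 184, "calpha"),
    "nTM7": ("Sec61", 292, 295, "calpha"),
    "nTM10": ("Sec61", 447, 450, "calpha"),
    "mTM2": ("Sec61", 89, 92, "calpha"),
    "mTM4": ("Sec61", 158, 161, "calpha"),
    "cTM4": ("Sec61", 168, 171, "calpha"),
    "nTM1": ("Sec61", 30, 33, "calpha"),
    "IS1_Sec61": ("Sec61", 274, 276, "calpha"),
    "IS1_Sec63": ("Sec63", 446, 448, "calpha"),
    "IS2_Sbh1": ("Sbh1", 61, 63, "calpha"),
    "IS2_Sec63": ("Sec63", 232, 235, "calpha"),
    # IS3 is defined on whole residues, not Cα only: heavy-atom COM.
    "IS3_Sec61": ("Sec61", 202, 202, "heavy"),
    "IS3_Sec63": ("Sec63", 207, 207, "heavy"),
    "IS4_Sec61": ("Sec61", 37, 40, "calpha"),
    "IS4_Sec63": ("Sec63", 234, 237, "calpha"),
    "IS3_region": ("Sec61", 200, 212, "calpha"),
    "IS1_region": ("Sec61", 264, 282, "calpha"),
    "gate_cTM2": ("Sec61", 91, 98, "heavy"),
    "gate_nTM7": ("Sec61", 291, 298, "heavy"),
}

_DISTANCE_PAIRS: dict[str, tuple[str, str]] = {
    "d_nTM2_nTM10": ("nTM2", "nTM10"),
    "d_nTM5_nTM7": ("nTM5", "nTM7"),
    "d_nTM2_nTM7": ("nTM2", "nTM7"),
    "d_mTM2_mTM4": ("mTM2", "mTM4"),
    "IS1": ("IS1_Sec61", "IS1_Sec63"),
    "IS2": ("IS2_Sbh1", "IS2_Sec63"),
    "IS3": ("IS3_Sec61", "IS3_Sec63"),
    "IS4": ("IS4_Sec61", "IS4_Sec63"),
}


def default_config(chains: Mapping[str, str] | None = None, **overrides) -> RunConfig:
    """The shipped yeast definitions, optionally with a custom chain mapping."""
    cmap = dict(_DEFAULT_CHAINS)
    if chains:
        cmap.update(chains)
    helices = {
        name: HelixSpec(name, cmap[prot], lo, hi) for name, (prot, lo, hi) in _HELICES.items()
    }
    regions = {
        label: RegionSpec(label, cmap[prot], lo, hi, subset)  # type: ignore[arg-type]
        for label, (prot, lo, hi, subset) in _REGIONS.items()
    }
    cfg = RunConfig(
        chains=cmap,
        helices=helices,
        regions=regions,
        distance_pairs=dict(_DISTANCE_PAIRS),
        ring_region_names=["nTM2", "nTM5", "nTM7", "nTM10"],
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    return cfg


def guess_chain_mapping(model: StructureModel) -> dict[str, str]:
    """Heuristic protein → chain assignment for a deposited structure.

    Deposited entries label chains differently, so chains are recognised by
    which descriptor residue windows they cover in author numbering: the
    pore-forming subunit must cover most of the four pore-ring turn windows,
    the partner protein its interaction-site windows, and the β-subunit its
    short membrane window on a small chain.  Only confidently identified
    proteins appear in the result.
    """
    coverage: dict[str, set[int]] = {}
    for a in model.atoms:
        if a.name == "CA" and not a.is_hydrogen:
            coverage.setdefault(a.chain_id, set()).add(a.residue_number)

    def score(chain: str, windows: list[range]) -> int:
        return sum(1 for w in windows if set(w) <= coverage[chain])

    sec61_windows = [range(83, 87), range(181, 185), range(292, 296), range(447, 451)]
    sec63_windows = [range(205, 210), range(232, 238), range(444, 450)]
    sbh1_windows = [range(60, 64)]

    mapping: dict[str, str] = {}
    best61 = max(coverage, key=lambda c: (score(c, sec61_windows), len(coverage[c])), default=None)
    if best61 is not None and score(best61, sec61_windows) >= 3:
        mapping["Sec61"] = best61
    rest = [c for c in coverage if c != mapping.get("Sec61")]
    best63 = max(rest, key=lambda c: (score(c, sec63_windows), len(coverage[c])), default=None)
    if best63 is not None and score(best63, sec63_windows) >= 2:
        mapping["Sec63"] = best63
    small = [c for c in rest if c != mapping.get("Sec63") and len(coverage[c]) <= 120]
    bestb = max(small, key=lambda c: score(c, sbh1_windows), default=None)
    if bestb is not None and score(bestb, sbh1_windows) >= 1:
        mapping["Sbh1"] = bestb
    return mapping


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unspecified sections fall back to the defaults.

    Recognised keys: ``chains`` (protein -> chain id), ``helices``
    (name -> [protein, first, last] or [protein, first, last, turn_length]),
    ``regions`` (label -> [protein, first, last, atom_subset]),
    ``theta_convention``, ``pore_contact_cutoff``, ``gate_cutoff``,
    ``window`` ([t_start, t_end]), ``seed``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cmap = dict(_DEFAULT_CHAINS)
    cmap.update(raw.get("chains", {}))
    cfg = default_config(chains=cmap)
    for name, row in raw.get("helices", {}).items():
        prot, lo, hi, *rest = row
        cfg.helices[name] = HelixSpec(name, cmap[prot], int(lo), int(hi), *(int(x) for x in rest))
    for label, row in raw.get("regions", {}).items():
        prot, lo, hi, subset = row
        cfg.regions[label] = RegionSpec(label, cmap[prot], int(lo), int(hi), subset)
    if "theta_convention" in raw:
        cfg.theta_convention = raw["theta_convention"]
    if "pore_contact_cutoff" in raw:
        cfg.pore_contact_cutoff = float(raw["pore_contact_cutoff"])
    if "gate_cutoff" in raw:
        cfg.gate_cutoff = float(raw["gate_cutoff"])
    if "window" in raw:
        lo, hi = raw["window"]
        cfg.window = (float(lo), float(hi))
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg
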