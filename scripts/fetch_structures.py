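"""Download the cryo-EM reference structures used for descriptor validation.

Requires network access.  Fetches the Sec complex (6ND1) and the idle (3J7Q)
and open (3JC2) ribosome–Sec61 entries from RCSB, extracts the translocon
chains, and writes plain-text PDB files under ``data/cryoem/``.  Where the
OPM database provides a membrane-oriented copy (needed for tilt angles
against the membrane normal), that orientation is preferred.

Usage:  python scripts/fetch_structures.py [--dest data/cryoem]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

import gemmi

ENTRIES = ["6nd1", "3j7q", "3jc2"]
RCSB_CIF = "https://files.rcsb.org/download/{pdb_id}.cif"
OPM_PDB = "https://opm-assets.storage.googleapis.com/pdb/{pdb_id}.pdb"


def _fetch(url: str, dest: Path) -> bool:
    try:
        with urllib.request.urlopen(url, timeout=120) as resp:
            dest.write_bytes(resp.read())
        return True
    except Exception as exc:  # noqa: BLE001
        print(f"  failed: {url} ({exc})")
        return False


def _slim(structure: gemmi.Structure, out_path: Path) -> None:
    """Keep protein chains below ribosome size and write single-model PDB."""
    structure.setup_entities()
    structure.remove_ligands_and_waters()
    model = structure[0]
    keep = []
    for chain in model:
        n_res = len(chain)
        has_ca = any(res.find_atom("CA", "*") for res in chain)
        if has_ca and n_res <= 800:  # drop rRNA and ribosomal protein bulk by size
            keep.append(chain.name)
    for chain in [c.name for c in model]:
        if chain not in keep:
            model.remove_chain(chain)
    structure.write_pdb(str(out_path))


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", default="data/cryoem", type=Path)
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    ok = True
    for pdb_id in ENTRIES:
        out = args.dest / f"{pdb_id}.pdb"
        if out.exists():
            print(f"{pdb_id}: already present")
            continue
        print(f"{pdb_id}: downloading")
        raw = args.dest / f"{pdb_id}.raw"
        if _fetch(OPM_PDB.format(pdb_id=pdb_id), raw):
            st = gemmi.read_structure(str(raw))
        elif _fetch(RCSB_CIF.format(pdb_id=pdb_id), raw):
            st = gemmi.read_structure(str(raw))
            print(f"  note: {pdb_id} is in the deposited frame; tilt angles against"
                  " the membrane normal require a membrane-oriented copy")
        else:
            ok = False
            continue
        _slim(st, out)
        raw.unlink(missing_ok=True)
        print(f"  wrote {out}")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
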