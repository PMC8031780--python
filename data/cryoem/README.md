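# Cryo-EM reference structures (not bundled)

The descriptor-validation tests and the worked examples against deposited
structures use three entries that are too large to ship and must be fetched
once (network required):

| file | entry | contents |
|------|-------|----------|
| `6nd1.pdb` | 6ND1 | yeast Sec complex (channel bound to the Sec62–Sec63 partner complex) |
| `3j7q.pdb` | 3J7Q | idle ribosome-bound Sec61 channel |
| `3jc2.pdb` | 3JC2 | open (substrate-engaged) ribosome-bound Sec61 channel |

Fetch them with:

    python scripts/fetch_structures.py

The script prefers membrane-oriented copies (needed for tilt angles against
the membrane normal) and strips ribosomal RNA/protein bulk, keeping the
translocon chains as plain-text PDB.
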