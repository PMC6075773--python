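"""Regenerate the bundled synthetic reference sequences.

The packaged reference FASTAs (src/aoxkit/data/tbaox_reference.fasta and
clade_references.fasta) are deterministic synthetic stand-ins: a shared
340-residue background with the catalog residue letters, signature motifs,
diagnostic residues and clade-specific substitutions planted at fixed
positions.  They exist so the pipeline, the simulator and the test suite run
fully offline; replace them with real sequences for production analyses.

Run from the repository root:  python scripts/make_reference_data.py
"""

from __future__ import annotations

import random
from pathlib import Path

LENGTH = 340
SEED = 20180803
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# reference residue letters at reference-numbering positions (1-based)
DIIRON = {123: "E", 162: "E", 165: "H", 213: "E", 266: "E", 269: "H"}
DIMER_CORE = {138: "H", 142: "L", 143: "R", 163: "R", 166: "L", 187: "Q"}
DIMER_HIGH = {131: "M", 135: "M", 139: "L", 141: "S", 145: "M", 147: "R",
              148: "D", 156: "L", 159: "A", 167: "M", 180: "R", 183: "I"}
CAVITY_ORDER = [91, 94, 95, 97, 98, 99, 102, 117, 118, 121, 122, 125, 126,
                128, 178, 179, 181, 182, 185, 186, 189, 190, 193, 194, 197,
                198, 200, 201, 204, 205, 208, 209, 212]
CAVITY_REF = dict(zip(CAVITY_ORDER, "STCWLFFSRFLVAVPLVSITIMFLAYISFVFVL"))

# per-clade residue rows over the cavity / dimer-high positions
CAVITY_ROWS = {
    "AOX1a": "TSLFPTFCRMLVAVYEALAVVFAYGYISFAVVL",
    "AOX1c": "TSLVPTFCRMLVAVYEALAVVFAYGYVSFAVVL",
    "AOX1e": "TAIWPTFCRMLVAVYEALVVVFAYTYASVAMVL",
    "AOX1d": "VSLVPRFSHLLVAVWEALAAVFAYGYISFAFVL",
}
DIMER_HIGH_ORDER = [131, 135, 139, 141, 145, 147, 148, 156, 159, 167, 180, 183]
DIMER_HIGH_ROWS = {
    "AOX1a": "MMLSFQSLAMRV",
    "AOX1c": "MMLSFQSLAMRV",
    "AOX1e": "MALSFQSLAMRV",
    "AOX1d": "MVLSFHSMAMRV",
}

# signature motifs planted in the clade backbones (1-based start positions)
MOTIFS = [("LETVAA", 40), ("ERMHLMT", 70), ("LEEEA", 218), ("RADEAHH", 276)]

# diagnostic residues shared by every backbone (all clades are Type 1)
TYPE1 = {112: "E", 124: "L", 229: "T", 233: "R", 241: "D"}
SUBTYPE = {
    "ace": {167: "M", 175: "E", 178: "Y", 180: "R", 181: "A", 295: "K"},
    "d": {167: "M", 175: "D", 178: "W", 180: "R", 181: "A", 295: "R"},
}


def _apply(seq: list[str], plants: dict[int, str]) -> None:
    for pos, letter in plants.items():
        seq[pos - 1] = letter


def build() -> tuple[str, dict[str, str]]:
    rng = random.Random(SEED)
    background = [rng.choice(AMINO_ACIDS) for _ in range(LENGTH)]

    tbaox = background.copy()
    for plants in (DIIRON, DIMER_CORE, DIMER_HIGH, CAVITY_REF):
        _apply(tbaox, plants)

    used = set(DIIRON) | set(DIMER_CORE) | set(DIMER_HIGH) | set(CAVITY_REF)
    used |= set(TYPE1) | {167, 175, 178, 180, 181, 295}
    for pattern, start in MOTIFS:
        used |= set(range(start, start + len(pattern)))
    free = sorted(set(range(1, LENGTH + 1)) - used)

    clades = {}
    for i, clade in enumerate(["AOX1a", "AOX1c", "AOX1e", "AOX1d"]):
        seq = background.copy()
        _apply(seq, DIIRON)
        _apply(seq, DIMER_CORE)
        _apply(seq, dict(zip(DIMER_HIGH_ORDER, DIMER_HIGH_ROWS[clade])))
        _apply(seq, dict(zip(CAVITY_ORDER, CAVITY_ROWS[clade])))
        _apply(seq, TYPE1)
        _apply(seq, SUBTYPE["d" if clade == "AOX1d" else "ace"])
        for pattern, start in MOTIFS:
            _apply(seq, {start + j: aa for j, aa in enumerate(pattern)})
        # clade-specific separation: 12 extra substitutions on a disjoint slice
        for pos in free[i::4][:12]:
            current = seq[pos - 1]
            choices = [a for a in AMINO_ACIDS if a != current]
            seq[pos - 1] = choices[(pos + i) % len(choices)]
        clades[clade] = "".join(seq)
    return "".join(tbaox), clades


def write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def main() -> None:
    data_dir = Path(__file__).resolve().parents[1] / "src" / "aoxkit" / "data"
    tbaox, clades = build()
    write_fasta(data_dir / "tbaox_reference.fasta", {"TbAOX_standin": tbaox})
    write_fasta(data_dir / "clade_references.fasta", clades)
    print(f"wrote reference data to {data_dir}")


if __name__ == "__main__":
    main()
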