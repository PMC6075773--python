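"""Catalog configuration: signature motifs, diagnostic residue scheme,
reference position lists, regulator motifs and side-chain chemistry classes.

Catalog values live in an editable YAML data file rather than code.  The
shipped defaults are transcriptions / stand-ins documented in the data file
itself; users can point every consumer at their own catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from aoxkit.core import AoxkitError, read_fasta

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

CHEMISTRY_CLASSES = ("hydrophobic", "polar", "cyclic", "glycine")


@dataclass(frozen=True)
class SignatureMotif:
    name: str
    pattern: str
    # 1-based offsets within the pattern that must be preserved in a variant hit
    catalytic: tuple[int, ...]


@dataclass(frozen=True)
class DiagnosticScheme:
    reference_id: str
    reference_seq: str
    type_positions: tuple[int, ...]
    subtype_positions: tuple[int, ...]
    # class -> {position -> allowed residue letters}
    type_allowed: dict[str, dict[int, frozenset[str]]]
    subtype_allowed: dict[str, dict[int, frozenset[str]]]


@dataclass(frozen=True)
class RegulatorMotif:
    name: str
    pattern: str
    positive: bool
    categories: tuple[str, ...]


@dataclass
class CatalogBundle:
    signature_motifs: list[SignatureMotif]
    diagnostic_scheme: DiagnosticScheme
    # domain -> {tbaox position -> reference residue letter}
    tbaox_positions: dict[str, dict[int, str]]
    tbaox_seq: str
    regulator_motifs: list[RegulatorMotif]
    chemistry_map: dict[str, str]
    clade_references: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def motif(self, name: str) -> SignatureMotif:
        for m in self.signature_motifs:
            if m.name == name:
                return m
        raise AoxkitError(f"unknown signature motif {name!r}")


def validate_iupac(pattern: str, name: str = "") -> None:
    bad = set(pattern.upper()) - set(IUPAC_SETS)
    if bad:
        label = f" in pattern {name!r}" if name else ""
        raise AoxkitError(f"invalid IUPAC letter(s) {sorted(bad)}{label}: {pattern}")


def default_catalog_path() -> Path:
    return Path(resources.files("aoxkit").joinpath("data/catalogs.yaml"))  # type: ignore[arg-type]


def _positions(raw, context: str) -> dict[int, str]:
    """Parse a position list like ``["H138", "L142"]`` into {pos: letter}."""
    out: dict[int, str] = {}
    prev = 0
    for item in raw:
        letter, pos = str(item)[0], int(str(item)[1:])
        if pos in out:
            raise AoxkitError(f"{context}: position {pos} duplicated")
        if pos <= prev:
            raise AoxkitError(f"{context}: positions must be strictly increasing at {pos}")
        out[pos] = letter
        prev = pos
    return out


def load_catalogs(config_path: str | Path | None = None) -> CatalogBundle:
    """Load and validate a catalog YAML file (the package default if None)."""
    path = Path(config_path) if config_path is not None else default_catalog_path()
    if not path.exists():
        raise AoxkitError(f"catalog file not found: {path}")
    raw = yaml.safe_load(path.read_text())

    names_seen: set[str] = set()

    def unique(name: str) -> str:
        if name in names_seen:
            raise AoxkitError(f"duplicate catalog entry name {name!r}")
        names_seen.add(name)
        return name

    motifs = []
    for m in raw["signature_motifs"]:
        pattern = m["pattern"].upper()
        bad = set(pattern) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise AoxkitError(f"invalid residue letter(s) {sorted(bad)} in motif {m['name']!r}")
        catalytic = tuple(int(i) for i in m.get("catalytic", []))
        if any(i < 1 or i > len(pattern) for i in catalytic):
            raise AoxkitError(f"catalytic offset out of range for motif {m['name']!r}")
        motifs.append(SignatureMotif(unique(m["name"]), pattern, catalytic))

    data_dir = path.parent
    ref_fasta = raw["diagnostic_scheme"]["reference_fasta"]
    ref_records = dict(read_fasta(data_dir / ref_fasta))
    ref_id = raw["diagnostic_scheme"]["reference_id"]
    if ref_id not in ref_records:
        raise AoxkitError(f"diagnostic reference {ref_id!r} not in {ref_fasta}")

    def allowed(section) -> dict[str, dict[int, frozenset[str]]]:
        out: dict[str, dict[int, frozenset[str]]] = {}
        for cls, mapping in section.items():
            out[cls] = {int(p): frozenset(str(v).upper()) for p, v in mapping.items()}
        return out

    scheme = DiagnosticScheme(
        reference_id=ref_id,
        reference_seq=ref_records[ref_id],
        type_positions=tuple(int(p) for p in raw["diagnostic_scheme"]["type_positions"]),
        subtype_positions=tuple(int(p) for p in raw["diagnostic_scheme"]["subtype_positions"]),
        type_allowed=allowed(raw["diagnostic_scheme"]["type_allowed"]),
        subtype_allowed=allowed(raw["diagnostic_scheme"]["subtype_allowed"]),
    )
    for positions, table in (
        (scheme.type_positions, scheme.type_allowed),
        (scheme.subtype_positions, scheme.subtype_allowed),
    ):
        if len(set(positions)) != len(positions) or list(positions) != sorted(positions):
            raise AoxkitError("diagnostic positions must be strictly increasing")
        for cls, mapping in table.items():
            if set(mapping) != set(positions):
                raise AoxkitError(f"diagnostic class {cls!r} does not cover all positions")

    tbaox_positions = {
        unique(domain): _positions(items, f"tbaox_positions.{domain}")
        for domain, items in raw["tbaox_positions"].items()
    }
    tbaox_records = dict(read_fasta(data_dir / raw["tbaox_reference_fasta"]))
    (tbaox_seq,) = tbaox_records.values()
    check_reference_consistency(tbaox_seq, tbaox_positions)

    regulators = []
    for r in raw["regulator_motifs"]:
        pattern = r["pattern"].upper()
        validate_iupac(pattern, r["name"])
        regulators.append(
            RegulatorMotif(
                unique(r["name"]), pattern, bool(r.get("positive", True)),
                tuple(r.get("categories", [])),
            )
        )

    chemistry = {str(k).upper(): str(v) for k, v in raw["chemistry_map"].items()}
    bad_classes = set(chemistry.values()) - set(CHEMISTRY_CLASSES)
    if bad_classes:
        raise AoxkitError(f"unknown chemistry classes {sorted(bad_classes)}")

    clade_refs: dict[str, str] = {}
    if "clade_reference_fasta" in raw:
        for name, seq in read_fasta(data_dir / raw["clade_reference_fasta"]):
            clade_refs[name] = seq

    return CatalogBundle(
        signature_motifs=motifs,
        diagnostic_scheme=scheme,
        tbaox_positions=tbaox_positions,
        tbaox_seq=tbaox_seq,
        regulator_motifs=regulators,
        chemistry_map=chemistry,
        clade_references=clade_refs,
        source=str(path),
    )


def check_reference_consistency(seq: str, tbaox_positions: dict[str, dict[int, str]]) -> None:
    """Any reference replacement must carry the catalog residue letters at the
    catalog positions; this is the only validation applied to a user-supplied
    reference."""
    for domain, positions in tbaox_positions.items():
        for pos, letter in positions.items():
            if pos > len(seq):
                raise AoxkitError(
                    f"reference too short for {domain} position {pos} (length {len(seq)})"
                )
            if seq[pos - 1] != letter:
                raise AoxkitError(
                    f"reference residue mismatch at {domain} position {pos}: "
                    f"expected {letter}, found {seq[pos - 1]}"
                )
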