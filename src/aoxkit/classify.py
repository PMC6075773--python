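"""Isoform classification: signature-motif scanning, diagnostic-residue typing
against the classification reference, clade assignment by nearest reference,
and the systematic naming grammar.

Naming grammar (reproduced from the family's published conventions)::

    [put.][reg|ne.]<species>AOX[1a|1c|1e|1d|•][-like][-<arm>][.<paralog>][.sv<k>]

Examples: ``TaAOX1a-2BL``, ``put.TaAOX1d-like-4AS``, ``regTaAOX-4BL.sv1``,
``ne.TaAOX•-2AL``, ``TuAOX1d.1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from aoxkit.core import AoxkitError, IsoformRecord
from aoxkit.catalogs import CatalogBundle, SignatureMotif
from aoxkit.residues import global_align, map_to_reference

BULLET = "•"
CLADE_CORES = ("AOX1a", "AOX1c", "AOX1e", "AOX1d")
SPECIES_CODES = ("Ta", "Tu", "Aet", "Aes")


# ---------------------------------------------------------------------------
# signature motifs
# ---------------------------------------------------------------------------

@dataclass
class MotifPresence:
    motif_name: str
    status: str                  # present | variant | absent
    position: int | None = None  # 1-based protein offset of the hit
    matched_text: str | None = None


def _variant_hit(window: str, motif: SignatureMotif) -> bool:
    """True when the window differs from the pattern at exactly one position
    and every catalytic-flagged position is preserved."""
    diffs = [i for i, (a, b) in enumerate(zip(window, motif.pattern), 1) if a != b]
    return len(diffs) == 1 and diffs[0] not in motif.catalytic


def scan_signature_motifs(
    protein_seq: str, catalogs: CatalogBundle, strict: bool = False
) -> list[MotifPresence]:
    """Scan for the four signature motifs; leftmost hit per motif.

    Exact hit -> ``present``.  One substitution that preserves the
    catalytic-flagged residues -> ``variant`` (disabled by ``strict``).
    """
    seq = protein_seq.upper()
    if not seq:
        raise AoxkitError("scan_signature_motifs requires a non-empty sequence")
    out = []
    for motif in catalogs.signature_motifs:
        idx = seq.find(motif.pattern)
        if idx >= 0:
            out.append(MotifPresence(motif.name, "present", idx + 1, motif.pattern))
            continue
        hit = None
        if not strict:
            for i in range(len(seq) - len(motif.pattern) + 1):
                window = seq[i : i + len(motif.pattern)]
                if _variant_hit(window, motif):
                    hit = MotifPresence(motif.name, "variant", i + 1, window)
                    break
        out.append(hit or MotifPresence(motif.name, "absent"))
    return out


# ---------------------------------------------------------------------------
# diagnostic residue typing
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticTyping:
    residues: dict[int, str | None]   # scheme position -> observed residue or None
    type_call: str                    # Type1 | Type2 | mixed | unresolved
    subtype_call: str                 # ace | d | mixed | unresolved


def _call(observed: dict[int, str | None],
          allowed: dict[str, dict[int, frozenset[str]]]) -> str:
    present = {p: r for p, r in observed.items() if r is not None}
    if len(present) * 2 < len(observed):
        return "unresolved"
    qualifying = [
        cls for cls, sets in allowed.items()
        if all(r in sets[p] for p, r in present.items())
    ]
    if len(qualifying) == 1:
        return qualifying[0]
    if len(qualifying) > 1:
        return "unresolved"  # residues do not discriminate between classes
    return "mixed"


def type_diagnostic_residues(
    protein_seq: str, catalogs: CatalogBundle
) -> DiagnosticTyping:
    """Read the diagnostic residues off the query at the columns aligned to the
    scheme positions of the classification reference, then call type/subtype."""
    scheme = catalogs.diagnostic_scheme
    if max(scheme.type_positions + scheme.subtype_positions) > len(scheme.reference_seq):
        raise AoxkitError("diagnostic scheme positions exceed reference length")
    rmap = map_to_reference(protein_seq, scheme.reference_seq)
    lookup = dict(rmap.pairs)
    observed: dict[int, str | None] = {}
    for pos in scheme.type_positions + scheme.subtype_positions:
        iso_pos = lookup.get(pos)
        observed[pos] = protein_seq[iso_pos - 1].upper() if iso_pos else None
    type_obs = {p: observed[p] for p in scheme.type_positions}
    subtype_obs = {p: observed[p] for p in scheme.subtype_positions}
    return DiagnosticTyping(
        residues=observed,
        type_call=_call(type_obs, scheme.type_allowed),
        subtype_call=_call(subtype_obs, scheme.subtype_allowed),
    )


# ---------------------------------------------------------------------------
# clade assignment
# ---------------------------------------------------------------------------

@dataclass
class CladeCall:
    clade: str
    rule: str
    identities: dict[str, float] = field(default_factory=dict)


def assign_clade(
    protein_seq: str,
    catalogs: CatalogBundle,
    identity_floor: float = 25.0,
) -> CladeCall:
    """Assign a clade from diagnostic typing plus nearest-reference identity.

    A decisive subtype call restricts the candidate clades to its family
    (a/c/e vs d); the winner within the family, and all ties, are resolved by
    highest global-alignment percent identity to the bundled references.
    """
    identities = {
        clade: global_align(protein_seq, ref).identity
        for clade, ref in catalogs.clade_references.items()
    }
    typing = type_diagnostic_residues(protein_seq, catalogs)
    if typing.subtype_call == "d":
        candidates = ["AOX1d"]
        rule = "subtype_d"
    elif typing.subtype_call == "ace":
        candidates = ["AOX1a", "AOX1c", "AOX1e"]
        rule = "subtype_ace+identity"
    else:
        candidates = list(identities)
        rule = f"identity_only({typing.subtype_call})"
    best = max(candidates, key=lambda c: identities[c])
    if identities[best] < identity_floor:
        return CladeCall("unknown", f"below_floor({identities[best]:.1f}%)", identities)
    return CladeCall(best, rule, identities)


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NameParts:
    species_code: str
    core: str                      # clade label, or "AOX" for reg, or "AOX•"
    put: bool = False
    reg: bool = False
    ne: bool = False
    like_suffix: bool = False
    location: str | None = None    # chromosome arm, e.g. "2AL"
    paralog_index: int | None = None
    sv_index: int | None = None


def _validate_parts(parts: NameParts) -> None:
    if parts.species_code not in SPECIES_CODES:
        raise AoxkitError(f"unknown species code {parts.species_code!r}")
    if parts.reg and parts.ne:
        raise AoxkitError("a name cannot be both reg and ne")
    if parts.reg:
        if parts.core != "AOX":
            raise AoxkitError("reg names take the bare core 'AOX', no clade")
        if parts.like_suffix:
            raise AoxkitError("reg names cannot carry the -like suffix")
    elif parts.core == "AOX" + BULLET:
        pass  # placeholder core: ne names or unresolved clades
    elif parts.core not in CLADE_CORES:
        raise AoxkitError(f"invalid name core {parts.core!r}")
    if parts.sv_index is not None and parts.sv_index < 1:
        raise AoxkitError("sv_index must be >= 1")


def assign_name(parts: NameParts) -> str:
    """Deterministic concatenation of the naming grammar."""
    _validate_parts(parts)
    bits = []
    if parts.put:
        bits.append("put.")
    if parts.reg:
        bits.append("reg")
    if parts.ne:
        bits.append("ne.")
    bits.append(parts.species_code)
    bits.append(parts.core)
    if parts.like_suffix:
        bits.append("-like")
    if parts.location:
        bits.append(f"-{parts.location}")
    if parts.paralog_index is not None:
        bits.append(f".{parts.paralog_index}")
    if parts.sv_index is not None:
        bits.append(f".sv{parts.sv_index}")
    return "".join(bits)


_NAME_RE = re.compile(
    r"^(?P<put>put\.)?(?P<reg>reg)?(?P<ne>ne\.)?"
    r"(?P<species>Ta|Tu|Aet|Aes)"
    r"(?P<core>AOX(?:1[aced]|•)?)"
    r"(?P<like>-like)?"
    r"(?:-(?P<location>\d[A-D][SL]?|\d[A-D]?))?"
    r"(?:\.(?P<paralog>\d+))?"
    r"(?:\.sv(?P<sv>\d+))?$"
)


def parse_name(name: str) -> NameParts:
    """Inverse of :func:`assign_name` (round-trip tested)."""
    m = _NAME_RE.match(name)
    if not m:
        raise AoxkitError(f"cannot parse name {name!r}")
    parts = NameParts(
        species_code=m.group("species"),
        core=m.group("core"),
        put=bool(m.group("put")),
        reg=bool(m.group("reg")),
        ne=bool(m.group("ne")),
        like_suffix=bool(m.group("like")),
        location=m.group("location"),
        paralog_index=int(m.group("paralog")) if m.group("paralog") else None,
        sv_index=int(m.group("sv")) if m.group("sv") else None,
    )
    _validate_parts(parts)
    return parts


# ---------------------------------------------------------------------------
# family-level protocol
# ---------------------------------------------------------------------------

@dataclass
class IsoformInput:
    isoform_id: str
    protein_seq: str
    source_gene: str
    confidence: str                 # high | low | non_expressed
    species_code: str = "Ta"
    location: str | None = None     # chromosome arm, from input metadata
    paralog_index: int | None = None
    sv_index: int | None = None


def classify_family(
    isoforms: list[IsoformInput],
    catalogs: CatalogBundle,
    strict_motifs: bool = False,
) -> list[IsoformRecord]:
    """Apply the full classification protocol to a family.

    Order of rules: motif scan; all four present/variant on a high-confidence
    isoform -> full family name; >=1 absent -> "-like"; all absent -> "reg";
    low confidence adds "put."; non-expressed adds "ne." plus the placeholder
    core when the clade is unresolved.  Clades come from
    :func:`assign_clade`; chromosome arms and paralog indices are taken from
    input metadata, never inferred.
    """
    records = []
    for iso in isoforms:
        presences = scan_signature_motifs(iso.protein_seq, catalogs, strict=strict_motifs)
        statuses = [p.status for p in presences]
        n_absent = sum(1 for s in statuses if s == "absent")
        all_absent = n_absent == len(statuses)

        call = assign_clade(iso.protein_seq, catalogs)
        clade = call.clade

        reg = all_absent
        like = (not all_absent) and n_absent >= 1
        ne = iso.confidence == "non_expressed"
        put = iso.confidence == "low" and not ne

        if reg:
            core = "AOX"
        elif clade == "unknown":
            core = "AOX" + BULLET  # placeholder pending resolution
        else:
            core = clade

        parts = NameParts(
            species_code=iso.species_code,
            core=core,
            put=put,
            reg=reg,
            ne=ne,
            like_suffix=like,
            location=iso.location,
            paralog_index=iso.paralog_index,
            sv_index=iso.sv_index,
        )
        records.append(
            IsoformRecord(
                isoform_id=iso.isoform_id,
                protein_seq=iso.protein_seq,
                source_gene=iso.source_gene,
                clade=clade,
                motif_presence=statuses,
                name=assign_name(parts),
                rule=call.rule,
            )
        )
    return records
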