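"""Global protein alignment, residue-numbering transfer onto the structural
reference, domain profiles and conservation/chemistry summaries.

Scoring convention (documented because the source tooling leaves it open):
BLOSUM62, affine gaps where a run of L gap columns costs
``gap_open + L * gap_extend`` with defaults 10 / 0.5, end gaps penalised.
Percent identity = identical columns / total alignment columns (gaps count in
the denominator), reported to 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from aoxkit.core import AoxkitError
from aoxkit.catalogs import CatalogBundle

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DOMAINS = ("diiron", "dimer_core", "dimer_high", "cavity")


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # percent, one decimal


@dataclass
class ResidueMap:
    isoform_id: str
    pairs: list[tuple[int, int | None]]  # (reference position, isoform position or None)
    alignment_identity: float
    low_identity: bool = False

    def isoform_position(self, ref_pos: int) -> int | None:
        for rp, ip in self.pairs:
            if rp == ref_pos:
                return ip
        raise AoxkitError(f"reference position {ref_pos} not in map")


@dataclass
class DomainProfile:
    isoform_id: str
    domain: str
    residues: dict[int, str]       # reference position -> residue letter or "-"
    chemistry: dict[int, str]      # reference position -> chemistry class or "-"


@dataclass
class ConservationSummary:
    domain: str
    identical_positions: list[int]
    uniform_substitutions: list[tuple[int, str]]
    mixed_positions: list[int]
    excluded_isoforms: list[str] = field(default_factory=list)


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # biopython charges open_gap_score for the first gap column; fold the
    # per-column extend cost in so a run of L columns costs open + L * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment of two protein sequences."""
    if not seq_a or not seq_b:
        raise AoxkitError("global_align requires two non-empty sequences")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    identity = round(100.0 * matches / len(a_row), 1)
    return AlignmentResult(a_row, b_row, float(alignment.score), identity)


def map_to_reference(
    isoform_seq: str,
    reference_seq: str,
    isoform_id: str = "",
    identity_floor: float = 20.0,
    **align_kwargs,
) -> ResidueMap:
    """Transfer reference numbering onto an isoform via global alignment.

    Reference positions aligned to gap columns map to ``None``.  Identity
    below ``identity_floor`` flags the map but still emits it.
    """
    result = global_align(reference_seq, isoform_seq, **align_kwargs)
    pairs: list[tuple[int, int | None]] = []
    ref_pos = 0
    iso_pos = 0
    for r, i in zip(result.aligned_a, result.aligned_b):
        if r != "-" and i != "-":
            ref_pos += 1
            iso_pos += 1
            pairs.append((ref_pos, iso_pos))
        elif r != "-":
            ref_pos += 1
            pairs.append((ref_pos, None))
        else:
            iso_pos += 1
    return ResidueMap(
        isoform_id=isoform_id,
        pairs=pairs,
        alignment_identity=result.identity,
        low_identity=result.identity < identity_floor,
    )


def extract_domain_profile(
    residue_map: ResidueMap,
    isoform_seq: str,
    catalogs: CatalogBundle,
    domain: str,
) -> DomainProfile:
    """Read the isoform residues at a domain's reference positions.

    Unaligned reference positions give ``"-"`` cells, mirroring the dash
    convention of the published comparison tables.
    """
    if domain not in catalogs.tbaox_positions:
        raise AoxkitError(
            f"unknown domain {domain!r}; expected one of "
            f"{sorted(catalogs.tbaox_positions)}"
        )
    residues: dict[int, str] = {}
    chemistry: dict[int, str] = {}
    lookup = dict(residue_map.pairs)
    for pos in catalogs.tbaox_positions[domain]:
        iso_pos = lookup.get(pos)
        if iso_pos is None:
            residues[pos] = "-"
            chemistry[pos] = "-"
        else:
            letter = isoform_seq[iso_pos - 1].upper()
            residues[pos] = letter
            chemistry[pos] = catalogs.chemistry_map.get(letter, "-")
    return DomainProfile(
        isoform_id=residue_map.isoform_id, domain=domain,
        residues=residues, chemistry=chemistry,
    )


def conservation_summary(
    profiles: list[DomainProfile],
    reference_residues: dict[int, str],
    exclude: list[str] | None = None,
) -> ConservationSummary:
    """Partition a domain's positions into identical / uniformly substituted /
    mixed, relative to the reference residues.

    ``exclude`` drops isoforms from the tally (used to mirror the published
    counts which omit the truncated "-like" isoforms).  Gap cells ("-") do not
    participate: a position is identical or uniformly substituted based on the
    non-gap residues of the included isoforms; positions where every included
    isoform is a gap are counted as mixed.
    """
    exclude = exclude or []
    included = [p for p in profiles if p.isoform_id not in exclude]
    if not included:
        raise AoxkitError("no profiles left after exclusion")
    domain = included[0].domain
    if any(p.domain != domain for p in included):
        raise AoxkitError("profiles span multiple domains")

    identical: list[int] = []
    uniform: list[tuple[int, str]] = []
    mixed: list[int] = []
    for pos, ref_letter in reference_residues.items():
        letters = {p.residues[pos] for p in included} - {"-"}
        if letters == {ref_letter}:
            identical.append(pos)
        elif len(letters) == 1:
            uniform.append((pos, next(iter(letters))))
        else:
            mixed.append(pos)
    return ConservationSummary(
        domain=domain,
        identical_positions=identical,
        uniform_substitutions=uniform,
        mixed_positions=mixed,
        excluded_isoforms=list(exclude),
    )


def chemistry_ratios(profile: DomainProfile, chemistry_map: dict[str, str]) -> dict:
    """Counts and ratios of side-chain chemistry classes over non-gap cells."""
    counts = {"hydrophobic": 0, "polar": 0, "cyclic": 0, "glycine": 0}
    gaps = 0
    for pos, letter in profile.residues.items():
        if letter == "-":
            gaps += 1
            continue
        if letter not in chemistry_map:
            raise AoxkitError(f"residue {letter!r} missing from chemistry map")
        counts[chemistry_map[letter]] += 1
    total = sum(counts.values())
    ratios = (
        {k: v / total for k, v in counts.items()} if total else None
    )
    return {
        "isoform_id": profile.isoform_id,
        "domain": profile.domain,
        "counts": counts,
        "gaps": gaps,
        "ratios": ratios,
        "undefined": total == 0,
    }
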