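"""Shared data model, coordinate conventions and flat-file readers/writers.

All public coordinates are 1-based inclusive.  Internally, half-open 0-based
slices are used wherever Python slicing is involved; the converters
:func:`to_public` / :func:`from_public` are the only sanctioned boundary
crossings and are covered by round-trip tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class AoxkitError(Exception):
    """Base class for user-facing errors."""


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_public(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if end0 < start0:
        raise ValueError(f"empty or inverted interval [{start0}, {end0})")
    return start0 + 1, end0


def from_public(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid 1-based inclusive interval ({start1}..{end1})")
    return start1 - 1, end1


def format_span(start1: int, end1: int) -> str:
    """Render a 1-based inclusive interval in report style, e.g. ``(51..1249)``."""
    return f"({start1}..{end1})"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """One transcript of a gene.

    ``exons`` are 1-based inclusive intervals on the genomic sequence, sorted
    and non-overlapping.  ``cds_span`` is 1-based inclusive within the spliced
    transcript.
    """

    transcript_id: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None
    sv_index: int | None = None

    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def validate(self, genomic_length: int) -> None:
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise AoxkitError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({s}..{e})"
                )
            if s < 1 or e > genomic_length:
                raise AoxkitError(
                    f"{self.transcript_id}: exon ({s}..{e}) outside genomic bounds"
                )
            prev_end = e
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if cs < 1 or ce > self.transcript_length():
                raise AoxkitError(
                    f"{self.transcript_id}: cds_span ({cs}..{ce}) outside transcript"
                )
        if self.sv_index is not None and self.sv_index < 1:
            raise AoxkitError(f"{self.transcript_id}: sv_index must be >= 1")


CONFIDENCE_TIERS = ("high", "low", "non_expressed")


@dataclass
class GeneModel:
    """A gene: genomic sequence, promoter, transcripts and a confidence tier."""

    gene_id: str
    genomic_seq: str
    promoter_seq: str = ""
    chromosome_arm: str | None = None
    transcripts: list[TranscriptModel] = field(default_factory=list)
    confidence: str = "high"

    def __post_init__(self) -> None:
        self.genomic_seq = self.genomic_seq.upper()
        self.promoter_seq = self.promoter_seq.upper()
        for name, seq in (("genomic", self.genomic_seq), ("promoter", self.promoter_seq)):
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise AoxkitError(
                    f"{self.gene_id}: non-IUPAC letters {sorted(bad)} in {name} sequence"
                )
        if len(self.promoter_seq) > 1500:
            raise AoxkitError(f"{self.gene_id}: promoter longer than 1500 bp")
        if self.confidence not in CONFIDENCE_TIERS:
            raise AoxkitError(f"{self.gene_id}: unknown confidence {self.confidence!r}")
        for t in self.transcripts:
            t.validate(len(self.genomic_seq))

    def spliced(self, transcript: TranscriptModel) -> str:
        parts = []
        for s1, e1 in transcript.exons:
            s0, e0 = from_public(s1, e1)
            parts.append(self.genomic_seq[s0:e0])
        return "".join(parts)


MOTIF_STATUSES = ("present", "variant", "absent")
CLADES = ("AOX1a", "AOX1c", "AOX1e", "AOX1d", "unknown")


@dataclass
class IsoformRecord:
    """A classified protein isoform."""

    isoform_id: str
    protein_seq: str
    source_gene: str
    clade: str = "unknown"
    motif_presence: list[str] = field(default_factory=list)
    name: str = ""
    rule: str = ""

    def __post_init__(self) -> None:
        self.protein_seq = self.protein_seq.upper().rstrip("*")
        bad = set(self.protein_seq) - AMINO_ACIDS - {"X"}
        if bad:
            raise AoxkitError(
                f"{self.isoform_id}: unexpected residue letters {sorted(bad)}"
            )
        if self.clade not in CLADES:
            raise AoxkitError(f"{self.isoform_id}: unknown clade {self.clade!r}")
        if self.motif_presence and len(self.motif_presence) != 4:
            raise AoxkitError(f"{self.isoform_id}: motif_presence must have 4 entries")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str | None = None) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased.  With ``alphabet="dna"``, U is mapped to T.
    Duplicate ids and empty records are errors.
    """
    path = Path(path)
    if not path.exists():
        raise AoxkitError(f"FASTA file not found: {path}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise AoxkitError(f"empty record {rec.id!r} in {path}")
        if rec.id in seen:
            raise AoxkitError(f"duplicate id {rec.id!r} in {path}")
        if alphabet == "dna":
            seq = seq.replace("U", "T")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise AoxkitError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in recs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(results: Sequence[dict], path: str | Path, format: str = "tsv",
                 columns: Sequence[str] | None = None) -> Path:
    """Write a list of flat dict rows as TSV or JSON with deterministic columns.

    Column order is ``columns`` if given, else the key order of the first row.
    Interval values supplied as ``(start, end)`` tuples are rendered
    ``(start..end)``.
    """
    if format not in ("tsv", "json"):
        raise AoxkitError(f"unsupported report format {format!r}")
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - OS dependent
        raise AoxkitError(f"cannot create directory for {path}: {exc}") from exc

    if columns is None:
        columns = list(results[0].keys()) if results else []

    def render(value):
        if isinstance(value, tuple) and len(value) == 2 and all(
            isinstance(v, int) for v in value
        ):
            return format_span(*value)
        if isinstance(value, float):
            return repr(value)
        return str(value)

    try:
        if format == "tsv":
            with open(path, "w") as fh:
                fh.write("\t".join(columns) + "\n")
                for row in results:
                    fh.write("\t".join(render(row.get(c, "")) for c in columns) + "\n")
        else:
            payload = [
                {c: render(row.get(c, "")) for c in columns} for row in results
            ]
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=False)
                fh.write("\n")
    except OSError as exc:
        raise AoxkitError(f"cannot write report to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive per GFF3."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["##gff-version 3"]
    for gene in genes:
        glen = len(gene.genomic_seq)
        lines.append(
            "\t".join(
                [gene.gene_id, "aoxkit", "gene", "1", str(glen), ".", "+", ".",
                 f"ID={gene.gene_id}"]
            )
        )
        for t in gene.transcripts:
            t_start = t.exons[0][0] if t.exons else 1
            t_end = t.exons[-1][1] if t.exons else glen
            lines.append(
                "\t".join(
                    [gene.gene_id, "aoxkit", "mRNA", str(t_start), str(t_end), ".",
                     "+", ".", f"ID={t.transcript_id};Parent={gene.gene_id}"]
                )
            )
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    "\t".join(
                        [gene.gene_id, "aoxkit", "exon", str(s), str(e), ".", "+",
                         ".", f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]
                    )
                )
            if t.cds_span is not None:
                for i, (s, e) in enumerate(_cds_genomic_intervals(t), 1):
                    lines.append(
                        "\t".join(
                            [gene.gene_id, "aoxkit", "CDS", str(s), str(e), ".",
                             "+", "0",
                             f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"]
                        )
                    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def read_gff3(path: str | Path) -> dict[str, list[TranscriptModel]]:
    """Read back transcripts written by :func:`write_gff3` (exons only)."""
    transcripts: dict[str, TranscriptModel] = {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _, ftype, start, end, _, _, _, attrs = line.split("\t")
        fields = dict(kv.split("=", 1) for kv in attrs.split(";"))
        if ftype == "mRNA":
            t = TranscriptModel(transcript_id=fields["ID"], exons=[])
            transcripts[fields["ID"]] = t
            by_gene.setdefault(fields["Parent"], []).append(t)
        elif ftype == "exon":
            transcripts[fields["Parent"]].exons.append((int(start), int(end)))
    return by_gene


def _cds_genomic_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    """Project the transcript-space cds_span back onto genomic exon intervals."""
    cs, ce = t.cds_span  # type: ignore[misc]
    out = []
    offset = 0  # transcript bases consumed so far
    for s, e in t.exons:
        exon_len = e - s + 1
        lo = max(cs, offset + 1)
        hi = min(ce, offset + exon_len)
        if lo <= hi:
            out.append((s + (lo - offset - 1), s + (hi - offset - 1)))
        offset += exon_len
    return out
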