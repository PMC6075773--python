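"""Synthetic gene families with known ground truth.

Every pipeline stage is testable offline against the generator's
TruthManifest: planted exon/intron coordinates, splice-variant events, clades,
motif knockouts, promoter motif loci and counts, CpG blocks and expression
fold changes.  Regenerating with the same seed reproduces bytes exactly.

Promoter motif counts are audited post hoc: after planting, the promoter is
re-scanned so the manifest separates planted loci from background chance hits
and records the honest total.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from aoxkit.core import AoxkitError, write_fasta
from aoxkit.catalogs import CatalogBundle, IUPAC_SETS, load_catalogs
from aoxkit.promoter import scan_iupac

STANDARD_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}
STOP_CODON = "TAA"

DEFAULT_FAMILY_CONFIG: dict = {
    "clade_counts": {"AOX1a": 3, "AOX1c": 2, "AOX1e": 1, "AOX1d": 2},
    # intron-count choices per clade (AOX1d intronless or single-intron)
    "intron_choices": {
        "AOX1a": [3], "AOX1c": [3, 4], "AOX1e": [3], "AOX1d": [0, 1],
    },
    "intron_length": [60, 160],
    "min_exon": 40,
    "flank_length": 120,
    "promoter_length": 1500,
    "promoter_gc": 0.45,
    # per-family plan: motif name -> copies planted in each promoter
    "promoter_motifs": {"MDM_stringent": 2},
    # genes (by index) that get a CpG block planted into an intron
    "cpg_block_length": 340,
    "cpg_genes": 1,
    # isoform knockout plan: list of (gene_index, [motif names to disable])
    "knockouts": [],
    # genes (by index, must have >= 1 intron) that get splice variants
    "splice_variants": 1,
    "low_confidence": [],       # gene indices given the low-confidence tier
    "species_code": "Ta",
}


@dataclass
class SimVariant:
    transcript_id: str
    transcript_seq: str
    exons: list[tuple[int, int]]
    event_type: str | None = None   # planted difference vs the wildtype


@dataclass
class SimGene:
    gene_id: str
    clade: str
    confidence: str
    location: str
    protein_seq: str
    cds_seq: str
    genomic_seq: str
    promoter_seq: str
    exons: list[tuple[int, int]]            # wildtype, 1-based inclusive
    introns: list[tuple[int, int]]
    splice_dinucleotides: list[tuple[str, str]]
    variants: list[SimVariant] = field(default_factory=list)
    knockouts: list[str] = field(default_factory=list)
    planted_motifs: dict[str, list[int]] = field(default_factory=dict)
    audited_motif_counts: dict[str, int] = field(default_factory=dict)
    cpg_block: tuple[int, int] | None = None


@dataclass
class TruthManifest:
    seed: int
    genes: list[SimGene]

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "genes": [asdict(g) for g in self.genes]}
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _random_dna(rng: random.Random, length: int, gc: float) -> str:
    bases = []
    for _ in range(length):
        if rng.random() < gc:
            bases.append(rng.choice("GC"))
        else:
            bases.append(rng.choice("AT"))
    return "".join(bases)


def _back_translate(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(STANDARD_CODONS[aa]) for aa in protein) + STOP_CODON


def _knockout(protein: str, motif, rng: random.Random) -> str:
    """Disable a planted motif: two substitutions, one at a catalytic offset."""
    idx = protein.find(motif.pattern)
    if idx < 0:
        raise AoxkitError(f"motif {motif.name} not present; cannot knock out")
    window = list(motif.pattern)
    cat = motif.catalytic[0] - 1
    window[cat] = "G" if window[cat] != "G" else "P"
    other = next(i for i in range(len(window)) if i != cat)
    window[other] = "P" if window[other] != "P" else "G"
    return protein[:idx] + "".join(window) + protein[idx + len(window):]


def _concretize(rng: random.Random, pattern: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[p])) for p in pattern.upper())


def _plant_motifs(
    rng: random.Random, promoter: str, plan: dict[str, int],
    catalogs: CatalogBundle,
) -> tuple[str, dict[str, list[int]]]:
    taken: list[tuple[int, int]] = []
    loci: dict[str, list[int]] = {}
    seq = list(promoter)
    for name, copies in plan.items():
        pattern = next(
            (m.pattern for m in catalogs.regulator_motifs if m.name == name), name
        )
        if len(pattern) > len(promoter):
            raise AoxkitError(f"motif {name} longer than the promoter")
        loci[name] = []
        for _ in range(copies):
            for _attempt in range(200):
                start = rng.randrange(0, len(promoter) - len(pattern) + 1)
                span = (start, start + len(pattern))
                if all(span[1] <= s or span[0] >= e for s, e in taken):
                    break
            else:
                raise AoxkitError(f"cannot place {copies} copies of {name} without overlap")
            taken.append(span)
            text = _concretize(rng, pattern)
            seq[span[0]:span[1]] = text
            loci[name].append(start + 1)
    for positions in loci.values():
        positions.sort()
    return "".join(seq), loci


def make_family(
    config: dict | None = None,
    seed: int = 0,
    catalogs: CatalogBundle | None = None,
) -> TruthManifest:
    """Generate a gene family (proteins, CDS, genes, promoters) plus manifest."""
    cfg = dict(DEFAULT_FAMILY_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_FAMILY_CONFIG)
        if unknown:
            raise AoxkitError(f"unknown family config keys {sorted(unknown)}")
        cfg.update(config)
    catalogs = catalogs or load_catalogs()
    rng = random.Random(seed)
    flank = cfg["flank_length"]
    min_exon = cfg["min_exon"]
    knockout_plan = {int(i): list(names) for i, names in cfg["knockouts"]}

    genes: list[SimGene] = []
    index = 0
    for clade in sorted(cfg["clade_counts"]):
        for copy in range(cfg["clade_counts"][clade]):
            gene_id = f"sim{clade}-{copy + 1}"
            protein = catalogs.clade_references[clade]
            knockouts = knockout_plan.get(index, [])
            for motif_name in knockouts:
                protein = _knockout(protein, catalogs.motif(motif_name), rng)
            cds = _back_translate(rng, protein)

            n_introns = rng.choice(cfg["intron_choices"][clade])
            # split points inside the CDS, min_exon apart
            while True:
                points = sorted(
                    rng.sample(range(min_exon, len(cds) - min_exon), n_introns)
                ) if n_introns else []
                if all(b - a >= min_exon for a, b in zip(points, points[1:])):
                    break
            plant_cpg = index < cfg["cpg_genes"] and n_introns > 0
            lo, hi = cfg["intron_length"]
            intron_seqs = []
            for k in range(n_introns):
                core_len = rng.randrange(lo, hi + 1) - 4
                core = _random_dna(rng, core_len, 0.45)
                if plant_cpg and k == 0:
                    core += "CG" * (cfg["cpg_block_length"] // 2)
                intron_seqs.append("GT" + core + "AG")

            pieces = []
            exons: list[tuple[int, int]] = []
            introns: list[tuple[int, int]] = []
            dinucs: list[tuple[str, str]] = []
            cpg_block = None
            pos = flank  # 0-based length assembled so far
            pieces.append(_random_dna(rng, flank, 0.40))
            prev = 0
            for k, point in enumerate(points + [len(cds)]):
                exon_seq = cds[prev:point]
                exons.append((pos + 1, pos + len(exon_seq)))
                pieces.append(exon_seq)
                pos += len(exon_seq)
                if k < len(intron_seqs):
                    iseq = intron_seqs[k]
                    introns.append((pos + 1, pos + len(iseq)))
                    dinucs.append((iseq[:2], iseq[-2:]))
                    if plant_cpg and k == 0:
                        block_len = cfg["cpg_block_length"] // 2 * 2
                        block_end = pos + len(iseq) - 2
                        cpg_block = (block_end - block_len + 1, block_end)
                    pieces.append(iseq)
                    pos += len(iseq)
                prev = point
            pieces.append(_random_dna(rng, flank, 0.40))
            genomic = "".join(pieces)

            variants = [SimVariant(f"{gene_id}.t1", cds, list(exons))]
            if index < cfg["splice_variants"] and n_introns > 0:
                variants.extend(
                    _make_variants(gene_id, genomic, exons, introns, flank)
                )

            promoter = _random_dna(rng, cfg["promoter_length"], cfg["promoter_gc"])
            promoter, loci = _plant_motifs(rng, promoter, cfg["promoter_motifs"], catalogs)
            audited = {}
            for name in loci:
                pattern = next(
                    m.pattern for m in catalogs.regulator_motifs if m.name == name
                )
                audited[name] = len(scan_iupac(promoter, pattern, 0, "+", name))

            genes.append(
                SimGene(
                    gene_id=gene_id,
                    clade=clade,
                    confidence="low" if index in cfg["low_confidence"] else "high",
                    location=f"{(index % 7) + 1}AL",
                    protein_seq=protein,
                    cds_seq=cds,
                    genomic_seq=genomic,
                    promoter_seq=promoter,
                    exons=exons,
                    introns=introns,
                    splice_dinucleotides=dinucs,
                    variants=variants,
                    knockouts=knockouts,
                    planted_motifs=loci,
                    audited_motif_counts=audited,
                    cpg_block=cpg_block,
                )
            )
            index += 1
    return TruthManifest(seed=seed, genes=genes)


def _make_variants(gene_id, genomic, exons, introns, flank):
    """One intron-retention and one alternative-3'UTR variant."""
    out = []
    # retain intron 1
    i_s, i_e = introns[0]
    retained = list(exons)
    merged = (retained[0][0], retained[1][1])
    retained = [merged] + retained[2:]
    seq = "".join(genomic[s - 1 : e] for s, e in retained)
    out.append(SimVariant(f"{gene_id}.t2", seq, retained, "intron_retention"))
    # extend the last exon 40 bp into the 3' flank
    ext = min(40, flank - 2)
    extended = list(exons)
    last_s, last_e = extended[-1]
    extended[-1] = (last_s, last_e + ext)
    seq = "".join(genomic[s - 1 : e] for s, e in extended)
    out.append(SimVariant(f"{gene_id}.t3", seq, extended, "alt_3utr"))
    return out


def write_family(manifest: TruthManifest, outdir: str | Path) -> None:
    """FASTA set (genomic, CDS, promoter, protein) + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(g.gene_id, g.genomic_seq) for g in manifest.genes],
                outdir / "genomic.fasta")
    write_fasta(
        [(v.transcript_id, v.transcript_seq) for g in manifest.genes
         for v in g.variants],
        outdir / "transcripts.fasta",
    )
    write_fasta([(g.gene_id, g.promoter_seq) for g in manifest.genes],
                outdir / "promoters.fasta")
    write_fasta([(f"{g.gene_id}.p1", g.protein_seq) for g in manifest.genes],
                outdir / "proteins.fasta")
    manifest.to_json(outdir / "manifest.json")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def make_expression(config: dict, seed: int = 0):
    """TPM table + pairing + truth.

    config keys: ``genes`` (list or int), ``conditions`` (list; first is the
    control), ``folds`` {(gene, condition): fold}, ``sigma`` (multiplicative
    lognormal noise, expressed as the log2-scale standard deviation), and
    ``baseline``.
    """
    rng = random.Random(seed)
    conditions = list(config.get("conditions", []))
    if not conditions:
        raise AoxkitError("empty condition list")
    genes = config.get("genes", 10)
    if isinstance(genes, int):
        genes = [f"gene{i + 1}" for i in range(genes)]
    sigma = float(config.get("sigma", 0.0))
    baseline = float(config.get("baseline", 10.0))
    folds = {(g, c): float(v) for (g, c), v in dict(config.get("folds", {})).items()}
    if any(v < 0 for v in folds.values()):
        raise AoxkitError("negative fold change")

    rows = {}
    truth = {}
    for g in genes:
        base = baseline
        row = {}
        for c in conditions:
            fold = folds.get((g, c), 1.0)
            noise = 2.0 ** rng.gauss(0.0, sigma) if sigma > 0 else 1.0
            row[c] = base * fold * noise
            truth[(g, c)] = fold
        rows[g] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[conditions]
    control = conditions[0]
    pairs = [(c, control) for c in conditions[1:]]
    return table, pairs, {"folds": truth, "seed": seed, "control": control}
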