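"""Pipeline orchestration: run the analysis stages over a set of input files
and write one report bundle; load the bundled, checksummed table fixtures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from aoxkit import __version__
from aoxkit.core import AoxkitError, read_fasta, write_report
from aoxkit.catalogs import CatalogBundle, load_catalogs
from aoxkit.classify import IsoformInput, classify_family
from aoxkit.expression import export_heatmap_matrix, ratio_matrix, read_tpm_table
from aoxkit.promoter import find_cpg_islands, scan_iupac
from aoxkit.properties import properties_table
from aoxkit.residues import extract_domain_profile, map_to_reference
from aoxkit.structure import delineate_structure, structure_summary

ALL_STAGES = ("structure", "classification", "domains", "promoter", "cpg",
              "properties", "expression")

_KNOWN_KEYS = {
    "genomic_fasta", "transcripts_fasta", "promoters_fasta", "proteins_fasta",
    "tpm_table", "expression_pairs", "catalog", "stages", "strand_convention",
    "pka_set", "cpg", "min_intron", "seed", "meta",
}


@dataclass
class RunConfig:
    genomic_fasta: str | None = None
    transcripts_fasta: str | None = None
    promoters_fasta: str | None = None
    proteins_fasta: str | None = None
    tpm_table: str | None = None
    expression_pairs: list[tuple[str, str]] = field(default_factory=list)
    catalog: str | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    strand_convention: str = "+-"
    pka_set: str = "emboss"
    cpg: dict = field(default_factory=lambda: {"window": 100, "min_len": 200,
                                               "oe_threshold": 0.6,
                                               "gc_threshold": 50.0})
    min_intron: int = 20
    seed: int = 0
    meta: dict = field(default_factory=dict)  # isoform_id -> naming metadata

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise AoxkitError(f"unknown config keys {sorted(unknown)}")
        if "expression_pairs" in raw:
            raw["expression_pairs"] = [tuple(p) for p in raw["expression_pairs"]]
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise AoxkitError(f"unknown stages {sorted(unknown)}")
        for attr in ("genomic_fasta", "transcripts_fasta", "promoters_fasta",
                     "proteins_fasta", "tpm_table", "catalog"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise AoxkitError(f"{attr} does not exist: {value}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the configured stages in order and write the report bundle.

    Stage order: structure -> classification -> domains -> promoter/cpg ->
    properties -> expression.  A stage failure halts the run with a
    stage-scoped error; outputs of earlier stages are preserved on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalogs = load_catalogs(config.catalog)
    log: dict = {
        "version": __version__,
        "parameters": {
            "strand_convention": config.strand_convention,
            "pka_set": config.pka_set,
            "cpg": config.cpg,
            "min_intron": config.min_intron,
            "seed": config.seed,
        },
        "catalog_checksum": _checksum(Path(catalogs.source)),
        "stages_run": [],
        "outputs": {},
    }

    def stage(name: str) -> bool:
        return name in config.stages

    try:
        structures = []
        if stage("structure") and config.genomic_fasta and config.transcripts_fasta:
            genomic = dict(read_fasta(config.genomic_fasta, alphabet="dna"))
            for tid, tseq in read_fasta(config.transcripts_fasta, alphabet="dna"):
                gene_id = config.meta.get(tid, {}).get("gene", tid.rsplit(".", 1)[0])
                if gene_id not in genomic:
                    raise AoxkitError(f"no genomic sequence for transcript {tid}")
                st = delineate_structure(
                    tseq, genomic[gene_id], min_intron=config.min_intron,
                    gene_id=gene_id, transcript_id=tid,
                )
                structures.append(st)
            table = structure_summary(structures)
            table.to_csv(outdir / "structure_summary.tsv", sep="\t", index=False)
            log["outputs"]["structure"] = "structure_summary.tsv"
            log["stages_run"].append("structure")

        proteins = []
        if config.proteins_fasta:
            proteins = read_fasta(config.proteins_fasta)

        if stage("classification") and proteins:
            isoforms = []
            for iso_id, seq in proteins:
                meta = config.meta.get(iso_id, {})
                isoforms.append(
                    IsoformInput(
                        isoform_id=iso_id,
                        protein_seq=seq,
                        source_gene=meta.get("gene", iso_id),
                        confidence=meta.get("confidence", "high"),
                        species_code=meta.get("species_code", "Ta"),
                        location=meta.get("location"),
                        paralog_index=meta.get("paralog_index"),
                        sv_index=meta.get("sv_index"),
                    )
                )
            records = classify_family(isoforms, catalogs)
            write_report(
                [
                    {
                        "isoform_id": r.isoform_id,
                        "clade": r.clade,
                        "motifs": ",".join(r.motif_presence),
                        "rule": r.rule,
                        "name": r.name,
                    }
                    for r in records
                ],
                outdir / "classification.tsv",
            )
            log["outputs"]["classification"] = "classification.tsv"
            log["stages_run"].append("classification")

        if stage("domains") and proteins:
            rows = []
            for iso_id, seq in proteins:
                rmap = map_to_reference(seq, catalogs.tbaox_seq, isoform_id=iso_id)
                for domain in catalogs.tbaox_positions:
                    profile = extract_domain_profile(rmap, seq, catalogs, domain)
                    row = {"isoform_id": iso_id, "domain": domain,
                           "identity": rmap.alignment_identity}
                    row.update({str(p): a for p, a in profile.residues.items()})
                    rows.append(row)
            write_report(rows, outdir / "domain_profiles.tsv")
            log["outputs"]["domains"] = "domain_profiles.tsv"
            log["stages_run"].append("domains")

        if stage("promoter") and config.promoters_fasta:
            rows = []
            for pid, pseq in read_fasta(config.promoters_fasta, alphabet="dna"):
                for motif in catalogs.regulator_motifs:
                    hits = scan_iupac(pseq, motif.pattern, 0,
                                      config.strand_convention, motif.name)
                    for h in hits:
                        rows.append(
                            {"promoter": pid, "motif": h.motif_name,
                             "start": h.start, "strand": h.strand,
                             "matched_text": h.matched_text}
                        )
            write_report(rows, outdir / "promoter_hits.tsv",
                         columns=["promoter", "motif", "start", "strand",
                                  "matched_text"])
            log["outputs"]["promoter"] = "promoter_hits.tsv"
            log["stages_run"].append("promoter")

        if stage("cpg") and config.genomic_fasta:
            rows = []
            for gid, gseq in read_fasta(config.genomic_fasta, alphabet="dna"):
                for island in find_cpg_islands(gseq, **config.cpg):
                    rows.append(
                        {"sequence": gid, "region": (island.start, island.end),
                         "length": island.length,
                         "mean_gc": round(island.mean_gc, 2),
                         "mean_oe": round(island.mean_oe, 3)}
                    )
            write_report(rows, outdir / "cpg_islands.tsv",
                         columns=["sequence", "region", "length", "mean_gc",
                                  "mean_oe"])
            log["outputs"]["cpg"] = "cpg_islands.tsv"
            log["stages_run"].append("cpg")

        if stage("properties") and proteins:
            write_report(properties_table(proteins, config.pka_set),
                         outdir / "protein_properties.tsv")
            log["outputs"]["properties"] = "protein_properties.tsv"
            log["stages_run"].append("properties")

        if stage("expression") and config.tpm_table:
            matrix = read_tpm_table(config.tpm_table)
            ratios = ratio_matrix(matrix, config.expression_pairs)
            export_heatmap_matrix(ratios, outdir / "expression_ratios.tsv")
            log["outputs"]["expression"] = "expression_ratios.tsv"
            log["stages_run"].append("expression")
    except AoxkitError as exc:
        raise AoxkitError(f"pipeline halted: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return log


# ---------------------------------------------------------------------------
# transcribed table fixtures
# ---------------------------------------------------------------------------

def _fixture_dir() -> Path:
    return Path(resources.files("aoxkit").joinpath("data/fixtures"))  # type: ignore[arg-type]


def load_published_tables(verify: bool = True) -> dict:
    """Load the transcribed domain-comparison matrices.

    Returns ``{"cavity": DataFrame, "dimer_core": DataFrame,
    "dimer_high": DataFrame, "reference": {domain: {pos: letter}}}`` where each
    DataFrame is isoforms x positions.  Fixture files are checksummed; a
    tampered file is an error.
    """
    import pandas as pd

    fdir = _fixture_dir()
    manifest = json.loads((fdir / "checksums.json").read_text())
    catalogs = load_catalogs()
    out: dict = {"reference": catalogs.tbaox_positions}
    frames: dict[str, "pd.DataFrame"] = {}
    for fname in ("dimer_profiles.tsv", "cavity_profiles.tsv"):
        path = fdir / fname
        if verify and _checksum(path) != manifest[fname]:
            raise AoxkitError(f"fixture checksum mismatch for {fname}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = [int(c[1:]) for c in df.columns]  # "H138" -> 138
        frames[fname] = df

    cavity = frames["cavity_profiles.tsv"]
    if set(cavity.columns) != set(catalogs.tbaox_positions["cavity"]):
        raise AoxkitError("cavity fixture columns disagree with the catalog")
    dimer = frames["dimer_profiles.tsv"]
    core_cols = [p for p in dimer.columns if p in catalogs.tbaox_positions["dimer_core"]]
    high_cols = [p for p in dimer.columns if p in catalogs.tbaox_positions["dimer_high"]]
    if len(core_cols) + len(high_cols) != len(dimer.columns):
        raise AoxkitError("dimer fixture columns disagree with the catalog")
    out["cavity"] = cavity
    out["dimer_core"] = dimer[core_cols]
    out["dimer_high"] = dimer[high_cols]
    return out


def fixture_profiles(frame, domain: str):
    """Convert a fixture DataFrame into DomainProfile objects."""
    from aoxkit.residues import DomainProfile

    profiles = []
    for isoform, row in frame.iterrows():
        residues = {int(p): str(v) for p, v in row.items()}
        profiles.append(
            DomainProfile(isoform_id=str(isoform), domain=domain,
                          residues=residues, chemistry={})
        )
    return profiles
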