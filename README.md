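# aoxkit

Curation toolkit for small plant gene families (built around the wheat
alternative-oxidase family conventions). Given genomic, CDS, promoter and
protein sequences for candidate family members it:

- **delineates gene structure** by spliced exact matching of each
  transcript/CDS against its gene, preferring GT..AG introns, and classifies
  splice-variant differences (intron retention, alternative 5'/3' UTR);
- **classifies isoforms** by the four signature motifs (LETVAA, ERMHLMT,
  LEEEA, RADEAHH, with a one-substitution variant tolerance that must preserve
  the catalytic E/H residues), diagnostic-residue typing against a
  classification reference, and nearest-reference clade assignment, then
  generates systematic names
  (`put.`/`reg`/`ne.` prefixes, `-like` suffix, chromosome arm, `.svN`);
- **transfers residue numbering** onto the structural reference (TbAOX-style
  numbering) via Needleman–Wunsch global alignment and profiles the diiron,
  dimer-interface and hydrophobic-cavity positions, with conservation
  summaries and side-chain chemistry ratios;
- **scans promoters** for degenerate IUPAC motifs (e.g. the MDM element
  `CTTGNNNNNCAMG` / `YTTGNNNNNVAMV`) with mismatch tolerance on both strands,
  and detects **CpG islands** by windowed GC% and observed/expected CpG
  statistics (window 100, min length 200, OE > 0.6, GC > 50 by default);
- computes **protein properties** (length, average MW in kDa, theoretical pI
  by Henderson–Hasselbalch bisection with selectable pKa sets) and
  **expression log2-ratio matrices** for heat maps;
- ships a **synthetic-data generator** (`aoxkit simulate`) that plants gene
  structures, clades, motif knockouts, promoter motifs, CpG blocks and
  expression fold changes with a JSON TruthManifest, so the whole pipeline is
  testable offline.

## CLI

```bash
aoxkit simulate --seed 17 --out sim/                 # synthetic family + manifest
aoxkit structure --genomic sim/genomic.fasta --transcripts sim/transcripts.fasta
aoxkit classify  --proteins sim/proteins.fasta --meta meta.tsv
aoxkit domains   --proteins sim/proteins.fasta
aoxkit promoter  --seq sim/promoters.fasta
aoxkit cpg       --seq sim/genomic.fasta
aoxkit props     --proteins sim/proteins.fasta --pka emboss
aoxkit run       --config run.yaml --out report/     # full pipeline bundle
```

Exit codes: 0 ok, 1 user error, 2 internal error.

## Conventions

- All public coordinates are 1-based inclusive; reports mirror the
  `(start..end)` interval style.
- Alignment scoring: BLOSUM62, affine gaps costing `open + L*extend`
  (10/0.5), end gaps penalised; percent identity uses all alignment columns.
- CpG window statistics are attributed to the window midpoint, so the first
  reportable base with the default window of 100 is position 51.
- Promoter tallies scan both strands by default (`--strands`/config flag);
  published-count reproduction uses the forward strand, as documented in the
  acceptance tests.
- Default pKa set is the EMBOSS one; `lehninger` and `sillero` are selectable
  and every report is tagged with the set used.
- The bundled TbAOX-numbering reference and per-clade backbones under
  `src/aoxkit/data/` are deterministic synthetic stand-ins that carry the
  catalog residues at the catalog positions (regenerate with
  `python scripts/make_reference_data.py`). Replace them with real sequences
  for production analyses; any replacement must pass the catalog
  consistency check. Catalog values (motifs, positions, allowed residue
  sets, chemistry classes) live in `src/aoxkit/data/catalogs.yaml` and are
  user-overridable.
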