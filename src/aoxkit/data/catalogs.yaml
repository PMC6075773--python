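# Default catalog bundle.
#
# Everything in this file is configuration, not code: signature motif
# patterns, diagnostic residue scheme, reference position lists, regulator
# motifs and the side-chain chemistry classes.  Edit or replace freely.
#
# Provenance notes:
#   * signature_motifs: the four family signature motifs with the
#     active-site glutamate/histidine offsets flagged as catalytic.
#   * diagnostic_scheme: the allowed-residue sets per class are shipped as
#     self-consistent defaults tied to the bundled synthetic reference
#     (AOX1A_REF).  The published residue-identity sets are conveyed by
#     table cell colour in the source material and are not machine-readable;
#     replace reference_fasta/reference_id and the allowed sets with your own
#     transcription when available.
#   * tbaox_positions: reference position lists with their reference residue
#     letters.  Any replacement reference sequence must carry these letters
#     at these positions (consistency check).
#   * regulator_motifs: IUPAC patterns for promoter scanning.  Only the two
#     degenerate MDM patterns plus canonical W-box / CE1 binding sites are
#     bundled; extend with your own catalog for full cis-element surveys.

signature_motifs:
  - name: LETVAA
    pattern: LETVAA
    catalytic: [2]          # glutamate
  - name: ERMHLMT
    pattern: ERMHLMT
    catalytic: [1, 4]       # glutamate, histidine
  - name: LEEEA
    pattern: LEEEA
    catalytic: [2, 3, 4]    # glutamates
  - name: RADEAHH
    pattern: RADEAHH
    catalytic: [4, 6, 7]    # glutamate, histidines

diagnostic_scheme:
  reference_fasta: clade_references.fasta
  reference_id: AOX1a
  type_positions: [112, 124, 229, 233, 241]
  subtype_positions: [167, 175, 178, 180, 181, 295]
  type_allowed:
    Type1: {112: E, 124: L, 229: T, 233: R, 241: D}
    Type2: {112: Q, 124: F, 229: S, 233: K, 241: N}
  subtype_allowed:
    ace: {167: M, 175: E, 178: Y, 180: R, 181: A, 295: K}
    d:   {167: M, 175: D, 178: W, 180: R, 181: A, 295: R}

tbaox_reference_fasta: tbaox_reference.fasta

tbaox_positions:
  diiron: [E123, E162, H165, E213, E266, H269]
  dimer_core: [H138, L142, R143, R163, L166, Q187]
  dimer_high: [M131, M135, L139, S141, M145, R147, D148, L156, A159, M167, R180, I183]
  cavity: [S91, T94, C95, W97, L98, F99, F102, S117, R118, F121, L122, V125,
           A126, V128, P178, L179, V181, S182, I185, T186, I189, M190, F193,
           L194, A197, Y198, I200, S201, F204, V205, F208, V209, L212]

clade_reference_fasta: clade_references.fasta

regulator_motifs:
  - name: MDM_stringent
    pattern: CTTGNNNNNCAMG
    positive: true
    categories: [mitochondrial_retrograde]
  - name: MDM_alternative
    pattern: YTTGNNNNNVAMV
    positive: true
    categories: [mitochondrial_retrograde]
  - name: W_box
    pattern: TTGACY
    positive: true
    categories: [biotic_response]
  - name: W_box_negative
    pattern: TTGACT
    positive: false
    categories: [biotic_response]
  - name: CE1_like
    pattern: CACCG
    positive: false
    categories: [ABA_response]

chemistry_map:
  A: hydrophobic
  V: hydrophobic
  L: hydrophobic
  I: hydrophobic
  M: hydrophobic
  C: hydrophobic
  F: cyclic
  Y: cyclic
  W: cyclic
  P: cyclic
  H: cyclic
  G: glycine
  S: polar
  T: polar
  N: polar
  Q: polar
  D: polar
  E: polar
  K: polar
  R: polar
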