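import pytest
from hypothesis import given, settings, strategies as st

from aoxkit.classify import (
    IsoformInput,
    NameParts,
    assign_clade,
    assign_name,
    classify_family,
    parse_name,
    scan_signature_motifs,
    type_diagnostic_residues,
)
from aoxkit.core import AoxkitError


class TestMotifScan:
    def test_exact_hits(self, catalogs):
        seq = catalogs.clade_references["AOX1a"]
        statuses = {m.motif_name: m.status for m in scan_signature_motifs(seq, catalogs)}
        assert set(statuses.values()) == {"present"}

    def test_variant_preserving_catalytic(self, catalogs):
        # LETVAA -> LEMVAA: one substitution away from the catalytic glutamate
        seq = "GGGG" + "LEMVAA" + "GGGG"
        hits = {m.motif_name: m for m in scan_signature_motifs(seq, catalogs)}
        assert hits["LETVAA"].status == "variant"
        assert hits["LETVAA"].matched_text == "LEMVAA"
        assert hits["LETVAA"].position == 5

    def test_variant_touching_catalytic_is_absent(self, catalogs):
        # LQTVAA substitutes the catalytic E (offset 2) -> not a variant
        hits = {m.motif_name: m for m in scan_signature_motifs("LQTVAA", catalogs)}
        assert hits["LETVAA"].status == "absent"

    def test_two_substitutions_absent(self, catalogs):
        hits = {m.motif_name: m for m in scan_signature_motifs("LEMVAG", catalogs)}
        assert hits["LETVAA"].status == "absent"

    def test_all_absent(self, catalogs):
        assert all(
            m.status == "absent" for m in scan_signature_motifs("AAAA", catalogs)
        )

    def test_strict_mode_rejects_variants(self, catalogs):
        hits = {m.motif_name: m
                for m in scan_signature_motifs("GGLEMVAAGG", catalogs, strict=True)}
        assert hits["LETVAA"].status == "absent"

    def test_leftmost_hit_reported(self, catalogs):
        seq = "AA" + "LEEEA" + "AAAA" + "LEEEA"
        hits = {m.motif_name: m for m in scan_signature_motifs(seq, catalogs)}
        assert hits["LEEEA"].position == 3

    @settings(max_examples=30, deadline=None)
    @given(prefix=st.text(alphabet="ACDEFGHIKMNPQSWY", min_size=0, max_size=25))
    def test_position_shift_property(self, catalogs, prefix):
        """Prepending residues shifts hit positions by the prefix length."""
        base = catalogs.clade_references["AOX1c"]
        base_hits = scan_signature_motifs(base, catalogs)
        shifted = scan_signature_motifs(prefix + base, catalogs)
        for h0, h1 in zip(base_hits, shifted):
            if h0.status != "absent":
                assert h1.position == h0.position + len(prefix)


class TestDiagnosticTyping:
    def test_reference_types_as_itself(self, catalogs):
        ref = catalogs.diagnostic_scheme.reference_seq
        t = type_diagnostic_residues(ref, catalogs)
        assert all(r is not None for r in t.residues.values())
        assert t.type_call == "Type1"
        assert t.subtype_call == "ace"

    def test_planted_subtype_d(self, catalogs):
        scheme = catalogs.diagnostic_scheme
        seq = list(scheme.reference_seq)
        for pos in scheme.subtype_positions:
            seq[pos - 1] = next(iter(scheme.subtype_allowed["d"][pos]))
        t = type_diagnostic_residues("".join(seq), catalogs)
        assert t.subtype_call == "d"

    def test_backbone_1d_types_d(self, catalogs):
        t = type_diagnostic_residues(catalogs.clade_references["AOX1d"], catalogs)
        assert t.subtype_call == "d"
        assert t.type_call == "Type1"

    def test_planted_type2(self, catalogs):
        scheme = catalogs.diagnostic_scheme
        seq = list(scheme.reference_seq)
        for pos in scheme.type_positions:
            seq[pos - 1] = next(iter(scheme.type_allowed["Type2"][pos]))
        assert type_diagnostic_residues("".join(seq), catalogs).type_call == "Type2"

    def test_conflicting_residues_mixed(self, catalogs):
        scheme = catalogs.diagnostic_scheme
        seq = list(scheme.reference_seq)
        # one Type2 residue among Type1 ones, at a position where the sets differ
        pos = scheme.type_positions[0]
        seq[pos - 1] = next(iter(scheme.type_allowed["Type2"][pos]))
        assert type_diagnostic_residues("".join(seq), catalogs).type_call == "mixed"

    def test_mostly_absent_unresolved(self, catalogs):
        # a short fragment aligned far from the diagnostic positions
        frag = catalogs.diagnostic_scheme.reference_seq[:60]
        t = type_diagnostic_residues(frag, catalogs)
        assert t.type_call == "unresolved"


class TestAssignClade:
    def test_reference_is_its_own_clade(self, catalogs):
        for clade, seq in catalogs.clade_references.items():
            call = assign_clade(seq, catalogs)
            assert call.clade == clade
            assert call.identities[clade] == 100.0

    def test_chimera_nearest_reference(self, catalogs):
        """~60% identical to the AOX1c reference -> AOX1c (oracle identity is
        checked through an independent mutation count)."""
        import random

        rng = random.Random(42)
        ref = catalogs.clade_references["AOX1c"]
        seq = list(ref)
        scheme = catalogs.diagnostic_scheme
        protected = set(scheme.subtype_positions) | set(scheme.type_positions)
        mutable = [i for i in range(len(seq)) if (i + 1) not in protected]
        for i in rng.sample(mutable, int(0.4 * len(seq))):
            seq[i] = "W" if seq[i] != "W" else "Y"
        chimera = "".join(seq)
        call = assign_clade(chimera, catalogs)
        assert call.clade == "AOX1c"
        hamming_identity = 100.0 * sum(a == b for a, b in zip(chimera, ref)) / len(ref)
        assert abs(call.identities["AOX1c"] - hamming_identity) < 2.0

    def test_unrelated_sequence_unknown(self, catalogs):
        call = assign_clade("MKKKKKKKKKKKKKKKKKKKK", catalogs)
        assert call.clade == "unknown"


class TestNaming:
    TABLE1_NAMES = [
        "TaAOX1a-2AL.sv1", "TaAOX1a-2AL.sv2", "TaAOX1a-2BL", "TaAOX1a-2DL.sv1",
        "TaAOX1a-2DL.sv2", "TaAOX1a-like-2DL", "regTaAOX-4BL.sv1",
        "regTaAOX-4BL.sv2", "regTaAOX-4BL.sv3", "regTaAOX-4BL.sv4",
        "put.regTaAOX-3B", "put.regTaAOX-6BL", "TaAOX1c-6AL", "TaAOX1c-6BL.sv1",
        "TaAOX1c-6BL.sv2", "TaAOX1c-6BL.sv3", "TaAOX1c-6DL", "regTaAOX-3B",
        "put.TaAOX1e-3DS", "TaAOX1d-2AL.1", "TaAOX1d-2AL.2.sv1",
        "TaAOX1d-2AL.2.sv2", "TaAOX1d-2DL", "put.TaAOX1d-like-4AS",
        "TuAOX1d.1", "TuAOX1d.2", "TuAOX1c", "TuAOX1a", "AetAOX1d",
        "AetAOX1d-like", "AetAOX1e", "AetAOX1a", "ne.TaAOX1d-2BL.1",
        "ne.TaAOX1d-2BL.2", "ne.TaAOX1d-2DL", "ne.TaAOX•-2AL",
        "ne.AesAOX1d", "ne.AesAOX•",
    ]

    @pytest.mark.parametrize("name", TABLE1_NAMES)
    def test_published_names_round_trip(self, name):
        assert assign_name(parse_name(name)) == name

    def test_examples(self):
        assert assign_name(NameParts("Ta", "AOX1d", put=True, like_suffix=True,
                                     location="4AS")) == "put.TaAOX1d-like-4AS"
        assert assign_name(NameParts("Ta", "AOX", reg=True, location="4BL",
                                     sv_index=1)) == "regTaAOX-4BL.sv1"
        assert assign_name(NameParts("Ta", "AOX1a", location="2BL")) == "TaAOX1a-2BL"

    def test_reg_with_like_rejected(self):
        with pytest.raises(AoxkitError):
            assign_name(NameParts("Ta", "AOX", reg=True, like_suffix=True))

    def test_reg_with_clade_core_rejected(self):
        with pytest.raises(AoxkitError):
            assign_name(NameParts("Ta", "AOX1a", reg=True))

    @settings(max_examples=100, deadline=None)
    @given(
        species=st.sampled_from(["Ta", "Tu", "Aet", "Aes"]),
        kind=st.sampled_from(["clade", "reg", "bullet"]),
        clade=st.sampled_from(["AOX1a", "AOX1c", "AOX1e", "AOX1d"]),
        put=st.booleans(),
        ne=st.booleans(),
        like=st.booleans(),
        location=st.sampled_from([None, "2AL", "4AS", "3B", "6DL"]),
        paralog=st.sampled_from([None, 1, 2]),
        sv=st.sampled_from([None, 1, 2, 3]),
    )
    def test_round_trip_property(self, species, kind, clade, put, ne, like,
                                 location, paralog, sv):
        if kind == "reg":
            parts = NameParts(species, "AOX", put=put, reg=True, ne=False,
                              location=location, paralog_index=paralog, sv_index=sv)
        elif kind == "bullet":
            parts = NameParts(species, "AOX•", put=put, ne=True, like_suffix=like,
                              location=location, paralog_index=paralog, sv_index=sv)
        else:
            parts = NameParts(species, clade, put=put, ne=ne, like_suffix=like,
                              location=location, paralog_index=paralog, sv_index=sv)
        assert parse_name(assign_name(parts)) == parts


class TestClassifyFamily:
    def test_empty_input(self, catalogs):
        assert classify_family([], catalogs) == []

    def test_synthetic_family_recovery(self, catalogs, family):
        isoforms = []
        for i, gene in enumerate(family.genes):
            isoforms.append(
                IsoformInput(
                    isoform_id=f"{gene.gene_id}.p1",
                    protein_seq=gene.protein_seq,
                    source_gene=gene.gene_id,
                    confidence=gene.confidence,
                    location=gene.location,
                )
            )
        records = classify_family(isoforms, catalogs)
        for gene, rec in zip(family.genes, records):
            n_ko = len(gene.knockouts)
            if n_ko == 0:
                assert rec.clade == gene.clade, rec.isoform_id
                expected = ("put." if gene.confidence == "low" else "") + \
                    f"Ta{gene.clade}-{gene.location}"
                assert rec.name == expected
            elif n_ko == 4:
                assert rec.name.startswith(("reg", "put.reg", "ne."))
                assert "reg" in rec.name
            else:
                assert "-like" in rec.name
                assert rec.clade == gene.clade
            statuses = dict(zip([m.name for m in catalogs.signature_motifs],
                                rec.motif_presence))
            for ko in gene.knockouts:
                assert statuses[ko] == "absent"

    def test_non_expressed_naming(self, catalogs):
        iso = IsoformInput(
            isoform_id="x", protein_seq=catalogs.clade_references["AOX1d"],
            source_gene="g", confidence="non_expressed", location="2BL",
            paralog_index=1,
        )
        (rec,) = classify_family([iso], catalogs)
        assert rec.name == "ne.TaAOX1d-2BL.1"
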