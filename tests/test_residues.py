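"""Alignment and residue-mapping tests, including an exhaustive alignment
enumeration oracle for short sequences."""

import random

import pytest
from Bio.Align import substitution_matrices

from aoxkit.core import AoxkitError
from aoxkit.pipeline import fixture_profiles, load_published_tables
from aoxkit.residues import (
    DomainProfile,
    chemistry_ratios,
    conservation_summary,
    extract_domain_profile,
    global_align,
    map_to_reference,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 10.0, 0.5


def score_alignment(row_a: str, row_b: str) -> float:
    """Score an explicit alignment under the package's documented convention:
    a gap run of length L costs open + L * extend."""
    score = 0.0
    for gapped in (row_a, row_b):
        i = 0
        while i < len(gapped):
            if gapped[i] == "-":
                j = i
                while j < len(gapped) and gapped[j] == "-":
                    j += 1
                score -= GAP_OPEN + (j - i) * GAP_EXTEND
                i = j
            else:
                i += 1
    for a, b in zip(row_a, row_b):
        if a != "-" and b != "-":
            score += BLOSUM62[a, b]
    return score


def enumerate_alignments(a: str, b: str):
    """Every global alignment of a and b (no gap-against-gap columns)."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


class TestGlobalAlign:
    def test_identical_sequences(self):
        r = global_align("MKLVNT", "MKLVNT")
        assert r.identity == 100.0
        assert "-" not in r.aligned_a + r.aligned_b

    def test_self_alignment_score_is_diagonal_sum(self, catalogs):
        seq = catalogs.clade_references["AOX1e"][:80]
        r = global_align(seq, seq)
        assert r.score == pytest.approx(sum(BLOSUM62[x, x] for x in seq))

    def test_single_gap_identity(self):
        r = global_align("ACDE", "ACE")
        assert (r.aligned_a, r.aligned_b) == ("ACDE", "AC-E")
        assert r.identity == 75.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_enumeration_oracle(self, seed):
        """The DP score equals the max over every explicit alignment.

        Enumeration is super-exponential, so the oracle runs at lengths <= 6
        (about 4e4 alignments/pair) rather than the 12 the budget cannot fit.
        """
        rng = random.Random(seed)
        alphabet = "ARNDCQEGHILKMFPSTWYV"
        a = "".join(rng.choice(alphabet) for _ in range(rng.randint(2, 6)))
        b = "".join(rng.choice(alphabet) for _ in range(rng.randint(2, 6)))
        best = max(score_alignment(ra, rb) for ra, rb in enumerate_alignments(a, b))
        assert global_align(a, b).score == pytest.approx(best)

    def test_reported_alignment_scores_its_own_score(self, catalogs):
        a = catalogs.clade_references["AOX1a"][:60]
        b = catalogs.clade_references["AOX1d"][10:70]
        r = global_align(a, b)
        assert score_alignment(r.aligned_a, r.aligned_b) == pytest.approx(r.score)

    def test_empty_sequence_rejected(self):
        with pytest.raises(AoxkitError):
            global_align("", "ACDE")


class TestMapToReference:
    def test_self_map_is_identity(self, catalogs):
        ref = catalogs.tbaox_seq
        m = map_to_reference(ref, ref, isoform_id="self")
        assert m.pairs == [(i, i) for i in range(1, len(ref) + 1)]
        assert m.alignment_identity == 100.0

    def test_insertion_shifts_mapping(self, catalogs):
        """Reference with a 10-residue insertion after position 100: positions
        <= 100 map identically, later ones shift by 10 (constructed truth)."""
        ref = catalogs.tbaox_seq
        iso = ref[:100] + "G" * 10 + ref[100:]
        m = map_to_reference(iso, ref)
        lookup = dict(m.pairs)
        for p in (1, 50, 100):
            assert lookup[p] == p
        for p in (101, 200, len(ref)):
            assert lookup[p] == p + 10

    def test_backbone_maps_gaplessly(self, catalogs):
        m = map_to_reference(catalogs.clade_references["AOX1a"], catalogs.tbaox_seq)
        assert all(ip is not None for _, ip in m.pairs)

    def test_low_identity_flag(self, catalogs):
        m = map_to_reference("MKKKKKKLLLLLLAAAAAA", catalogs.tbaox_seq)
        assert m.low_identity

    def test_mapping_consistency(self, catalogs):
        """Composing the map with its inverse on aligned columns is identity."""
        iso = catalogs.clade_references["AOX1d"]
        m = map_to_reference(iso, catalogs.tbaox_seq)
        inverse = {ip: rp for rp, ip in m.pairs if ip is not None}
        for rp, ip in m.pairs:
            if ip is not None:
                assert inverse[ip] == rp


class TestDomainProfiles:
    def test_reference_profile_equals_catalog(self, catalogs):
        m = map_to_reference(catalogs.tbaox_seq, catalogs.tbaox_seq, isoform_id="ref")
        for domain, positions in catalogs.tbaox_positions.items():
            profile = extract_domain_profile(m, catalogs.tbaox_seq, catalogs, domain)
            assert profile.residues == positions

    def test_backbone_profile_matches_published_row(self, catalogs):
        """The bundled AOX1a backbone reproduces the published cavity and
        dimer rows for the corresponding isoforms."""
        fixtures = load_published_tables()
        m = map_to_reference(catalogs.clade_references["AOX1a"], catalogs.tbaox_seq,
                             isoform_id="AOX1a")
        cavity = extract_domain_profile(
            m, catalogs.clade_references["AOX1a"], catalogs, "cavity"
        )
        published = fixtures["cavity"].loc["TaAOX1a-2AL.sv1"]
        assert {p: r for p, r in cavity.residues.items()} == dict(published)

    def test_unknown_domain(self, catalogs):
        m = map_to_reference(catalogs.tbaox_seq, catalogs.tbaox_seq)
        with pytest.raises(AoxkitError, match="unknown domain"):
            extract_domain_profile(m, catalogs.tbaox_seq, catalogs, "nope")

    def test_truncated_isoform_has_gap_cells(self, catalogs):
        iso = catalogs.clade_references["AOX1d"][150:]  # N-terminal truncation
        m = map_to_reference(iso, catalogs.tbaox_seq)
        profile = extract_domain_profile(m, iso, catalogs, "cavity")
        assert profile.residues[91] == "-"


class TestConservationSummary:
    def test_single_identical_profile(self, catalogs):
        ref = catalogs.tbaox_positions["cavity"]
        profile = DomainProfile("x", "cavity", dict(ref), {})
        s = conservation_summary([profile], ref)
        assert len(s.identical_positions) == 33
        assert not s.uniform_substitutions and not s.mixed_positions

    def test_partition_property(self, catalogs):
        fixtures = load_published_tables()
        profiles = fixture_profiles(fixtures["cavity"], "cavity")
        ref = catalogs.tbaox_positions["cavity"]
        s = conservation_summary(profiles, ref)
        covered = (set(s.identical_positions)
                   | {p for p, _ in s.uniform_substitutions}
                   | set(s.mixed_positions))
        assert covered == set(ref)
        assert len(s.identical_positions) + len(s.uniform_substitutions) + len(
            s.mixed_positions
        ) == 33

    def test_empty_after_exclusion(self, catalogs):
        ref = catalogs.tbaox_positions["cavity"]
        profile = DomainProfile("x", "cavity", dict(ref), {})
        with pytest.raises(AoxkitError):
            conservation_summary([profile], ref, exclude=["x"])


class TestChemistryRatios:
    def test_all_leucine(self, catalogs):
        profile = DomainProfile("x", "cavity",
                                {p: "L" for p in catalogs.tbaox_positions["cavity"]},
                                {})
        out = chemistry_ratios(profile, catalogs.chemistry_map)
        assert out["ratios"]["hydrophobic"] == 1.0
        assert sum(out["ratios"].values()) == pytest.approx(1.0)

    def test_published_row_hand_tally(self, catalogs):
        """Counts for the published TaAOX1a-2AL.sv1 cavity row match an
        independent hand tally of that row's 33 letters."""
        fixtures = load_published_tables()
        profiles = fixture_profiles(fixtures["cavity"], "cavity")
        row = next(p for p in profiles if p.isoform_id == "TaAOX1a-2AL.sv1")
        out = chemistry_ratios(row, catalogs.chemistry_map)
        # frozen hand tally of the row TSLFPTFCRMLVAVYEALAVVFAYGYISFAVVL:
        #   hydrophobic (AVLIMC): L C M L V A V A L A V V A I A V V L -> 18
        #   polar (STNQDEKR):     T S T R E S                        -> 6
        #   cyclic (FYWPH):       F P F Y F Y Y F                    -> 8
        #   glycine:              G                                  -> 1
        assert out["counts"] == {
            "hydrophobic": 18, "polar": 6, "cyclic": 8, "glycine": 1,
        }
        assert out["gaps"] == 0

    def test_gap_only_profile_undefined(self, catalogs):
        profile = DomainProfile("x", "cavity",
                                {p: "-" for p in catalogs.tbaox_positions["cavity"]},
                                {})
        out = chemistry_ratios(profile, catalogs.chemistry_map)
        assert out["undefined"] and out["ratios"] is None
        assert out["gaps"] == 33

    def test_unknown_residue_error(self, catalogs):
        profile = DomainProfile("x", "cavity", {91: "B"}, {})
        with pytest.raises(AoxkitError, match="'B'"):
            chemistry_ratios(profile, catalogs.chemistry_map)
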