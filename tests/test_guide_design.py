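import random

import pytest

from artemisdx import (
    LBCAS12A_SCAFFOLD,
    ScanConfig,
    design_oligo_targets,
    enumerate_synthetic_mismatches,
    revcomp,
    scan,
    spacer_to_crrna,
    validate_primer_pair,
)
from artemisdx.artemis_core import ArtemisHit, PamSite
from artemisdx.fixtures import generate_toy_genome
from artemisdx.genome_io import Strand, VariantRecord
from artemisdx.guide_design import PrimerSearchError

RNA_OF_TARGET = {"A": "U", "C": "G", "G": "C", "T": "A"}  # independent table:
# crRNA homopair base = RNA complement of the protospacer base


def _hit_with_spacer(spacer_ref, spacer_alt, seed_pos):
    return ArtemisHit(
        variant=VariantRecord("c", 30, "v", "A", "G"),
        pam=PamSite("c", 4, 8, Strand.FORWARD, "TTTA"),
        seed_pos=seed_pos,
        spacer_ref=spacer_ref,
        spacer_alt=spacer_alt,
    )


class TestSpacerToCrRNA:
    def test_t_to_u_and_scaffold_length(self):
        d = spacer_to_crrna("CGATCGATCGATCGATCGATC", "ref")
        assert d.spacer == "CGAUCGAUCGAUCGAUCGAUC"
        assert d.full_sequence == LBCAS12A_SCAFFOLD + d.spacer
        assert len(d.full_sequence) == 42

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="21 nt"):
            spacer_to_crrna("ACGTACGTACGTACGTACGT", "ref")  # 20 nt

    def test_t_free_spacer_unchanged(self):
        d = spacer_to_crrna("A" * 21, "alt")
        assert d.spacer == "A" * 21

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            spacer_to_crrna("ACGU" + "A" * 17, "ref")


class TestSyntheticMismatches:
    def test_homopair_count_and_positions(self, toy_hit):
        designs = enumerate_synthetic_mismatches(toy_hit, allele="alt")
        assert len(designs) == 4  # seed_size - 1
        assert sorted(d.sm_pos for d in designs) == [1, 2, 4, 5]
        assert all(d.sm_pos != toy_hit.seed_pos for d in designs)

    def test_homopair_bases(self):
        # protospacer C at position 1 -> target strand G -> crRNA G (G.G pair);
        # protospacer A at position 2 -> target strand T -> crRNA U (U.T pair)
        hit = _hit_with_spacer("CAATCGATCGATCGATCGATC", "CAGTCGATCGATCGATCGATC", 3)
        designs = {d.sm_pos: d for d in enumerate_synthetic_mismatches(hit, "alt")}
        assert designs[1].sm_base == "G" and not designs[1].wobble_flag
        assert designs[2].sm_base == "U" and not designs[2].wobble_flag

    def test_mismatch_site_differs_exactly_at_sm_pos(self, toy_hit):
        base = spacer_to_crrna(toy_hit.spacer_alt, "alt")
        for d in enumerate_synthetic_mismatches(toy_hit, "alt"):
            diffs = [i + 1 for i, (a, b) in enumerate(zip(base.spacer, d.spacer))
                     if a != b]
            assert diffs == [d.sm_pos]

    def test_all_mode_emits_three_per_position_and_flags_wobbles(self):
        hit = _hit_with_spacer("CAATCGATCGATCGATCGATC", "CAGTCGATCGATCGATCGATC", 3)
        designs = enumerate_synthetic_mismatches(hit, "alt", mode="all")
        assert len(designs) == 12  # 4 positions x 3 bases
        # position 1: protospacer C, target G -> crRNA U is the U.G wobble
        # position 2: protospacer A, target T -> crRNA G is the G.T wobble
        wobbles = {(d.sm_pos, d.sm_base) for d in designs if d.wobble_flag}
        assert (1, "U") in wobbles and (2, "G") in wobbles
        homopairs = {(d.sm_pos, d.sm_base) for d in designs if not d.wobble_flag}
        assert (1, "G") in homopairs

    def test_homopair_rule_on_random_hits(self):
        rng = random.Random(42)
        for _ in range(50):
            seed_pos = rng.randint(1, 5)
            spacer = "".join(rng.choice("ACGT") for _ in range(21))
            alt = spacer  # allele content irrelevant to the pairing rule
            hit = _hit_with_spacer(spacer, alt, seed_pos)
            for d in enumerate_synthetic_mismatches(hit, "ref"):
                assert d.sm_base == RNA_OF_TARGET[spacer[d.sm_pos - 1]]

    def test_degenerate_seed_size_rejected(self, toy_hit):
        with pytest.raises(ValueError):
            enumerate_synthetic_mismatches(toy_hit, seed_size=1)


class TestOligoTargets:
    def test_toy_layout_55nt_differing_at_snv(self, padded_genome, padded_hit):
        ref, alt = design_oligo_targets({"chr_pad": padded_genome}, padded_hit)
        for oligo in (ref, alt):
            assert len(oligo.top_strand) == 55  # 15 + 4 + 21 + 15
            assert oligo.bottom_strand == revcomp(oligo.top_strand)
        diffs = [i for i, (a, b) in enumerate(zip(ref.top_strand, alt.top_strand))
                 if a != b]
        assert len(diffs) == 1
        # layout check: PAM sits right after the 5' flank
        assert ref.top_strand[15:19] == "TTTA"
        assert ref.top_strand[19:40] == padded_hit.spacer_ref

    def test_reverse_strand_hit_layout(self):
        truth = generate_toy_genome(2000, 4, 4, 0, seed=5)
        rev_hits = [h for h in scan(truth.genome_map, truth.variants, ScanConfig())
                    if h.pam.strand is Strand.REVERSE]
        assert rev_hits, "fixture must plant reverse-strand hits"
        for hit in rev_hits:
            ref, alt = design_oligo_targets(truth.genome_map, hit)
            assert ref.top_strand[15:19] == hit.pam.motif
            assert ref.top_strand[19:40] == hit.spacer_ref
            assert alt.top_strand[19:40] == hit.spacer_alt
            assert ref.bottom_strand == revcomp(ref.top_strand)

    def test_short_flank_rejected_when_enforced(self, padded_genome, padded_hit):
        with pytest.raises(ValueError, match="15-nt minimum"):
            design_oligo_targets({"chr_pad": padded_genome}, padded_hit, flank=3)

    def test_flank_beyond_contig_names_deficit(self, padded_genome, padded_hit):
        with pytest.raises(ValueError, match="boundary by"):
            design_oligo_targets({"chr_pad": padded_genome}, padded_hit, flank=40)


class TestPrimerValidation:
    @pytest.fixture
    def template(self):
        rng = random.Random(7)
        seq = "".join(rng.choice("ACGT") for _ in range(200))
        return seq

    def test_flanking_primers_pass(self, template):
        target = (80, 105)
        fwd = template[40:60]
        rev = revcomp(template[110:130])
        check = validate_primer_pair(template, target, fwd, rev)
        assert check.verdict == "pass"
        assert check.amplicon_length == 90
        assert not check.overlaps_target and check.within_bounds

    def test_primer_overlapping_target_fails(self, template):
        target = (80, 105)
        fwd = template[62:82]  # ends 2 nt inside the target
        rev = revcomp(template[110:130])
        check = validate_primer_pair(template, target, fwd, rev)
        assert check.verdict == "fail" and check.overlaps_target

    def test_long_amplicon_fails_bounds(self, template):
        target = (80, 105)
        fwd = template[20:40]
        rev = revcomp(template[130:150])
        check = validate_primer_pair(template, target, fwd, rev)
        assert check.amplicon_length == 130
        assert check.verdict == "fail" and not check.within_bounds

    def test_missing_or_ambiguous_primer_is_error(self, template):
        with pytest.raises(PrimerSearchError, match="not found"):
            validate_primer_pair(template, (80, 105), "T" * 25,
                                 revcomp(template[110:130]))
        doubled = template + template
        with pytest.raises(PrimerSearchError, match="ambiguous"):
            validate_primer_pair(doubled, (80, 105), doubled[40:60],
                                 revcomp(doubled[110:130]))

    def test_amplicon_must_contain_target(self, template):
        check = validate_primer_pair(
            template, (150, 175), template[40:60], revcomp(template[110:130]))
        assert check.verdict == "fail"

    def test_swapping_primers_with_strands_mirrors_the_amplicon(self, template):
        target = (80, 105)
        fwd = template[40:60]
        rev = revcomp(template[110:130])
        check = validate_primer_pair(template, target, fwd, rev)
        length = len(template)
        mirrored = validate_primer_pair(
            revcomp(template), (length - 105, length - 80), rev, fwd)
        assert mirrored.amplicon_length == check.amplicon_length
        assert mirrored.verdict == check.verdict
        assert (mirrored.amplicon_start, mirrored.amplicon_end) == (
            length - check.amplicon_end, length - check.amplicon_start)
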