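import pytest

from artemisdx import (
    GenomeSequence,
    ScanConfig,
    Strand,
    VariantRecord,
    exclude_common_pam,
    find_pam_sites,
    keyword_filter,
    scan,
    seed_offset,
)
from artemisdx.artemis_core import (
    ContigMismatchError,
    PamSite,
    ReferenceMismatchError,
    compile_pam_pattern,
)
from artemisdx.fixtures import generate_toy_genome

CFG = ScanConfig()


class TestFindPamSites:
    def test_forward_tttv_site(self, toy_genome):
        sites = find_pam_sites(toy_genome, CFG)
        assert [(s.start, s.end, s.strand, s.motif) for s in sites] == [
            (2, 6, Strand.FORWARD, "TTTA")
        ]

    def test_reverse_strand_site(self):
        # forward text CAAA at [1,5) is TTTG on the reverse strand
        sites = find_pam_sites(GenomeSequence("c", "GCAAAT"), CFG)
        assert [(s.start, s.end, s.strand, s.motif) for s in sites] == [
            (1, 5, Strand.REVERSE, "TTTG")
        ]

    def test_no_match(self):
        assert find_pam_sites(GenomeSequence("c", "GGGGGG"), CFG) == []

    def test_overlapping_sites_all_reported(self):
        # TTTA forward at 0 and TAAA (= TTTA reverse) at 2 overlap
        sites = find_pam_sites(GenomeSequence("c", "TTTAAA"), CFG)
        assert {(s.start, s.strand) for s in sites} == {
            (0, Strand.FORWARD), (2, Strand.REVERSE)}

    def test_forward_only_flag(self):
        cfg = ScanConfig(both_strands=False)
        assert find_pam_sites(GenomeSequence("c", "GCAAAT"), cfg) == []

    def test_raw_regex_pattern_matches_iupac(self, toy_genome):
        iupac = find_pam_sites(toy_genome, ScanConfig(pam_pattern="TTTV"))
        regex = find_pam_sites(toy_genome, ScanConfig(pam_pattern="TTT[ACG]"))
        assert iupac == regex

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            compile_pam_pattern("TTT[")
        with pytest.raises(ValueError):
            ScanConfig(pam_pattern="")


class TestSeedOffset:
    PAM = PamSite("chr_toy", 2, 6, Strand.FORWARD, "TTTA")

    def _variant(self, pos):
        return VariantRecord("chr_toy", pos, ".", "A", "G")

    def test_forward_inside_window(self):
        assert seed_offset(self.PAM, self._variant(9), CFG) == 3

    def test_forward_beyond_window(self):
        assert seed_offset(self.PAM, self._variant(12), CFG) is None

    def test_inside_pam_is_not_seed(self):
        assert seed_offset(self.PAM, self._variant(4), CFG) is None

    def test_reverse_geometry(self):
        pam = PamSite("chr_toy", 10, 14, Strand.REVERSE, "TTTA")
        assert seed_offset(pam, self._variant(10), CFG) == 1  # pos0 9 = start-1
        assert seed_offset(pam, self._variant(6), CFG) == 5
        assert seed_offset(pam, self._variant(5), CFG) is None

    def test_contig_mismatch_is_error(self):
        with pytest.raises(ContigMismatchError):
            seed_offset(self.PAM, VariantRecord("chr_other", 9, ".", "A", "G"), CFG)


class TestScan:
    def test_toy_hit_spacers(self, toy_hit):
        assert toy_hit.seed_pos == 3
        assert (toy_hit.pam.start, toy_hit.pam.end) == (2, 6)
        assert toy_hit.spacer_ref == "CGATCGATCGATCGATCGATC"
        assert toy_hit.spacer_alt == "CGGTCGATCGATCGATCGATC"

    def test_snv_left_of_pam_yields_nothing(self, toy_genome):
        v = VariantRecord("chr_toy", 2, ".", "G", "A")
        assert scan({"chr_toy": toy_genome}, [v], CFG) == []

    def test_contig_name_mismatch_is_hard_error(self, toy_genome):
        v = VariantRecord("chrX", 9, ".", "A", "G")
        with pytest.raises(ContigMismatchError, match="chrX"):
            scan({"chr_toy": toy_genome}, [v], CFG)

    def test_vcf_ref_disagreeing_with_genome_is_error(self, toy_genome):
        v = VariantRecord("chr_toy", 9, ".", "C", "G")  # genome has A there
        with pytest.raises(ReferenceMismatchError):
            scan({"chr_toy": toy_genome}, [v], CFG)

    def test_spacer_window_beyond_contig_is_dropped(self):
        # PAM at [2,6) but only 10 bases of spacer room
        g = GenomeSequence("c", "GG" + "TTTA" + "CGATCGATCG")
        v = VariantRecord("c", 9, ".", "A", "G")
        assert scan({"c": g}, [v], CFG) == []

    def test_seed_window_boundary_offsets_1_to_8(self):
        truth = generate_toy_genome(
            3000, 4, 0, 0, seed=3, snv_offsets=[1, 2, 3, 4, 5, 6, 7, 8]
        )
        hits = scan(truth.genome_map, truth.variants, CFG)
        assert sorted(h.seed_pos for h in hits) == [1, 2, 3, 4, 5]
        hit_ids = {h.variant.variant_id for h in hits}
        assert {truth.labels[i] for i in hit_ids} == {"seed_hit"}

    def test_spacer_pair_differs_exactly_at_seed_pos(self):
        for seed in range(5):
            truth = generate_toy_genome(1500, 4, 6, 2, seed=seed)
            for h in scan(truth.genome_map, truth.variants, CFG):
                diffs = [i for i, (a, b) in
                         enumerate(zip(h.spacer_ref, h.spacer_alt), start=1)
                         if a != b]
                assert diffs == [h.seed_pos]
                assert 1 <= h.seed_pos <= CFG.seed_size

    def test_strand_symmetry_under_genome_revcomp(self):
        from artemisdx import revcomp

        truth = generate_toy_genome(2000, 5, 5, 0, seed=5)
        genome = truth.genomes[0]
        length = len(genome.sequence)
        flipped = GenomeSequence(genome.contig_id, revcomp(genome.sequence))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        remapped = [
            VariantRecord(v.contig_id, length - v.pos + 1, v.variant_id,
                          comp[v.ref_allele], comp[v.alt_allele], info=v.info)
            for v in truth.variants if v.is_snv
        ]
        fwd_hits = scan(truth.genome_map, [v for v in truth.variants if v.is_snv], CFG)
        rev_hits = scan({genome.contig_id: flipped}, remapped, CFG)
        key = lambda hs: sorted(
            (h.variant.variant_id, h.seed_pos, h.spacer_ref, h.spacer_alt,
             h.pam.motif) for h in hs)
        assert key(fwd_hits) == key(rev_hits)
        strands = {h.variant.variant_id: h.pam.strand for h in fwd_hits}
        for h in rev_hits:
            assert h.pam.strand is strands[h.variant.variant_id].opposite

    def test_enlarging_seed_window_never_removes_hits(self):
        truth = generate_toy_genome(2500, 5, 6, 3, seed=9)
        small = scan(truth.genome_map, truth.variants, ScanConfig(seed_size=3))
        large = scan(truth.genome_map, truth.variants, ScanConfig(seed_size=5))
        key = lambda h: (h.variant.variant_id, h.pam.start, h.pam.strand.value)
        assert {key(h) for h in small} <= {key(h) for h in large}


class TestExcludeCommonPam:
    def _common(self, pos, af):
        return VariantRecord("chr_toy", pos, f"common{pos}", "T", "C", af=af)

    def test_common_variant_in_pam_removes_hit(self, toy_hit):
        removed = []
        kept = exclude_common_pam([toy_hit], [self._common(4, 0.30)], CFG,
                                  removed=removed)
        assert kept == []
        assert removed[0][1].variant_id == "common4"

    def test_rare_variant_keeps_hit(self, toy_hit):
        assert exclude_common_pam([toy_hit], [self._common(4, 0.001)], CFG) == [toy_hit]

    def test_seed_variant_keeps_hit_by_default(self, toy_hit):
        assert exclude_common_pam([toy_hit], [self._common(9, 0.30)], CFG) == [toy_hit]

    def test_seed_variant_removes_hit_with_include_seed(self, toy_hit):
        kept = exclude_common_pam([toy_hit], [self._common(9, 0.30)], CFG,
                                  include_seed=True)
        assert kept == []

    def test_unknown_af_never_excludes(self, toy_hit):
        assert exclude_common_pam([toy_hit], [self._common(4, None)], CFG) == [toy_hit]

    def test_empty_common_set_is_identity(self, toy_hit):
        assert exclude_common_pam([toy_hit], [], CFG) == [toy_hit]

    def test_raising_threshold_never_removes_a_retained_hit(self, toy_hit):
        commons = [self._common(4, 0.05)]
        for low, high in [(0.01, 0.1), (0.001, 0.05), (0.04, 0.06)]:
            kept_low = exclude_common_pam([toy_hit], commons,
                                          ScanConfig(af_threshold=low))
            kept_high = exclude_common_pam([toy_hit], commons,
                                           ScanConfig(af_threshold=high))
            assert set(id(h) for h in kept_low) <= set(id(h) for h in kept_high)


class TestKeywordFilter:
    def test_case_insensitive_substring_match(self, toy_hit):
        assert keyword_filter([toy_hit], ["melanoma"]) == [toy_hit]

    def test_non_matching_keyword_drops_hit(self, toy_genome):
        v = VariantRecord("chr_toy", 9, ".", "A", "G",
                          info={"CLNDN": "Cystic fibrosis"})
        hits = scan({"chr_toy": toy_genome}, [v], CFG)
        assert keyword_filter(hits, ["carcinoma"]) == []

    def test_empty_keyword_list_keeps_all(self, toy_hit):
        assert keyword_filter([toy_hit], []) == [toy_hit]
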