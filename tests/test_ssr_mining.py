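"""SSR detection, motif canonicalization, compound merging, PAL pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_tracts
from ssrpipe import (
    ContigSet,
    DetectorConfig,
    canonical_motif,
    classify_periods,
    filter_pal,
    find_ssrs,
    merge_compound,
    ssr_density,
)
from ssrpipe.ssr_mining import SSRComponent, SSRLocus


def make_contig(seq: str, cid: str = "c1") -> ContigSet:
    return ContigSet([(cid, seq)])


def spans(loci):
    return {(l.span[0], l.span[1], l.first_period) for l in loci}


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "word,canon,primitive",
        [
            ("TAA", "AAT", True),
            ("ATAT", "ATAT", False),
            ("CGTC", "CCGT", True),
            ("A", "A", True),
            ("AAA", "AAA", False),
            ("ACGTA", "AACGT", True),
        ],
    )
    def test_examples(self, word, canon, primitive):
        assert canonical_motif(word) == (canon, primitive)

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("ANT")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_canonical_is_minimal_rotation_and_idempotent(self, word):
        canon, primitive = canonical_motif(word)
        rotations = {word[i:] + word[:i] for i in range(len(word))}
        assert canon == min(rotations)
        assert canonical_motif(canon)[0] == canon
        # brute-force primitivity: word equals a strict power of some prefix?
        power = any(
            word == word[:d] * (len(word) // d)
            for d in range(1, len(word))
            if len(word) % d == 0
        )
        assert primitive == (not power)


class TestFindSSRs:
    def test_simple_dinucleotide(self):
        cfg = DetectorConfig(min_repeats_detect=5, min_tract_length=10)
        loci = find_ssrs(make_contig("ATATATATAT"), cfg)
        assert len(loci) == 1
        (locus,) = loci
        assert locus.span == (0, 10)
        assert locus.components[0].motif == "AT"
        assert locus.components[0].repeats == 5

    def test_homopolymer_discarded(self):
        loci = find_ssrs(make_contig("A" * 30), DetectorConfig())
        assert loci == []

    def test_homopolymer_not_reported_under_rotated_period(self):
        # AAAA... must not surface as period-2 "AA" etc.
        cfg = DetectorConfig(min_repeats_detect=2, min_tract_length=4)
        assert find_ssrs(make_contig("A" * 40), cfg) == []

    def test_partial_trailing_unit_in_span_not_repeats(self):
        cfg = DetectorConfig(min_repeats_detect=5, min_tract_length=10)
        loci = find_ssrs(make_contig("ATCATCATCATCATCAT"), cfg)  # 5 units + "AT"
        (locus,) = loci
        assert locus.span == (0, 17)
        assert locus.components[0].repeats == 5

    def test_n_breaks_tracts(self):
        cfg = DetectorConfig(min_repeats_detect=5, min_tract_length=10)
        assert find_ssrs(make_contig("ATATANATATATATATAT"), cfg) != []
        assert find_ssrs(make_contig("ATATANATATAN"), cfg) == []

    def test_flanks_measured_to_contig_ends(self):
        cfg = DetectorConfig(min_repeats_detect=5, min_tract_length=10)
        seq = "GCCGA" + "AT" * 6 + "CGGCG"
        (locus,) = find_ssrs(make_contig(seq), cfg)
        assert locus.left_flank == 5
        assert locus.right_flank == 5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
        cfg = DetectorConfig(min_repeats_detect=3, min_tract_length=6)
        got = spans(find_ssrs(make_contig(seq), cfg))
        expected = brute_force_tracts(
            seq, min_period=2, max_period=5, min_repeats=3, min_length=6
        )
        assert got == expected


class TestMergeCompound:
    def _locus(self, start, end, period=3, contig_len=2000):
        comp = SSRComponent("AAT", "AAT", period, (end - start) // period, (start, end))
        return SSRLocus("c1", (start, end), (comp,), start, contig_len - end)

    def test_four_tracts_chain_into_one_compound(self):
        # gap pattern 4, 48, 71 between successive tracts
        starts_ends = [(100, 133), (137, 152), (200, 233), (304, 346)]
        loci = [self._locus(s, e) for s, e in starts_ends]
        merged = merge_compound(loci, DetectorConfig())
        assert len(merged) == 1
        assert merged[0].is_compound
        assert len(merged[0].components) == 4
        assert merged[0].span == (100, 346)

    def test_gap_exactly_100_not_merged(self):
        loci = [self._locus(100, 130), self._locus(230, 260)]
        merged = merge_compound(loci, DetectorConfig())
        assert len(merged) == 2

    def test_gap_99_merged(self):
        loci = [self._locus(100, 130), self._locus(229, 259)]
        merged = merge_compound(loci, DetectorConfig())
        assert len(merged) == 1

    def test_two_tract_compound_preserves_gap_in_motif_string(self):
        loci = [self._locus(0, 21), self._locus(78, 96)]
        (merged,) = merge_compound(loci, DetectorConfig())
        assert " 57 " in merged.motif_string

    def test_idempotent(self):
        loci = [self._locus(100, 130), self._locus(160, 190), self._locus(500, 530)]
        once = merge_compound(loci, DetectorConfig())
        twice = merge_compound(once, DetectorConfig())
        assert once == twice

    def test_overlapping_input_rejected(self):
        loci = [self._locus(100, 130), self._locus(120, 150)]
        with pytest.raises(ValueError):
            merge_compound(loci, DetectorConfig())

    def test_compound_flanks_span_contig(self):
        (merged,) = merge_compound(
            [self._locus(100, 130), self._locus(150, 180)], DetectorConfig()
        )
        assert merged.left_flank == 100
        assert merged.right_flank == 2000 - 180


class TestFilterPal:
    def _contig_with_tract(self, left, repeats, right, motif="AAT"):
        rng = np.random.default_rng(1)
        flank_l = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=left)])
        flank_r = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=right)])
        seq = flank_l + motif * repeats + flank_r
        return make_contig(seq), len(flank_l)

    def test_low_repeat_locus_rejected_with_reason(self):
        cfg = DetectorConfig(min_repeats_detect=4, min_tract_length=12)
        contigs, _ = self._contig_with_tract(100, 4, 100)
        loci = merge_compound(find_ssrs(contigs, cfg), cfg)
        pal, rejects = filter_pal(loci, contigs, cfg)
        assert pal == []
        assert [r.reason for r in rejects] == ["min_repeats"]

    def test_short_flank_rejected_with_reason(self):
        cfg = DetectorConfig()
        contigs, _ = self._contig_with_tract(10, 7, 200)
        loci = merge_compound(find_ssrs(contigs, cfg), cfg)
        pal, rejects = filter_pal(loci, contigs, cfg)
        assert pal == []
        assert [r.reason for r in rejects] == ["flank"]

    def test_every_locus_lands_in_exactly_one_output(self):
        cfg = DetectorConfig()
        contigs, _ = self._contig_with_tract(200, 8, 200)
        loci = merge_compound(find_ssrs(contigs, cfg), cfg)
        always_fail = lambda locus, ctgs: False
        pal, rejects = filter_pal(loci, contigs, cfg, primer_check=always_fail)
        assert len(pal) + len(rejects) == len(loci)

    def test_primer_hook_controls_retention(self):
        cfg = DetectorConfig()
        contigs, _ = self._contig_with_tract(200, 8, 200)
        loci = merge_compound(find_ssrs(contigs, cfg), cfg)
        pal, _ = filter_pal(loci, contigs, cfg, primer_check=lambda l, c: True)
        assert len(pal) == len(loci)


class TestClassifyAndDensity:
    def test_one_of_each_period(self):
        loci = []
        for period, motif in [(2, "AT"), (3, "AAT"), (4, "AATG"), (5, "AATGC")]:
            comp = SSRComponent(motif, motif, period, 6, (0, 6 * period))
            loci.append(SSRLocus("c", (0, 6 * period), (comp,), 0, 0))
        dist = classify_periods(loci)
        assert all(cnt == 1 and pct == 25.0 for cnt, pct in dist.values())

    def test_empty_input_all_zero(self):
        dist = classify_periods([])
        assert all(cnt == 0 and pct == 0.0 for cnt, pct in dist.values())

    def test_density_examples(self):
        assert round(ssr_density(288, 1_635_000)[0], 2) == 0.18
        assert round(ssr_density(93, 1_635_000)[0], 2) == 0.06
        assert ssr_density(0, 1000)[0] == 0.0

    def test_density_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            ssr_density(5, 0)
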