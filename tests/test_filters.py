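"""End-trimming, core-run, regional selection and slide-tie rules."""

import pytest

from triplexkit import (
    Frame,
    SearchParams,
    SequenceRecord,
    Strand,
    find_purine_tracts,
    search_triplexes,
)
from triplexkit.filters import (
    apply_filters,
    passes_core_run,
    resolve_slide_ties,
    select_by_region,
    trim_to_matched_ends,
)
from triplexkit.search import PurineTract, TriplexCandidate, scan_pair

from conftest import hit_keys, random_instance


def make_candidate(
    mask,
    tts_offset=0,
    tfo_start=0,
    tract_seq=None,
    frame=Frame.PARALLEL_PYRIMIDINE,
    tract_start=0,
):
    length = len(mask)
    if tract_seq is None:
        tract_seq = "A" * (tts_offset + length + 2)
    tract = PurineTract(
        "d", Strand.PLUS, tract_start, tract_start + len(tract_seq), tract_seq
    )
    return TriplexCandidate(
        tract=tract,
        rna_id="r",
        tts_offset=tts_offset,
        tfo_start=tfo_start,
        tfo_end=tfo_start + length,
        frame=frame,
        mask=mask,
    )


class TestTrim:
    def test_leading_zero_is_stripped(self):
        c = trim_to_matched_ends(make_candidate("011111111", tfo_start=5))
        assert c.mask == "11111111"
        assert c.tts_offset == 1
        assert (c.tfo_start, c.tfo_end) == (6, 14)

    def test_all_matched_is_unchanged(self):
        c0 = make_candidate("1111111")
        assert trim_to_matched_ends(c0) == c0

    def test_both_ends_stripped(self):
        c = trim_to_matched_ends(make_candidate("00110"))
        assert c.mask == "11"
        assert c.tts_offset == 2

    def test_all_mismatch_vanishes(self):
        assert trim_to_matched_ends(make_candidate("000")) is None

    def test_antiparallel_trims_the_far_rna_end(self):
        c = trim_to_matched_ends(
            make_candidate("0111", tfo_start=10, frame=Frame.ANTIPARALLEL_MIXED)
        )
        # TTS 5' trim removes the RNA 3' end for an antiparallel frame
        assert (c.tfo_start, c.tfo_end) == (10, 13)
        assert c.tts_offset == 1


class TestCoreRun:
    @pytest.mark.parametrize(
        "mask,ok",
        [
            ("1111110111111", False),  # runs of 6 and 6
            ("11111110111", True),  # run of 7
            ("1111111", True),  # exactly the floor
            ("1" * 20, True),
        ],
    )
    def test_seven_consecutive_matches_required(self, mask, ok):
        assert passes_core_run(make_candidate(mask)) is ok


class TestRegionSelection:
    def test_equal_error_keeps_only_longest(self):
        # both at 10% error over the same region: only the 20-mer stays
        long = make_candidate(
            "1" * 10 + "0" + "1" * 4 + "0" + "1" * 4, tract_seq="A" * 22
        )
        short = make_candidate("1" * 8 + "01", tract_seq="A" * 22)
        kept = select_by_region([long, short])
        assert kept == [long]

    def test_lower_error_shorter_candidate_survives(self):
        long = make_candidate("1" * 9 + "011", tract_seq="A" * 14)  # 1/12
        short = make_candidate("1" * 10, tract_seq="A" * 14)  # 0/10
        kept = select_by_region([long, short])
        assert set(map(id, kept)) == {id(long), id(short)}

    def test_identical_sequences_at_distinct_loci_are_both_kept(self):
        a = make_candidate("1" * 8, tract_start=0)
        b = make_candidate("1" * 8, tract_start=100)
        assert len(select_by_region([a, b])) == 2

    def test_non_overlapping_tfo_prevents_conflict(self):
        a = make_candidate("1" * 8, tfo_start=0, tract_seq="A" * 12)
        b = make_candidate("1" * 10, tfo_start=50, tract_seq="A" * 12)
        assert len(select_by_region([a, b])) == 2


class TestSlideTies:
    def test_even_tts_odd_tfo_keeps_two_central_placements(self):
        # TTS run of 10 A against a 7-U TFO: four raw offsets, keep two
        cands = [
            make_candidate("1" * 7, tts_offset=k, tfo_start=0, tract_seq="A" * 10)
            for k in range(4)
        ]
        kept = resolve_slide_ties(cands)
        assert sorted(c.tts_offset for c in kept) == [1, 2]

    def test_odd_odd_keeps_single_central_placement(self):
        cands = [
            make_candidate("1" * 7, tts_offset=k, tfo_start=0, tract_seq="A" * 9)
            for k in range(3)
        ]
        kept = resolve_slide_ties(cands)
        assert [c.tts_offset for c in kept] == [1]

    def test_singleton_untouched(self):
        c = make_candidate("1" * 8)
        assert resolve_slide_ties([c]) == [c]

    def test_search_resolves_homopolymer_slide(self):
        # per frame using the TA:U code, 4 placements collapse to 2
        hits = search_triplexes(
            SequenceRecord.dna("AAAAAAAAAACC"), SequenceRecord.rna("U" * 7)
        )
        per_frame = {}
        for h in hits:
            per_frame.setdefault(h.frame, []).append(h)
        for frame, fh in per_frame.items():
            assert sorted(h.tts_start for h in fh) == [2, 3], frame


class TestFilterChain:
    def params(self):
        return SearchParams()

    def scan_candidates(self, seed):
        dna, rna, params = random_instance(seed)
        cands = []
        for tract in find_purine_tracts(dna, params.min_consecutive):
            for frame in Frame:
                cands.extend(scan_pair(tract, rna, frame, params))
        return cands, params

    @pytest.mark.parametrize("seed", [1, 4, 8, 15])
    def test_idempotent(self, seed):
        cands, params = self.scan_candidates(seed)
        once = apply_filters(cands, params)
        twice = apply_filters(once, params)
        assert [c.mask for c in twice] == [c.mask for c in once]
        assert twice == once

    @pytest.mark.parametrize("seed", [2, 6, 13])
    def test_order_independent(self, seed):
        cands, params = self.scan_candidates(seed)
        fwd = apply_filters(cands, params)
        rev = apply_filters(list(reversed(cands)), params)
        assert fwd == rev

    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_survivors_satisfy_all_rules(self, seed):
        cands, params = self.scan_candidates(seed)
        for c in apply_filters(cands, params):
            assert c.mask[0] == "1" and c.mask[-1] == "1"
            assert max(len(r) for r in c.mask.split("0")) >= 7
            assert c.length >= params.min_consecutive
            assert params.within_budget(c.mismatches, c.length)

    def test_chain_never_increases_count(self):
        cands, params = self.scan_candidates(30)
        assert len(apply_filters(cands, params)) <= len(cands)
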