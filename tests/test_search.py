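"""Purine-tract extraction, diagonal scanning, stats and full search."""

import pytest
from fractions import Fraction

from triplexkit import (
    Frame,
    SearchParams,
    SequenceRecord,
    Strand,
    compute_stats,
    find_purine_tracts,
    scan_pair,
    search_triplexes,
)
from triplexkit.search import PurineTract
from triplexkit.sequences import AlphabetError, reverse_complement
from triplexkit.synthetic import plant_triplex

from conftest import hit_keys


class TestSearchParams:
    def test_defaults(self):
        p = SearchParams()
        assert p.min_consecutive == 7
        assert p.max_error_rate == Fraction(1, 5)

    def test_float_error_rate_is_exact(self):
        assert SearchParams(max_error_rate=0.2).max_error_rate == Fraction(1, 5)
        # 4/20 is accepted, 5/20 is not, exactly
        p = SearchParams()
        assert p.within_budget(4, 20) and not p.within_budget(5, 20)

    def test_validation(self):
        with pytest.raises(ValueError):
            SearchParams(min_consecutive=6)
        with pytest.raises(ValueError):
            SearchParams(max_error_rate=1.5)


class TestPurineTracts:
    def test_plus_strand_runs(self):
        tr = find_purine_tracts(SequenceRecord.dna("AAGGTTAAGG"), 4)
        assert [(t.strand, t.start, t.end) for t in tr] == [
            (Strand.PLUS, 0, 4),
            (Strand.PLUS, 6, 10),
        ]
        assert [t.purine_seq for t in tr] == ["AAGG", "AAGG"]

    def test_minus_strand_is_reverse_complement(self):
        tr = find_purine_tracts(SequenceRecord.dna("CCTTCC"), 1)
        assert [(t.strand, t.start, t.end, t.purine_seq) for t in tr] == [
            (Strand.MINUS, 0, 6, "GGAAGG")
        ]

    def test_whole_sequence_tract(self):
        tr = find_purine_tracts(SequenceRecord.dna("AGAGAGAG"), 7)
        assert [(t.strand, t.start, t.end) for t in tr] == [(Strand.PLUS, 0, 8)]

    def test_tracts_are_maximal(self):
        tr = find_purine_tracts(SequenceRecord.dna("CAGGAGTCCAG"), 1)
        seq = "CAGGAGTCCAG"
        for t in tr:
            if t.strand is Strand.PLUS:
                assert t.start == 0 or seq[t.start - 1] not in "AG"
                assert t.end == len(seq) or seq[t.end] not in "AG"
            else:
                assert t.start == 0 or seq[t.start - 1] not in "CT"
                assert t.end == len(seq) or seq[t.end] not in "CT"


class TestScanPair:
    def tract(self, purine):
        return PurineTract("d", Strand.PLUS, 0, len(purine), purine)

    def test_perfect_diagonal(self):
        cands = scan_pair(
            self.tract("GGAAGGAAGGAA"),
            SequenceRecord.rna("CCUUCCUUCCUU"),
            Frame.PARALLEL_PYRIMIDINE,
            SearchParams(),
        )
        full = [c for c in cands if c.length == 12]
        assert len(full) == 1
        assert full[0].mask == "1" * 12
        assert (full[0].tfo_start, full[0].tfo_end) == (0, 12)

    def test_mismatch_within_budget_spans_the_gap(self):
        # mismatch at triplet 8; the 12-mer window carries it at 1/12 error
        cands = scan_pair(
            self.tract("GGAAGGAAGGAA"),
            SequenceRecord.rna("CCUUCCUACCUU"),
            Frame.PARALLEL_PYRIMIDINE,
            SearchParams(max_error_rate=0.10),
        )
        masks = {c.mask for c in cands if c.tts_offset == 0}
        assert "111111101111" in masks  # spans the gap
        assert "1111111" in masks  # the error-free prefix run

    def test_zero_budget_restarts_after_mismatch(self):
        cands = scan_pair(
            self.tract("GGAAGGAAGGAA"),
            SequenceRecord.rna("CCUUCCUACCUU"),
            Frame.PARALLEL_PYRIMIDINE,
            SearchParams(max_error_rate=0),
        )
        # only pure runs survive a zero budget: lengths 7 and 4 on the main
        # diagonal, never the gap-spanning 12
        diag = [c for c in cands if c.tts_offset - c.tfo_start == 0]
        assert sorted(c.length for c in diag) == [4, 7]
        assert all(set(c.mask) == {"1"} for c in diag)

    def test_antiparallel_reverses_the_rna(self):
        cands = scan_pair(
            self.tract("GGGAAA"),
            SequenceRecord.rna("AAAGGG"),
            Frame.ANTIPARALLEL_PURINE,
            SearchParams(),
        )
        full = [c for c in cands if c.length == 6]
        assert len(full) == 1
        assert full[0].mask == "111111"
        assert (full[0].tfo_start, full[0].tfo_end) == (0, 6)


class TestComputeStats:
    def test_error_rate_from_mask(self):
        tract = PurineTract("d", Strand.PLUS, 0, 12, "GGAAGGAAGGAA")
        rna = SequenceRecord.rna("CCUUCCUACCUU")
        cand = scan_pair(
            tract, rna, Frame.PARALLEL_PYRIMIDINE, SearchParams(max_error_rate=0.1)
        )
        c12 = next(c for c in cand if c.length == 12)
        err, gu = compute_stats(c12, rna)
        assert err == pytest.approx(100 / 12)
        assert gu == pytest.approx(100 * 5 / 12)  # 5 U (one U replaced by A)

    def test_gu_percent_all_g(self):
        tract = PurineTract("d", Strand.PLUS, 0, 7, "G" * 7)
        rna = SequenceRecord.rna("G" * 7)
        cand = scan_pair(tract, rna, Frame.PARALLEL_MIXED, SearchParams())
        c7 = next(c for c in cand if c.length == 7)
        err, gu = compute_stats(c7, rna)
        assert (err, gu) == (0.0, 100.0)


class TestSearchTriplexes:
    def test_perfect_pair_top_hit(self, perfect_pair):
        dna, rna = perfect_pair
        hits = search_triplexes(dna, rna, SearchParams(max_error_rate=0))
        assert hits
        top = hits[0]
        assert (top.tts_start, top.tts_end) == (1, 12)
        assert (top.tfo_start, top.tfo_end) == (1, 12)
        assert top.tts_strand is Strand.PLUS
        assert top.length == 12
        assert top.error_rate == 0.0
        assert top.gu_percent == pytest.approx(50.0)

    def test_no_code_for_poly_pyrimidine_dna(self):
        hits = search_triplexes(
            SequenceRecord.dna("C" * 12), SequenceRecord.rna("U" * 12)
        )
        assert hits == []

    def test_below_minimum_length_is_empty(self):
        assert (
            search_triplexes(
                SequenceRecord.dna("GGAAGG"), SequenceRecord.rna("CCUUCC")
            )
            == []
        )

    def test_minus_strand_antiparallel_mapping(self):
        # plus-strand C/T block = minus-strand purine tract GGGGAAAA
        dna = SequenceRecord.dna("TTTTTTCCCCGG")
        rna = SequenceRecord.rna("CAAAAGGGGC")
        hits = search_triplexes(dna, rna)
        assert any(
            h.tts_strand is Strand.MINUS
            and h.frame is Frame.ANTIPARALLEL_PURINE
            and h.tts_seq == "GGGGAAAA"
            and h.tfo_seq == "AAAAGGGG"
            and (h.tts_start, h.tts_end) == (3, 10)
            and (h.tfo_start, h.tfo_end) == (2, 9)
            for h in hits
        )

    def test_hit_invariants_on_planted_instances(self):
        params = SearchParams()
        for seed in range(12):
            frame = list(Frame)[seed % 4]
            n_err = seed % 3
            dna, rna, truth = plant_triplex(
                160, 120, 15, frame, n_err, seed=seed
            )
            for h in search_triplexes(dna, rna, params):
                assert set(h.tts_seq) <= {"A", "G"}
                assert h.mask[0] == "1" and h.mask[-1] == "1"
                assert max(len(r) for r in h.mask.split("0")) >= 7
                assert h.length >= params.min_consecutive
                assert params.within_budget(h.mismatches, h.length)
                assert 0 <= h.gu_percent <= 100
                assert h.length == len(h.mask) == len(h.tts_seq) == len(h.tfo_seq)
                assert h.tts_end - h.tts_start + 1 == h.length
                assert h.tfo_end - h.tfo_start + 1 == h.length

    def test_strand_symmetry(self):
        for seed in (3, 11, 27):
            dna, rna, _ = plant_triplex(
                120, 90, 12, Frame.PARALLEL_MIXED, 1, seed=seed
            )
            rc = SequenceRecord.dna(reverse_complement(dna.residues), dna.id)
            fwd = search_triplexes(dna, rna)
            rev = search_triplexes(rc, rna)
            n = len(dna)

            def mirrored(hits):
                out = set()
                for h in hits:
                    s = n - h.tts_end + 1
                    e = n - h.tts_start + 1
                    strand = "-" if h.tts_strand is Strand.PLUS else "+"
                    out.add(
                        (s, e, strand, h.tfo_start, h.tfo_end, h.frame.name, h.mask)
                    )
                return out

            got = {
                (h.tts_start, h.tts_end, h.tts_strand.value, h.tfo_start,
                 h.tfo_end, h.frame.name, h.mask)
                for h in rev
            }
            assert got == mirrored(fwd)

    def test_relaxing_budget_never_uncovers_a_region(self):
        """Regions reported at a tight budget stay covered at a looser one."""
        for seed in (5, 9):
            dna, rna, _ = plant_triplex(
                150, 110, 14, Frame.PARALLEL_PYRIMIDINE, 1, seed=seed
            )
            tight = search_triplexes(dna, rna, SearchParams(max_error_rate=0.1))
            loose = search_triplexes(dna, rna, SearchParams(max_error_rate=0.2))
            for h in tight:
                assert any(
                    g.tts_start <= h.tts_end
                    and h.tts_start <= g.tts_end
                    and g.tfo_start <= h.tfo_end
                    and h.tfo_start <= g.tfo_end
                    for g in loose
                ), f"hit {h} lost at looser budget"

    def test_deterministic_order(self):
        dna, rna, _ = plant_triplex(150, 110, 12, Frame.ANTIPARALLEL_MIXED, 0, seed=2)
        assert hit_keys(search_triplexes(dna, rna)) == hit_keys(
            search_triplexes(dna, rna)
        )

    def test_invalid_alphabet_names_position(self):
        with pytest.raises(AlphabetError) as exc:
            SequenceRecord.dna("ACGNACG")
        assert exc.value.position == 4
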