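import numpy as np
import pytest

from _oracles import oracle_find_tsd
from conftest import make_locus, random_seq
from pseudoscan.signatures import (
    StructuralGroup,
    TruncationCall,
    TsdParams,
    annotate_repeat,
    call_truncation,
    classify,
    detect_gaps,
    detect_polya,
    find_tsd,
    flag_inverted_chimera,
    rebuild_boundaries,
)
from pseudoscan.seqmodel import reverse_complement


def pick_base_not(rng, *avoid):
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def tsd_fixture(rng, copy, tsd, inter="", extended_tail=0):
    """Locus with `tsd` at the end of the upstream flank and after `inter`
    downstream; the bases abutting both occurrences are chosen so the
    planted segment cannot chance-extend, keeping its length exact."""
    left_guard = pick_base_not(rng, inter[-1] if inter else copy[-1])
    upstream = random_seq(rng, 99 - len(tsd)) + left_guard + tsd
    right_guard = pick_base_not(rng, copy[0])
    down_core = inter + tsd + right_guard + random_seq(rng, 39)
    downstream = down_core[:100]
    if extended_tail or len(down_core) > 100:
        extended = down_core + random_seq(rng, extended_tail)
    else:
        extended = downstream
    return make_locus(upstream, copy, downstream, extended)


class TestFindTsd:
    def test_planted_11mer_found_stage1(self, ref):
        rng = np.random.default_rng(0)
        locus = tsd_fixture(rng, ref.seq, "GCGATTTAAGC")
        call = find_tsd(locus)
        assert call is not None
        assert call.length == 11
        assert call.tsd_seq == "GCGATTTAAGC"
        assert call.stage == "exact_near"
        assert call.mismatches == 0

    def test_planted_9mer_is_below_default_minimum(self, ref):
        # "TSDs were required to be at least ten nucleotides long": a 9-mer
        # common segment never qualifies on its own; anything reported must
        # be a longer chance segment the brute-force oracle also finds
        rng = np.random.default_rng(1)
        for _ in range(20):
            planted = random_seq(rng, 9)
            locus = tsd_fixture(rng, ref.seq, planted)
            call = find_tsd(locus)
            oracle = oracle_find_tsd(
                locus.upstream, locus.copy_seq, locus.downstream,
                locus.downstream_extended,
            )
            assert (call is None) == (oracle is None)
            if call is not None:
                assert call.tsd_seq != planted
                assert call.length >= 10
                if call.stage == "mismatch_extended":
                    assert call.length >= 12

    def test_distant_tsd_found_in_extended_stage(self, ref):
        rng = np.random.default_rng(2)
        tsd = random_seq(rng, 13)
        inter = random_seq(rng, 800)
        locus = tsd_fixture(rng, ref.seq, tsd, inter=inter, extended_tail=500)
        call = find_tsd(locus)
        assert call is not None and call.stage == "exact_extended"
        assert call.tsd_seq == tsd
        boundaries = rebuild_boundaries(locus, call)
        assert len(boundaries.inter_region) == 800

    def test_mismatch_stage_requires_longer_segment(self, ref):
        rng = np.random.default_rng(3)
        seg = random_seq(rng, 14)
        mutated = seg[:7] + {"A": "C", "C": "A", "G": "T", "T": "G"}[seg[7]] + seg[8:]
        upstream = random_seq(rng, 86) + seg
        downstream = mutated + random_seq(rng, 86)
        locus = make_locus(upstream, ref.seq, downstream)
        call = find_tsd(locus)
        assert call is not None
        assert call.stage == "mismatch_extended"
        assert call.length == 14
        assert call.mismatches == 1

    @pytest.mark.parametrize("case", range(60))
    def test_agrees_with_bruteforce_oracle(self, ref, case):
        rng = np.random.default_rng(10_000 + case)
        kind = case % 3
        if kind == 0:  # planted near TSD, length 9-16
            locus = tsd_fixture(rng, ref.seq, random_seq(rng, int(rng.integers(9, 17))))
        elif kind == 1:  # planted distant TSD
            locus = tsd_fixture(
                rng,
                ref.seq,
                random_seq(rng, int(rng.integers(10, 17))),
                inter=random_seq(rng, int(rng.integers(150, 700))),
                extended_tail=300,
            )
        else:  # no planted TSD
            locus = make_locus(
                random_seq(rng, 100), ref.seq, random_seq(rng, 100)
            )
        call = find_tsd(locus)
        oracle = oracle_find_tsd(
            locus.upstream, locus.copy_seq, locus.downstream, locus.downstream_extended
        )
        if oracle is None:
            assert call is None
        else:
            seq, length, stage = oracle
            assert call is not None
            assert (call.tsd_seq, call.length, call.stage) == (seq, length, stage)

    def test_lowering_min_length_is_monotone(self, ref):
        rng = np.random.default_rng(5)
        for _ in range(20):
            locus = tsd_fixture(rng, ref.seq, random_seq(rng, int(rng.integers(10, 15))))
            strict = find_tsd(locus, TsdParams(min_tsd_length=12))
            loose = find_tsd(locus, TsdParams(min_tsd_length=8))
            if strict is not None:
                assert loose is not None
                assert loose.length >= strict.length


class TestRebuildBoundaries:
    def test_adjacent_tsd_gives_empty_inter_region(self, ref):
        rng = np.random.default_rng(6)
        locus = tsd_fixture(rng, ref.seq, random_seq(rng, 12))
        call = find_tsd(locus)
        boundaries = rebuild_boundaries(locus, call)
        assert boundaries.inter_region == ""

    def test_polya_tract_becomes_inter_region(self, ref):
        rng = np.random.default_rng(7)
        locus = tsd_fixture(rng, ref.seq, "GCTTGACGGTAC", inter="A" * 20)
        call = find_tsd(locus)
        boundaries = rebuild_boundaries(locus, call)
        assert boundaries.inter_region == "A" * 20

    def test_requires_tsd(self, ref):
        rng = np.random.default_rng(8)
        locus = make_locus(random_seq(rng, 100), ref.seq, random_seq(rng, 100))
        with pytest.raises(ValueError):
            rebuild_boundaries(locus, None)


class TestAnnotateRepeat:
    def test_planted_fragment_sense_and_antisense(self, library):
        l1 = next(e for e in library if e.id == "L1")
        fragment = l1.seq[-200:]
        rng = np.random.default_rng(9)
        pad = random_seq(rng, 30)
        sense = annotate_repeat(fragment + pad, library)
        assert sense is not None and (sense.family, sense.orientation) == ("L1", "sense")
        anti = annotate_repeat(reverse_complement(fragment) + pad, library)
        assert anti is not None and (anti.family, anti.orientation) == ("L1", "antisense")

    def test_random_region_matches_nothing(self, library):
        rng = np.random.default_rng(10)
        assert annotate_repeat(random_seq(rng, 300), library) is None

    def test_short_region_and_empty_library(self, library):
        rng = np.random.default_rng(11)
        assert annotate_repeat(random_seq(rng, 19), library) is None
        assert annotate_repeat(random_seq(rng, 100), []) is None


class TestDetectPolya:
    def test_all_a_positive(self):
        call = detect_polya("A" * 30)
        assert call is not None
        assert call.start_offset == 0 and call.length == 30 and call.a_fraction == 1.0

    def test_six_adenosines_per_window_is_negative(self):
        # "more than six adenosines" - six does not qualify; every 10-nt
        # window of this periodic sequence contains exactly 6 A
        assert detect_polya("AAAAAACCCC" * 4) is None

    def test_seven_in_first_window_positive(self):
        call = detect_polya("CAAAAAAAGT" + "CGCGCGCGCG" * 3)
        assert call is not None
        assert call.start_offset == 1  # trimmed to the outermost A
        assert call.length == 7

    def test_tail_must_start_within_30nt(self):
        assert detect_polya("GCGT" * 10 + "A" * 20) is None

    def test_substrate_shorter_than_window(self):
        assert detect_polya("AAAAA") is None


class TestTruncation:
    def test_positions_reported_against_reference_length(self, ref):
        from conftest import make_locus

        locus = make_locus("", ref.seq[:83], "", ref_start=1, ref_end=83)
        call = call_truncation(locus.alignment, ref)
        assert call.three_prime_truncated and not call.five_prime_truncated
        assert call.ref_end == 83

    def test_full_length_and_five_prime(self, ref):
        full = make_locus("", ref.seq, "", ref_start=1, ref_end=ref.length)
        c = call_truncation(full.alignment, ref)
        assert not c.three_prime_truncated and not c.five_prime_truncated
        fivep = make_locus("", ref.seq[39:], "", ref_start=40, ref_end=ref.length)
        c = call_truncation(fivep.alignment, ref)
        assert c.five_prime_truncated and not c.three_prime_truncated

    def test_tolerance_boundary(self, ref):
        # ref_end == length - tolerance is still full length
        edge = make_locus("", ref.seq[: ref.length - 5], "", ref_end=ref.length - 5)
        assert not call_truncation(edge.alignment, ref, tolerance=5).three_prime_truncated
        inside = make_locus("", ref.seq[: ref.length - 6], "", ref_end=ref.length - 6)
        assert call_truncation(inside.alignment, ref, tolerance=5).three_prime_truncated


class TestDetectGaps:
    def test_run_inside_boundaries(self, ref):
        rng = np.random.default_rng(12)
        locus = tsd_fixture(rng, ref.seq, "GCTTGACGGTAC", inter="N" * 10)
        call = find_tsd(locus)
        boundaries = rebuild_boundaries(locus, call)
        assert detect_gaps(locus, boundaries) is True

    def test_isolated_n_below_threshold(self, ref):
        rng = np.random.default_rng(13)
        locus = make_locus(
            random_seq(rng, 50) + "N" + random_seq(rng, 49), ref.seq, random_seq(rng, 100)
        )
        assert detect_gaps(locus) is False

    def test_gap_outside_boundaries_ignored(self, ref):
        rng = np.random.default_rng(14)
        tsd = "GCTTGACGGTAC"
        upstream = random_seq(rng, 88) + tsd
        downstream = tsd + random_seq(rng, 30) + "N" * 10 + random_seq(rng, 48)
        locus = make_locus(upstream, ref.seq, downstream)
        call = find_tsd(locus)
        boundaries = rebuild_boundaries(locus, call)
        assert detect_gaps(locus, boundaries) is False


def trunc(five=False, three=False, ref_start=1, ref_end=106):
    return TruncationCall(
        five_prime_truncated=five,
        three_prime_truncated=three,
        ref_start=ref_start,
        ref_end=ref_end,
    )


class TestClassify:
    def make_tsd(self):
        from pseudoscan.signatures import TsdCall

        return TsdCall("GCTTGACGGTAC", 88, 10, 12, "exact_near")

    def make_repeat(self, orientation="sense"):
        from pseudoscan.signatures import RepeatAnnotation

        return RepeatAnnotation("L1", orientation, 0, 200, 1.0, 200)

    def make_polya(self):
        from pseudoscan.signatures import PolyACall

        return PolyACall(0, 20, 1.0)

    def test_cascade_routing(self):
        tsd, repeat, polya = self.make_tsd(), self.make_repeat(), self.make_polya()
        cases = [
            # (tsd, repeat, polya, truncation, gap) -> expected label
            ((None, None, None, trunc(), False), StructuralGroup.ALONE),
            ((tsd, repeat, None, trunc(three=True, ref_end=60), False), StructuralGroup.REPEAT),
            ((tsd, None, polya, trunc(), False), StructuralGroup.POLYA),
            ((tsd, None, None, trunc(three=True, ref_end=60), False), StructuralGroup.THREE_PRIME_TRUNC),
            ((tsd, None, None, trunc(), False), StructuralGroup.TO_CHECK),
            ((None, None, None, trunc(five=True, ref_start=40), False), StructuralGroup.TO_CHECK),
            ((None, None, None, trunc(three=True, ref_end=60), False), StructuralGroup.TO_CHECK),
            ((tsd, repeat, None, trunc(), True), StructuralGroup.GAPS),
            # 5'-truncation overrides poly(A) but not a repeat explanation
            ((tsd, None, polya, trunc(five=True, ref_start=40), False), StructuralGroup.TO_CHECK),
            ((tsd, repeat, None, trunc(five=True, ref_start=40), False), StructuralGroup.REPEAT),
        ]
        for (t, r, p, tr, gap), expected in cases:
            assert classify(t, r, p, tr, gap).label is expected

    def test_subflags(self):
        c = classify(self.make_tsd(), None, None, trunc(), False)
        assert c.flags == ("full_length_tsd",)
        c = classify(None, None, None, trunc(five=True, ref_start=40), False)
        assert "five_prime_truncated" in c.flags

    def test_deterministic_and_total(self):
        for _ in range(3):
            c = classify(None, None, None, trunc(), False)
            assert c.label is StructuralGroup.ALONE

    def test_missing_evidence_is_an_error(self):
        with pytest.raises(ValueError):
            classify(None, None, None, None, False)


class TestInvertedChimera:
    def make(self, orientation, three):
        from pseudoscan.signatures import RepeatAnnotation, TsdCall

        tsd = TsdCall("GCTTGACGGTAC", 88, 10, 12, "exact_near")
        rep = RepeatAnnotation("L1", orientation, 0, 200, 1.0, 200)
        return tsd, rep, trunc(three=three, ref_end=60 if three else 106)

    def test_twin_priming_signature(self):
        tsd, rep, tr = self.make("antisense", True)
        assert flag_inverted_chimera(StructuralGroup.REPEAT, tsd, rep, tr) is True

    def test_sense_chimera_is_not_inverted(self):
        tsd, rep, tr = self.make("sense", True)
        assert flag_inverted_chimera(StructuralGroup.REPEAT, tsd, rep, tr) is False

    def test_full_length_antisense_is_not_inverted(self):
        tsd, rep, tr = self.make("antisense", False)
        assert flag_inverted_chimera(StructuralGroup.REPEAT, tsd, rep, tr) is False

    def test_non_repeat_copy_is_a_contract_error(self):
        tsd, rep, tr = self.make("antisense", True)
        with pytest.raises(ValueError):
            flag_inverted_chimera(StructuralGroup.ALONE, tsd, rep, tr)
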