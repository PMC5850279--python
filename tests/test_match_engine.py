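import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esmatch.match_engine import (
    base_frequencies,
    base_pairing_overlap,
    count_matches,
    count_matches_naive,
    matched_transcript_fraction,
    max_repeats,
    reverse_complement,
    window_count,
)

from conftest import make_segment, make_transcript, random_rna

rna = st.text(alphabet="ACGU", min_size=1, max_size=50)


class TestWindowCount:
    @pytest.mark.parametrize(
        "seq_len,k,expected", [(801, 7, 795), (7, 7, 1), (6, 7, 0), (0, 1, 0)]
    )
    def test_values(self, seq_len, k, expected):
        assert window_count(seq_len, k) == expected

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            window_count(10, 0)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "tract,expected", [("GGGCCCU", "AGGGCCC"), ("AUGC", "GCAU"), ("A", "U")]
    )
    def test_hand_examples(self, tract, expected):
        assert reverse_complement(tract) == expected

    @given(rna)
    @settings(deadline=None)
    def test_involution(self, tract):
        assert reverse_complement(reverse_complement(tract)) == tract


class TestCountMatches:
    def test_poly_g_vs_poly_c_antisense(self):
        seg = make_segment("GGGGGGG")
        t = make_transcript(cds="CCCCCCCC")
        tally = count_matches(
            [seg], [t], k_range=(7, 7), orientations=("antisense", "sense")
        )
        assert tally.count("ESL7", "cds", 7, "antisense") == 2  # positions 0 and 1
        assert tally.count("ESL7", "cds", 7, "sense") == 0

    def test_sense_matches_identity(self):
        seg = make_segment("GGGGGGG")
        t = make_transcript(cds="GGGGGGGG")
        tally = count_matches(
            [seg], [t], k_range=(7, 7), orientations=("antisense", "sense")
        )
        assert tally.count("ESL7", "cds", 7, "sense") == 2
        assert tally.count("ESL7", "cds", 7, "antisense") == 0

    def test_windows_containing_n_never_match(self):
        seg = make_segment("GGGNGGG")
        t = make_transcript(cds="CCCNCCC" + "CCCCCCC")
        tally = count_matches(
            [seg], [t], k_range=(4, 7), orientations=("antisense", "sense")
        )
        # every segment window of k >= 4 includes the N -> nothing can match
        assert all(k < 4 for (_s, _sec, k, _o) in tally.cells)

    def test_empty_k_range_rejected(self):
        with pytest.raises(ValueError):
            count_matches([make_segment("GGGG")], [make_transcript()], k_range=(8, 7))

    def test_monotone_in_k_and_consistent_per_transcript(self, rng):
        seg = make_segment(random_rna(rng, 60))
        ts = [
            make_transcript(
                random_rna(rng, 40), random_rna(rng, 80), random_rna(rng, 40), f"t{i}"
            )
            for i in range(5)
        ]
        tally = count_matches(
            [seg], ts, k_range=(2, 10), orientations=("antisense", "sense")
        )
        tally.validate()  # raises on monotonicity / consistency violation

    def test_additivity_over_transcript_subsets(self, rng):
        seg = make_segment(random_rna(rng, 50))
        ts = [
            make_transcript(
                random_rna(rng, 30), random_rna(rng, 60), random_rna(rng, 30), f"t{i}"
            )
            for i in range(6)
        ]
        whole = count_matches([seg], ts, k_range=(3, 6))
        part_a = count_matches([seg], ts[:3], k_range=(3, 6))
        part_b = count_matches([seg], ts[3:], k_range=(3, 6))
        for cell in set(whole.cells) | set(part_a.cells) | set(part_b.cells):
            assert whole.cells.get(cell, 0) == part_a.cells.get(cell, 0) + part_b.cells.get(cell, 0)

    def test_duplicating_transcripts_doubles_counts(self, rng):
        seg = make_segment(random_rna(rng, 50))
        ts = [make_transcript(cds=random_rna(rng, 80))]
        doubled = [
            make_transcript(cds=ts[0].cds.residues, transcript_id="t1"),
            make_transcript(cds=ts[0].cds.residues, transcript_id="t2"),
        ]
        one = count_matches([seg], ts, k_range=(3, 6))
        two = count_matches([seg], doubled, k_range=(3, 6))
        for cell, c in one.cells.items():
            assert two.cells.get(cell, 0) == 2 * c

    def test_indexed_equals_naive_on_random_instances(self, rng):
        """Oracle equivalence on small random instances, both orientations."""
        for _ in range(30):
            seg_len = int(rng.integers(10, 80))
            seg = make_segment(random_rna(rng, seg_len, gc=rng.uniform(0.2, 0.8)))
            t = make_transcript(
                random_rna(rng, int(rng.integers(7, 50))),
                random_rna(rng, int(rng.integers(7, 60))),
                random_rna(rng, int(rng.integers(7, 50))),
            )
            fast = count_matches(
                [seg], [t], k_range=(2, 9), orientations=("antisense", "sense")
            )
            slow = count_matches_naive(
                [seg], [t], k_range=(2, 9), orientations=("antisense", "sense")
            )
            assert fast.cells == slow.cells
            assert fast.per_transcript == slow.per_transcript

    def test_antisense_symmetric_under_role_swap(self, rng):
        """Swapping segment and sector roles (both reverse-complemented) is neutral."""
        s_res = random_rna(rng, 30)
        t_res = random_rna(rng, 40)
        a = count_matches(
            [make_segment(s_res, "S")],
            [make_transcript(cds=t_res)],
            k_range=(3, 8),
        )
        b = count_matches(
            [make_segment(reverse_complement(t_res), "S")],
            [make_transcript(cds=reverse_complement(s_res))],
            k_range=(3, 8),
        )
        for k in range(3, 9):
            assert a.count("S", "cds", k) == b.count("S", "cds", k)

    def test_unique_windows_deduplicates_repeated_tracts(self):
        seg = make_segment("GGGGGGGG")  # two identical 7-nt windows
        t = make_transcript(cds="CCCCCCC")
        full = count_matches([seg], [t], k_range=(7, 7))
        dedup = count_matches([seg], [t], k_range=(7, 7), unique_windows=True)
        assert full.count("ESL7", "cds", 7) == 2
        assert dedup.count("ESL7", "cds", 7) == 1

    def test_maximal_only_counts_non_extendable_matches(self):
        # 8 G vs 8 C: of the four 7-mer (window, position) pairs, the two
        # nested inside the 8-mer duplex are extendable; the two alignments
        # hanging off the duplex ends ((0,0) and (1,1)) cannot extend in
        # either direction and stay. At k=8 exactly one alignment exists.
        seg = make_segment("GGGGGGGG")
        t = make_transcript(cds="CCCCCCCC")
        tally = count_matches([seg], [t], k_range=(7, 8), maximal_only=True)
        assert tally.count("ESL7", "cds", 7) == 2
        assert tally.count("ESL7", "cds", 8) == 1
        exhaustive = count_matches([seg], [t], k_range=(7, 8))
        assert exhaustive.count("ESL7", "cds", 7) == 4


class TestMatchedTranscriptFraction:
    def _tally(self, transcripts):
        seg = make_segment("GGGGGGG", "S")
        return seg, count_matches([seg], transcripts, k_range=(7, 7))

    def test_all_matched(self):
        seg, tally = self._tally(
            [make_transcript(cds="CCCCCCC", transcript_id=f"t{i}") for i in range(4)]
        )
        assert matched_transcript_fraction(tally, "S", 7) == 1.0

    def test_none_matched(self):
        seg, tally = self._tally(
            [make_transcript(cds="AAAAAAA", transcript_id=f"t{i}") for i in range(4)]
        )
        assert matched_transcript_fraction(tally, "S", 7) == 0.0

    def test_partial_fraction(self):
        ts = [
            make_transcript(
                cds="CCCCCCC" if i < 19 else "AAAAAAA", transcript_id=f"t{i}"
            )
            for i in range(20)
        ]
        _seg, tally = self._tally(ts)
        assert matched_transcript_fraction(tally, "S", 7) == pytest.approx(0.95)

    def test_unknown_segment_errors(self):
        _seg, tally = self._tally([make_transcript(cds="CCCCCCC")])
        with pytest.raises(KeyError):
            matched_transcript_fraction(tally, "nope", 7)


class TestMaxRepeats:
    def test_poly_c_run_counts_every_position(self):
        seg = make_segment("AAGGGGGGGAA", "S")
        t = make_transcript(utr3="CCCCCCCCCC")  # 10 C: 4 positions for a 7-mer
        tally = count_matches([seg], [t], k_range=(7, 7), record_tracts=True)
        tract, tid, count = max_repeats(tally, "S", 7)
        assert (tract, tid, count) == ("CCCCCCC", "t1", 4)

    def test_no_matches_gives_zero(self):
        seg = make_segment("GGGGGGG", "S")
        t = make_transcript()
        tally = count_matches([seg], [t], k_range=(7, 7), record_tracts=True)
        assert max_repeats(tally, "S", 7) == ("", "", 0)

    def test_requires_tract_recording(self):
        seg = make_segment("GGGGGGG", "S")
        tally = count_matches([seg], [make_transcript()], k_range=(7, 7))
        with pytest.raises(ValueError):
            max_repeats(tally, "S", 7)


class TestExpectedCountLaw:
    def test_pairing_overlap_uniform(self):
        p = {b: 0.25 for b in "ACGU"}
        assert base_pairing_overlap(p, p) == pytest.approx(0.25)

    def test_base_frequencies_exclude_ambiguity(self):
        freqs = base_frequencies("GGCCNN")
        assert freqs == {"A": 0.0, "C": 0.5, "G": 0.5, "U": 0.0}

    def test_observed_counts_near_expectation(self, rng):
        """iid sequences: counts within 3 SE of windows*windows*m^k."""
        seg_res = random_rna(rng, 300, gc=0.5)
        seg = make_segment(seg_res, "S")
        n_t, sec_len = 150, 400
        ts = [
            make_transcript(cds=random_rna(rng, sec_len), transcript_id=f"t{i}")
            for i in range(n_t)
        ]
        tally = count_matches([seg], ts, k_range=(5, 7))
        m = 0.25
        for k in (5, 6, 7):
            per_t = np.array([
                tally.per_transcript.get(("S", "cds", k, "antisense", f"t{i}"), 0)
                for i in range(n_t)
            ])
            expected = window_count(300, k) * window_count(sec_len, k) * m**k
            se = per_t.std(ddof=1) * np.sqrt(n_t)
            assert abs(per_t.sum() - n_t * expected) <= 3 * se + 1e-9
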