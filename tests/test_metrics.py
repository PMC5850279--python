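import math

import numpy as np
import pytest

from esmatch.match_engine import MatchTally, count_matches
from esmatch.metrics import (
    decay_regression,
    density,
    gc_of_matched_sectors,
    gc_of_matches,
    group_totals,
    percent_of_reference,
    sector_ratio,
    summarize_groups,
)

from conftest import make_segment, make_transcript, random_rna


def tally_of(cells):
    return MatchTally(cells=dict(cells))


class TestGroupTotals:
    def test_single_cell(self):
        t = tally_of({("E1", "utr5", 7, "antisense"): 5})
        totals = group_totals(t, {"E1": "ESL"})
        assert totals[("ESL", "utr5")] == 5
        assert totals[("ESL", "all")] == 5

    def test_sums_over_segments_and_k(self):
        t = tally_of(
            {
                ("E1", "cds", 7, "antisense"): 3,
                ("E2", "cds", 9, "antisense"): 4,
                ("E1", "cds", 16, "antisense"): 100,  # outside 7-15
                ("E1", "cds", 7, "sense"): 50,  # wrong orientation
            }
        )
        totals = group_totals(t, {"E1": "ESL", "E2": "ESL"})
        assert totals[("ESL", "cds")] == 7

    def test_group_without_segments_errors(self):
        t = tally_of({("E1", "utr5", 7, "antisense"): 5})
        with pytest.raises(ValueError, match="no member segments"):
            group_totals(t, {"E1": "ESL"}, expected_groups=["ESL", "CSL"])
        with pytest.raises(ValueError, match="empty"):
            group_totals(t, {})


class TestDensity:
    @pytest.mark.parametrize(
        "matches,nt,expected",
        [
            (19.312e6, 2387, 8090),  # GC-rich LSU expansion pool
            (14.733e6, 2648, 5564),
            (2.783e6, 521, 5342),
            (6.942e6, 1343, 5169),
        ],
    )
    def test_published_per_nt_densities(self, matches, nt, expected):
        assert density(matches, nt) == pytest.approx(expected, abs=1)

    def test_per_1000_transcripts_scale(self):
        assert density(1000, 100, n_transcripts=1000,
                       scale="per_nt_per_1000_mrna") == pytest.approx(10.0)

    def test_zero_nt_rejected(self):
        with pytest.raises(ValueError):
            density(10, 0)

    def test_per_1000_scale_invariant_to_duplicating_transcripts(self):
        base = density(500, 100, n_transcripts=200, scale="per_nt_per_1000_mrna")
        doubled = density(1000, 100, n_transcripts=400, scale="per_nt_per_1000_mrna")
        assert doubled == pytest.approx(base)


class TestPercentOfReference:
    @pytest.mark.parametrize(
        "value,ref,expected",
        [
            (14.733e6, 19.312e6, 76.3),
            (6.942e6, 19.312e6, 35.9),
            (5564, 8090.49, 68.8),
            (5169, 8090.49, 63.9),
        ],
    )
    def test_published_percentages(self, value, ref, expected):
        assert percent_of_reference(value, ref) == pytest.approx(expected, abs=0.1)

    def test_identity_is_100(self):
        assert percent_of_reference(42.0, 42.0) == 100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_of_reference(1.0, 0.0)

    def test_scale_invariance(self):
        assert percent_of_reference(3.0, 12.0) == percent_of_reference(300.0, 1200.0)


class TestSectorRatio:
    def test_equal_counts_give_unity(self):
        t = tally_of(
            {
                ("E1", "utr3", 7, "antisense"): 10,
                ("E1", "utr5", 7, "antisense"): 10,
            }
        )
        r = sector_ratio(t, {"E1": "ESL"}, "ESL", "utr3", "utr5", [7])
        assert r[7] == 1.0

    def test_quarter_ratio(self):
        t = tally_of(
            {
                ("E1", "utr3", 7, "antisense"): 10,
                ("E1", "utr5", 7, "antisense"): 40,
            }
        )
        assert sector_ratio(t, {"E1": "ESL"}, "ESL", "utr3", "utr5", [7])[7] == 0.25

    def test_zero_denominator_yields_nan_not_exception(self):
        t = tally_of({("E1", "utr3", 9, "antisense"): 3})
        r = sector_ratio(t, {"E1": "ESL"}, "ESL", "utr3", "utr5", [9])
        assert math.isnan(r[9])

    def test_gc_biased_ratio_decreases_with_k(self, rng):
        """GC-rich segment vs GC-rich 5'utr and AT-rich 3'utr: the utr3/utr5
        ratio must fall as the match length grows."""
        seg = make_segment(random_rna(rng, 400, gc=0.85), "E1")
        ts = [
            make_transcript(
                utr5=random_rna(rng, 300, gc=0.70),
                cds=random_rna(rng, 300, gc=0.50),
                utr3=random_rna(rng, 300, gc=0.35),
                transcript_id=f"t{i}",
            )
            for i in range(40)
        ]
        tally = count_matches([seg], ts, k_range=(2, 6))
        r = sector_ratio(tally, {"E1": "ESL"}, "ESL", "utr3", "utr5", [2, 4, 6])
        assert r[2] > r[4] > r[6]


class TestGcOfMatches:
    def _tally(self, cds, seg_res="GGGGGGG", k=7):
        seg = make_segment(seg_res, "S")
        t = make_transcript(cds=cds)
        return count_matches([seg], [t], k_range=(k, k), record_tracts=True)

    def test_all_gc_tracts(self):
        tally = self._tally("CCCCCCC")
        assert gc_of_matches(tally, {"S": "ESL"}, "ESL", "cds", 7) == 100.0

    def test_occurrence_weighting(self):
        # segment carries G7 and A7 tracts; cds matches each exactly once
        tally = self._tally("CCCCCCCAAAAGGGUUUUUUU", seg_res="GGGGGGGCCCAAAAAAA")
        got = gc_of_matches(tally, {"S": "ESL"}, "ESL", "cds", 7)
        assert got == pytest.approx(50.0)

    def test_repeated_occurrences_weigh_more(self):
        # CCCCCCCC gives two occurrences of the G7 tract; UUUUUUU one of A7
        tally = self._tally("CCCCCCCCAAAGGGUUUUUUU", seg_res="GGGGGGGCCCAAAAAAA")
        occ = gc_of_matches(tally, {"S": "ESL"}, "ESL", "cds", 7)
        uniq = gc_of_matches(
            tally, {"S": "ESL"}, "ESL", "cds", 7, weighting="unique"
        )
        assert occ == pytest.approx(100 * 2 / 3)
        assert uniq == pytest.approx(50.0)

    def test_no_matches_is_nan(self):
        tally = self._tally("AAAAAAA")
        assert math.isnan(gc_of_matches(tally, {"S": "ESL"}, "ESL", "cds", 7))

    def test_matches_small_instance_hand_enumeration(self, rng):
        seg = make_segment(random_rna(rng, 30), "S")
        t = make_transcript(cds=random_rna(rng, 60))
        tally = count_matches([seg], [t], k_range=(3, 3), record_tracts=True)
        # direct enumeration over the sector
        res = t.cds.residues
        from esmatch.match_engine import reverse_complement

        windows = [seg.sequence.residues[i:i + 3] for i in range(28)]
        gc_nt = tot = 0
        for pos in range(len(res) - 2):
            kmer = res[pos:pos + 3]
            hits = sum(1 for w in windows if reverse_complement(w) == kmer)
            gc_nt += hits * (kmer.count("G") + kmer.count("C"))
            tot += hits * 3
        expected = 100 * gc_nt / tot if tot else float("nan")
        got = gc_of_matches(tally, {"S": "ESL"}, "ESL", "cds", 3)
        assert got == pytest.approx(expected)


class TestGcOfMatchedSectors:
    def test_mean_over_qualifying_sectors(self):
        seg = make_segment("GGGGGGG", "S")
        ts = [
            make_transcript(cds="CCCCCCC" + "AUAU" * 4, transcript_id="a"),  # 40% GC? no: compute
            make_transcript(cds="CCCCCCC" + "GCGC" * 4, transcript_id="b"),
            make_transcript(cds="AAAAAAA", transcript_id="c"),  # no match
        ]
        tally = count_matches([seg], ts, k_range=(7, 7))
        from esmatch.segmentation import gc_content

        expected = np.mean([gc_content(ts[0].cds), gc_content(ts[1].cds)])
        got = gc_of_matched_sectors(tally, ts, {"S": "ESL"}, "ESL", "cds", 7)
        assert got == pytest.approx(expected)

    def test_two_sectors_40_60_average_50(self):
        seg = make_segment("GGGGG", "S")
        # 10-nt sectors, GC 40% and 60%, each containing CCCCC to match
        ts = [
            make_transcript(cds="CCCCCAAAUU", transcript_id="a"),  # 5 GC /10 = 50? C5=5 GC -> 50
            make_transcript(cds="CCCCCGAAAU", transcript_id="b"),
        ]
        tally = count_matches([seg], ts, k_range=(5, 5))
        from esmatch.segmentation import gc_content

        expected = np.mean([gc_content(t.cds) for t in ts])
        got = gc_of_matched_sectors(tally, ts, {"S": "ESL"}, "ESL", "cds", 5)
        assert got == pytest.approx(expected)

    def test_nothing_qualifies_is_nan(self):
        seg = make_segment("GGGGGGG", "S")
        ts = [make_transcript(cds="AAAAAAA")]
        tally = count_matches([seg], ts, k_range=(7, 7))
        assert math.isnan(
            gc_of_matched_sectors(tally, ts, {"S": "ESL"}, "ESL", "cds", 7)
        )


class TestDecayRegression:
    def test_exact_geometric_counts(self):
        counts = {k: 2.0 ** (15 - k) for k in range(7, 16)}
        fit = decay_regression(counts)
        assert fit.slope == pytest.approx(-math.log10(2), abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_sd == pytest.approx(0.0, abs=1e-10)
        assert fit.fold_decrease_per_nt == pytest.approx(2.0, abs=1e-9)

    def test_constant_counts_slope_zero(self):
        fit = decay_regression({k: 100 for k in range(7, 16)})
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_counts_excluded(self):
        counts = {7: 100, 8: 50, 9: 25, 10: 0, 11: 0}
        fit = decay_regression(counts, 7, 11)
        assert fit.n_points == 3
        assert fit.excluded_ks == (10, 11)
        assert fit.slope == pytest.approx(-math.log10(2), abs=1e-10)

    def test_fewer_than_three_points_errors(self):
        with pytest.raises(ValueError):
            decay_regression({7: 10, 8: 5}, 7, 15)


class TestSummarizeGroups:
    def test_reference_group_at_100_percent(self, rng):
        segs = [
            make_segment(random_rna(rng, 120, gc=0.8), "E1", "ESL"),
            make_segment(random_rna(rng, 120, gc=0.5), "C1", "CSL"),
        ]
        ts = [
            make_transcript(
                random_rna(rng, 60), random_rna(rng, 150), random_rna(rng, 100),
                transcript_id=f"t{i}",
            )
            for i in range(25)
        ]
        tally = count_matches(segs, ts, k_range=(3, 8))
        summaries = summarize_groups(tally, segs, k_lo=3, k_hi=8)
        assert summaries["ESL"].pct_of_reference["all"] == pytest.approx(100.0)
        # densities consistent with totals
        for g in ("ESL", "CSL"):
            s = summaries[g]
            assert s.density["all"] == pytest.approx(s.matches["all"] / s.total_nt)

    def test_missing_reference_group_errors(self, rng):
        segs = [make_segment(random_rna(rng, 50), "C1", "CSL")]
        tally = count_matches(segs, [make_transcript()], k_range=(7, 7))
        with pytest.raises(ValueError, match="reference group"):
            summarize_groups(tally, segs)
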