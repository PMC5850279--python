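"""Sequence-scramble null model.

The selectivity control: shuffle a segment's residues (a uniform random
permutation, which preserves the base composition and hence GC content
exactly) and compare the number of transcripts matched by the shuffled
sequence with the number matched by the native one. Because short-tract
matching is driven almost entirely by composition, the native and scrambled
statistics are expected to sit close together — a small mean percent
difference with a modest coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import NucleotideSequence, SectoredTranscript
from .match_engine import MatchTally, count_matches
from .segmentation import RnaSegment


def scramble(seq: NucleotideSequence, seed: int) -> NucleotideSequence:
    """Uniform random permutation of the residues, reproducible from seed."""
    if len(seq) < 2:
        raise ValueError("scramble needs a sequence of length >= 2")
    rng = np.random.default_rng(seed)
    chars = np.array(list(seq.residues))
    rng.shuffle(chars)
    return NucleotideSequence(f"{seq.id}|scrambled", "".join(chars))


@dataclass
class ScrambleReport:
    """Native-vs-shuffled matched-transcript statistics for one segment."""

    segment_id: str
    k: int
    n_replicates: int
    seed: int
    native_matched: int
    replicate_matched: list = field(default_factory=list)
    native_total_matches: int = 0
    replicate_total_matches: list = field(default_factory=list)

    @property
    def mean_abs_pct_diff(self) -> float:
        """Mean over replicates of 100*|replicate - native|/native (NaN if native 0)."""
        if self.native_matched == 0:
            return float("nan")
        diffs = [
            100.0 * abs(r - self.native_matched) / self.native_matched
            for r in self.replicate_matched
        ]
        return float(np.mean(diffs))

    @property
    def cv_pct(self) -> float:
        """Coefficient of variation of the replicate statistic, in percent.

        Undefined (NaN) with fewer than 2 replicates or a zero replicate mean.
        """
        if len(self.replicate_matched) < 2:
            return float("nan")
        mean = float(np.mean(self.replicate_matched))
        if mean == 0:
            return float("nan")
        return 100.0 * float(np.std(self.replicate_matched, ddof=1)) / mean


def _matched_count(
    segment: RnaSegment, transcripts: Sequence[SectoredTranscript], k: int
) -> tuple[int, int]:
    """(# transcripts with >=1 antisense k-match in any sector, total matches)."""
    tally: MatchTally = count_matches([segment], transcripts, k_range=(k, k))
    matched = {tid for (_seg, _s, _k, _o, tid), c in tally.per_transcript.items() if c > 0}
    total = sum(tally.cells.values())
    return len(matched), total


def scramble_comparison(
    segment: RnaSegment,
    transcripts: Sequence[SectoredTranscript],
    n_replicates: int = 10,
    k: int = 7,
    seed: int = 0,
) -> ScrambleReport:
    """Compare matched-transcript counts between a native segment and shuffles.

    Replicate i uses seed ``seed + i`` (auditably derived). The compared
    statistic is the number of transcripts with at least one antisense k-match
    in any sector; total match counts are carried along for reference.
    """
    if segment.n_nt < k:
        raise ValueError(
            f"segment {segment.segment_id!r} shorter than match length {k}"
        )
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    native_matched, native_total = _matched_count(segment, transcripts, k)
    report = ScrambleReport(
        segment_id=segment.segment_id,
        k=k,
        n_replicates=n_replicates,
        seed=seed,
        native_matched=native_matched,
        native_total_matches=native_total,
    )
    for i in range(n_replicates):
        shuffled = RnaSegment(
            segment_id=segment.segment_id,
            group=segment.group,
            sequence=scramble(segment.sequence, seed + i),
            start=segment.start,
        )
        matched, total = _matched_count(shuffled, transcripts, k)
        report.replicate_matched.append(matched)
        report.replicate_total_matches.append(total)
    return report


def pooled_scramble_stats(reports: Sequence[ScrambleReport]) -> dict:
    """Aggregate scramble reports across segments, both ways.

    ``per_segment`` averages each segment's own mean |%diff| and CV (each
    segment weighted equally); ``per_replicate`` pools every replicate's
    percent difference into one mean and one CV over all replicate values of
    all segments.
    """
    if not reports:
        raise ValueError("no scramble reports to pool")
    per_segment_diff = float(np.nanmean([r.mean_abs_pct_diff for r in reports]))
    per_segment_cv = float(np.nanmean([r.cv_pct for r in reports]))
    all_diffs, all_rel = [], []
    for r in reports:
        if r.native_matched == 0:
            continue
        for rep in r.replicate_matched:
            all_diffs.append(100.0 * abs(rep - r.native_matched) / r.native_matched)
            all_rel.append(100.0 * rep / r.native_matched)
    pooled_diff = float(np.mean(all_diffs)) if all_diffs else float("nan")
    pooled_cv = (
        100.0 * float(np.std(all_rel, ddof=1)) / float(np.mean(all_rel))
        if len(all_rel) > 1 and np.mean(all_rel) != 0
        else float("nan")
    )
    return {
        "per_segment_mean_abs_pct_diff": per_segment_diff,
        "per_segment_cv_pct": per_segment_cv,
        "per_replicate_mean_abs_pct_diff": pooled_diff,
        "per_replicate_cv_pct": pooled_cv,
    }
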