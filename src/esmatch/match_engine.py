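"""Exhaustive exact antisense/sense match counting between rRNA segments and mRNA sectors.

For every match length k in a configurable range (default 7-20), every
k-windows of every segment is compared against every k-window of every
transcript sector; a match is one (segment window, sector position) pair.
Antisense means the sector window equals the strict Watson-Crick reverse
complement of the segment window (G:C and A:U only, no G:U wobble); sense
means string equality. Overlapping, repeated and nested occurrences are all
counted, and different k are tallied independently.

The production path uses a hash index of segment windows per k; a naive
double-loop scan with the identical contract (:func:`count_matches_naive`)
is retained as an independent test oracle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import SECTORS, NucleotideSequence, SectoredTranscript
from .segmentation import RnaSegment, SegmentSet

ORIENTATIONS = ("antisense", "sense")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_UNAMBIGUOUS = frozenset("ACGU")


def window_count(seq_len: int, k: int) -> int:
    """Number of successive k-windows in a sequence: max(0, len - k + 1)."""
    if k < 1:
        raise ValueError(f"window length must be >= 1, got {k}")
    return max(0, seq_len - k + 1)


def reverse_complement(tract: str) -> str:
    """Strict Watson-Crick reverse complement (A<->U, G<->C).

    Ambiguity codes (N etc.) pass through unchanged; windows containing them
    are excluded from matching upstream, so they can never produce a match.
    """
    return tract.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchSite:
    """One exact match occurrence (0-based offsets, half-open windows)."""

    segment_id: str
    segment_offset: int
    transcript_id: str
    sector: str
    position: int
    k: int
    orientation: str


@dataclass
class MatchTally:
    """Counts of matches per (segment, sector, k, orientation) cell.

    ``per_transcript`` adds the transcript dimension; the two are consistent:
    every cell count equals the sum of its per-transcript counts. Optional
    tract/repeat/site records support GC-of-match statistics and repeated
    -match queries; they are populated only when requested at count time.
    """

    cells: dict = field(default_factory=dict)
    # (segment_id, sector, k, orientation, transcript_id) -> count
    per_transcript: dict = field(default_factory=dict)
    n_transcripts: int = 0
    segment_ids: tuple = ()
    # (segment_id, sector, k, orientation) -> Counter(sector tract -> occurrences)
    tract_counts: dict | None = None
    # (segment_id, k, orientation) -> Counter((sector tract, transcript_id) -> occurrences)
    repeat_counts: dict | None = None
    sites: list | None = None

    def count(self, segment_id: str, sector: str, k: int, orientation: str = "antisense") -> int:
        return self.cells.get((segment_id, sector, k, orientation), 0)

    def validate(self) -> None:
        """Assert internal consistency and monotonicity of counts in k."""
        if any(c < 0 for c in self.cells.values()):
            raise AssertionError("negative match count")
        if self.per_transcript:
            sums: Counter = Counter()
            for (seg, sector, k, orient, _tid), c in self.per_transcript.items():
                sums[(seg, sector, k, orient)] += c
            for key, total in sums.items():
                if total != self.cells.get(key, 0):
                    raise AssertionError(
                        f"cell {key} count {self.cells.get(key, 0)} != "
                        f"per-transcript sum {total}"
                    )
        by_cell: dict = {}
        for (seg, sector, k, orient), c in self.cells.items():
            by_cell.setdefault((seg, sector, orient), {})[k] = c
        for key, by_k in by_cell.items():
            ks = sorted(by_k)
            for a, b in zip(ks, ks[1:]):
                if b == a + 1 and by_k[b] > by_k[a]:
                    raise AssertionError(
                        f"count not monotone in k for {key}: "
                        f"count({b})={by_k[b]} > count({a})={by_k[a]}"
                    )


def _clean_windows(residues: str, k: int) -> Iterable[tuple[int, str]]:
    """Yield (offset, window) for every k-window free of ambiguity codes."""
    for i in range(window_count(len(residues), k)):
        w = residues[i : i + k]
        if _UNAMBIGUOUS.issuperset(w):
            yield i, w


def _segment_index(
    segments: Sequence[RnaSegment], k: int, orientation: str, unique_windows: bool
) -> dict:
    """Map sector-side k-mer -> {segment_id: list of segment offsets}.

    For antisense the key is the reverse complement of the segment window
    (i.e. the sector k-mer that would pair with it); for sense it is the
    window itself.
    """
    index: dict = {}
    for seg in segments:
        seen: set = set()
        for off, w in _clean_windows(seg.sequence.residues, k):
            key = reverse_complement(w) if orientation == "antisense" else w
            if unique_windows:
                if key in seen:
                    continue
                seen.add(key)
            index.setdefault(key, {}).setdefault(seg.segment_id, []).append(off)
    return index


def _is_maximal(
    seg_res: str, sec_res: str, seg_off: int, pos: int, k: int, orientation: str
) -> bool:
    """True when the k-match at (seg_off, pos) extends in neither direction."""
    if orientation == "sense":
        left = seg_off > 0 and pos > 0 and seg_res[seg_off - 1] == sec_res[pos - 1]
        right = (
            seg_off + k < len(seg_res)
            and pos + k < len(sec_res)
            and seg_res[seg_off + k] == sec_res[pos + k]
        )
        return not (left or right)
    # antisense: sector position pos-1 would pair with segment seg_off+k,
    # sector pos+k with segment seg_off-1
    comp = _COMPLEMENT
    left = (
        pos > 0
        and seg_off + k < len(seg_res)
        and seg_res[seg_off + k].translate(comp) == sec_res[pos - 1]
        and sec_res[pos - 1] in _UNAMBIGUOUS
    )
    right = (
        pos + k < len(sec_res)
        and seg_off > 0
        and seg_res[seg_off - 1].translate(comp) == sec_res[pos + k]
        and sec_res[pos + k] in _UNAMBIGUOUS
    )
    return not (left or right)


def count_matches(
    segments: SegmentSet | Sequence[RnaSegment],
    transcripts: Sequence[SectoredTranscript],
    k_range: tuple[int, int] = (7, 20),
    orientations: Sequence[str] = ("antisense",),
    *,
    record_tracts: bool = False,
    record_sites: bool = False,
    unique_windows: bool = False,
    maximal_only: bool = False,
) -> MatchTally:
    """Count all exact k-matches between every segment and every sector.

    Parameters
    ----------
    k_range
        Inclusive (k_min, k_max); the reference scan is (7, 20) with totals
        usually summarized over 7-15.
    orientations
        Any subset of {"antisense", "sense"}.
    record_tracts
        Keep per-cell counters of matched sector tracts (needed for GC-of-match
        statistics and repeated-match queries).
    record_sites
        Keep the full list of :class:`MatchSite` occurrences (memory-heavy on
        large runs; intended for small/planted-truth analyses).
    unique_windows
        Deduplicate identical windows within a segment before counting.
    maximal_only
        Count only matches that cannot be extended by one nucleotide on either
        side (non-nested mode; off by default, matching the exhaustive
        convention of the headline counts).
    """
    seg_list = list(segments)
    k_lo, k_hi = k_range
    if k_lo < 1 or k_hi < k_lo:
        raise ValueError(f"invalid k_range {k_range}")
    bad = set(orientations) - set(ORIENTATIONS)
    if bad:
        raise ValueError(f"unknown orientations {sorted(bad)}")
    seg_res = {s.segment_id: s.sequence.residues for s in seg_list}

    tally = MatchTally(
        n_transcripts=len(transcripts),
        segment_ids=tuple(s.segment_id for s in seg_list),
    )
    if record_tracts:
        tally.tract_counts = {}
        tally.repeat_counts = {}
    if record_sites:
        tally.sites = []

    for k in range(k_lo, k_hi + 1):
        for orientation in orientations:
            index = _segment_index(seg_list, k, orientation, unique_windows)
            if not index:
                continue
            for t in transcripts:
                for sector in SECTORS:
                    residues = t.sector(sector).residues
                    for pos in range(window_count(len(residues), k)):
                        kmer = residues[pos : pos + k]
                        hit = index.get(kmer)
                        if hit is None:
                            continue
                        for seg_id, offsets in hit.items():
                            if maximal_only:
                                offsets = [
                                    o
                                    for o in offsets
                                    if _is_maximal(
                                        seg_res[seg_id], residues, o, pos, k, orientation
                                    )
                                ]
                            n = len(offsets)
                            if n == 0:
                                continue
                            cell = (seg_id, sector, k, orientation)
                            tally.cells[cell] = tally.cells.get(cell, 0) + n
                            pt = (seg_id, sector, k, orientation, t.transcript_id)
                            tally.per_transcript[pt] = (
                                tally.per_transcript.get(pt, 0) + n
                            )
                            if record_tracts:
                                tally.tract_counts.setdefault(cell, Counter())[
                                    kmer
                                ] += n
                                tally.repeat_counts.setdefault(
                                    (seg_id, k, orientation), Counter()
                                )[(kmer, t.transcript_id)] += n
                            if record_sites:
                                tally.sites.extend(
                                    MatchSite(
                                        segment_id=seg_id,
                                        segment_offset=o,
                                        transcript_id=t.transcript_id,
                                        sector=sector,
                                        position=pos,
                                        k=k,
                                        orientation=orientation,
                                    )
                                    for o in offsets
                                )
    return tally


def count_matches_naive(
    segments: SegmentSet | Sequence[RnaSegment],
    transcripts: Sequence[SectoredTranscript],
    k_range: tuple[int, int] = (7, 20),
    orientations: Sequence[str] = ("antisense",),
    *,
    maximal_only: bool = False,
) -> MatchTally:
    """Reference O(n*m) double-loop scan with the same counting contract.

    Kept as an independent oracle for the indexed engine; not a runtime path.
    """
    seg_list = list(segments)
    k_lo, k_hi = k_range
    if k_lo < 1 or k_hi < k_lo:
        raise ValueError(f"invalid k_range {k_range}")
    tally = MatchTally(
        n_transcripts=len(transcripts),
        segment_ids=tuple(s.segment_id for s in seg_list),
    )
    for k in range(k_lo, k_hi + 1):
        for orientation in orientations:
            for seg in seg_list:
                sres = seg.sequence.residues
                windows = [
                    (i, reverse_complement(w) if orientation == "antisense" else w)
                    for i, w in _clean_windows(sres, k)
                ]
                for t in transcripts:
                    for sector in SECTORS:
                        residues = t.sector(sector).residues
                        n_pos = window_count(len(residues), k)
                        for i, target in windows:
                            for pos in range(n_pos):
                                if residues[pos : pos + k] != target:
                                    continue
                                if maximal_only and not _is_maximal(
                                    sres, residues, i, pos, k, orientation
                                ):
                                    continue
                                cell = (seg.segment_id, sector, k, orientation)
                                tally.cells[cell] = tally.cells.get(cell, 0) + 1
                                pt = (
                                    seg.segment_id,
                                    sector,
                                    k,
                                    orientation,
                                    t.transcript_id,
                                )
                                tally.per_transcript[pt] = (
                                    tally.per_transcript.get(pt, 0) + 1
                                )
    return tally


def matched_transcript_fraction(
    tally: MatchTally, segment_id: str, k: int, orientation: str = "antisense"
) -> float:
    """Fraction of transcripts with >= 1 match to the segment at length k in any sector."""
    if tally.n_transcripts == 0:
        raise ValueError("tally carries no transcripts")
    known = set(tally.segment_ids) or (
        {key[0] for key in tally.per_transcript} | {key[0] for key in tally.cells}
    )
    if segment_id not in known:
        raise KeyError(f"segment {segment_id!r} not present in tally")
    matched = {
        tid
        for (seg, _sector, kk, orient, tid), c in tally.per_transcript.items()
        if seg == segment_id and kk == k and orient == orientation and c > 0
    }
    return len(matched) / tally.n_transcripts


def max_repeats(
    tally: MatchTally, segment_id: str, k: int, orientation: str = "antisense"
) -> tuple[str, str, int]:
    """The (tract, transcript) pair with the most repeated occurrences.

    Requires tract recording (``record_tracts=True`` at count time). Ties are
    broken lexicographically by tract then transcript id; with no matches at
    all the count is 0.
    """
    if tally.repeat_counts is None:
        raise ValueError("tract recording was not enabled for this tally")
    counter = tally.repeat_counts.get((segment_id, k, orientation))
    if not counter:
        return ("", "", 0)
    # deterministic tie-break: highest count, then lexicographically smallest
    best_count = max(counter.values())
    candidates = sorted(
        (tract, tid) for (tract, tid), c in counter.items() if c == best_count
    )
    tract, tid = candidates[0]
    return (tract, tid, best_count)


def base_frequencies(residues: str) -> dict:
    """Relative frequencies of A/C/G/U (ambiguity codes excluded from the total)."""
    total = sum(residues.count(b) for b in "ACGU")
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return {b: residues.count(b) / total for b in "ACGU"}


def base_pairing_overlap(p: dict, q: dict) -> float:
    """m = sum_b p(b) * q(complement(b)): per-position antisense match probability.

    For independent uniformly drawn sequences the expected number of antisense
    k-matches is windows_seg * windows_sector * m**k.
    """
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return sum(p[b] * q[comp[b]] for b in "ACGU")


def expected_match_count(
    seg_windows: int, sector_windows: int, m: float, k: int
) -> float:
    """Expected-count law for iid sequences (see :func:`base_pairing_overlap`)."""
    return seg_windows * sector_windows * m**k
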