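"""Apply a boundary table to an rRNA to produce named segment sequences.

Expansion segments (ES) are eukaryote-specific insertions in rRNA; the
conserved stretches between them are core segments (CS). Crossing ES/CS with
the ribosomal subunit (LSU for 25-28S rRNA, SSU for 18S) gives the four
segment groups used throughout the pipeline: ESL, CSL, ESS, CSS.

Sub-threshold expansion segments (< 6 nt by default) are absorbed into a
neighbouring core segment, which keeps its own identifier; nucleotides are
conserved under this merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import (
    NucleotideSequence,
    SegmentBoundaryRecord,
    validate_boundaries,
)

logger = logging.getLogger(__name__)

GROUPS = ("ESL", "CSL", "ESS", "CSS")

#: default minimum expansion-segment size; smaller ES merge into a core segment
DEFAULT_MIN_ES_NT = 6


def group_label(subunit: str, seg_class: str) -> str:
    """ES/CS crossed with LSU/SSU -> ESL, CSL, ESS or CSS."""
    return {"LSU": {"ES": "ESL", "CS": "CSL"}, "SSU": {"ES": "ESS", "CS": "CSS"}}[
        subunit
    ][seg_class]


def gc_content(seq: NucleotideSequence | str) -> float:
    """GC content in percent: 100*(G+C)/length.

    Ambiguity codes (including N) count toward the denominator but never the
    numerator, so uncertain positions dilute rather than inflate the estimate.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    if not residues:
        raise ValueError("gc_content of an empty sequence is undefined")
    gc = residues.count("G") + residues.count("C")
    return 100.0 * gc / len(residues)


@dataclass(frozen=True)
class RnaSegment:
    """A named rRNA interval with its sequence and derived statistics."""

    segment_id: str
    group: str
    sequence: NucleotideSequence
    start: int = 1  # 1-based inclusive position in the parent rRNA

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.segment_id}: unknown group {self.group!r}")

    @property
    def n_nt(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.n_nt - 1

    @property
    def gc_percent(self) -> float:
        return gc_content(self.sequence)


@dataclass
class SegmentSet:
    """Segments extracted from one parent rRNA (or a pooled multi-rRNA set)."""

    parent_id: str
    segments: list[RnaSegment]

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"{self.parent_id}: duplicate segment ids {dupes}")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def by_id(self, segment_id: str) -> RnaSegment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(f"no segment {segment_id!r} in set {self.parent_id!r}")

    def group_of(self) -> dict:
        return {s.segment_id: s.group for s in self.segments}

    def groups(self) -> dict:
        """Map group label -> list of member segments (only non-empty groups)."""
        out: dict = {}
        for s in self.segments:
            out.setdefault(s.group, []).append(s)
        return out

    @property
    def total_nt(self) -> int:
        return sum(s.n_nt for s in self.segments)


def extract_segments(
    rrna: NucleotideSequence,
    boundaries: Sequence[SegmentBoundaryRecord],
    min_es_nt: int = DEFAULT_MIN_ES_NT,
    *,
    merge_direction: str = "preceding",
    strict: bool = False,
) -> SegmentSet:
    """Cut an rRNA into named segments, merging sub-threshold ES into core.

    An ES shorter than ``min_es_nt`` is absorbed by the adjacent CS — the
    preceding one by default (``merge_direction="following"`` flips this),
    falling back to the other side when the preferred neighbour does not
    exist. The absorbing CS keeps its own segment_id. In strict mode the
    boundary records must tile the full rRNA.
    """
    if merge_direction not in ("preceding", "following"):
        raise ValueError("merge_direction must be 'preceding' or 'following'")
    recs = sorted(boundaries, key=lambda r: r.start)
    validate_boundaries(recs)
    n = len(rrna)
    for r in recs:
        if r.end > n:
            raise ValueError(
                f"{r.segment_id}: end {r.end} exceeds rRNA {rrna.id!r} length {n}"
            )
    if strict:
        covered = sum(r.n_nt for r in recs)
        if covered != n or (recs and (recs[0].start != 1 or recs[-1].end != n)):
            raise ValueError(
                f"boundary records do not tile rRNA {rrna.id!r} "
                f"({covered}/{n} nt covered)"
            )

    # resolve merges on mutable [segment_id, seg_class, start, end, subunit]
    intervals = [[r.segment_id, r.seg_class, r.start, r.end, r.subunit] for r in recs]
    resolved: list[list] = []
    # start (and end, for the trailing case) of a sub-threshold ES run that is
    # still waiting for a core segment to absorb it
    pending: list[int] | None = None
    for seg_id, seg_class, start, end, subunit in intervals:
        if seg_class == "ES" and (end - start + 1) < min_es_nt:
            prev_is_cs = bool(resolved) and resolved[-1][1] == "CS"
            if merge_direction == "preceding" and prev_is_cs:
                resolved[-1][3] = end  # preceding CS grows, keeps its id
            else:
                # defer to the following CS (preferred direction, or no
                # preceding CS exists yet)
                pending = [start, end] if pending is None else [pending[0], end]
            continue
        if pending is not None and seg_class == "CS":
            start = pending[0]
            pending = None
        resolved.append([seg_id, seg_class, start, end, subunit])
    if pending is not None:
        # trailing sub-threshold ES with no following CS: fold backwards if a
        # CS precedes it, otherwise keep it as its own (tiny) segment
        if resolved and resolved[-1][1] == "CS":
            resolved[-1][3] = pending[1]
        else:
            logger.warning(
                "sub-threshold ES with no adjacent CS retained verbatim in %s",
                rrna.id,
            )
            resolved.append(["unmerged_es", "ES", pending[0], pending[1], recs[-1].subunit])

    segments = [
        RnaSegment(
            segment_id=seg_id,
            group=group_label(subunit, seg_class),
            sequence=NucleotideSequence(seg_id, rrna.residues[start - 1 : end]),
            start=start,
        )
        for seg_id, seg_class, start, end, subunit in resolved
    ]
    return SegmentSet(parent_id=rrna.id, segments=segments)


def pooled_gc_from_values(sizes: Sequence[float], gc_percents: Sequence[float]) -> float:
    """Size-weighted mean GC: 100-scale, 100*sum(gc_i*n_i)/sum(n_i) with gc in percent."""
    if len(sizes) != len(gc_percents) or not sizes:
        raise ValueError("need equal-length, non-empty size and GC lists")
    total = float(sum(sizes))
    if total <= 0:
        raise ValueError("total size must be positive")
    return sum(n * g for n, g in zip(sizes, gc_percents)) / total


def pooled_gc(segments: Iterable[RnaSegment]) -> float:
    """Size-weighted mean GC percent over a pool of segments."""
    segs = list(segments)
    if not segs:
        raise ValueError("pooled_gc of an empty segment list is undefined")
    return pooled_gc_from_values([s.n_nt for s in segs], [s.gc_percent for s in segs])
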