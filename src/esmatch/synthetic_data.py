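"""Synthetic rRNA-segment and sectored-mRNA generators with planted ground truth.

The generator emulates the statistical structure the analysis assumes for the
human data: a sectored transcript collection whose 5'utr/cds/3'utr lengths
average 250/1,678/1,474 nt with a GC gradient from the GC-rich 5'utr to the
AT-rich 3'utr, and rRNA segments whose groups differ sharply in GC (the
large-subunit expansion segments around 80% GC versus ~56-58% elsewhere).
Bases are drawn iid with an even G/C and A/U split inside each composition;
optional homoiteron runs (e.g. G x 6) can be stamped into segments. Every
draw is reproducible from the config seed.

Planted-truth fixtures overwrite exact reverse-complement copies of segment
windows into transcripts at recorded positions, giving the match engine a
known answer to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import (
    NucleotideSequence,
    SectoredTranscript,
    SegmentBoundaryRecord,
    SECTORS,
)
from .match_engine import MatchSite, reverse_complement, window_count
from .segmentation import RnaSegment, SegmentSet

_BASES = np.frombuffer(b"GCAU", dtype="S1")


@dataclass(frozen=True)
class SegmentSpec:
    """Recipe for one synthetic rRNA segment."""

    segment_id: str
    group: str  # ESL / CSL / ESS / CSS
    n_nt: int
    gc_percent: float
    # runs of identical bases stamped in at random non-overlapping positions
    homoiterons: tuple = ()  # of (base, run_length, n_runs)


#: default segment panel: two GC-rich large-subunit expansion segments sized
#: like the two biggest human ones, flanking cores, and small-subunit
#: counterparts at their groups' typical GC.
DEFAULT_SEGMENT_SPECS = (
    SegmentSpec("ESL7", "ESL", 801, 83.8),
    SegmentSpec("CSL8", "CSL", 260, 56.5),
    SegmentSpec("ESL15", "ESL", 182, 84.1),
    SegmentSpec("CSL16", "CSL", 261, 56.5),
    SegmentSpec("ESS6", "ESS", 180, 58.3),
    SegmentSpec("CSS7", "CSS", 300, 56.6),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic inputs.

    Defaults follow the human collection the analysis targets: sector length
    means 250/1678/1474 nt; a 5'utr > cds > 3'utr GC gradient (63/53.5/44%,
    in the neighbourhood of the matched-sector GC values of the low-GC
    segment groups); 200 transcripts for sub-minute end-to-end runs, with the
    full-size human-collection scale (18,810) available via ``full_scale``.
    """

    n_transcripts: int = 200
    sector_length_means: tuple = (250, 1678, 1474)
    sector_length_sigma: float = 0.35  # lognormal sigma; 0 = fixed lengths
    sector_gc: tuple = (63.0, 53.5, 44.0)
    segment_specs: tuple = DEFAULT_SEGMENT_SPECS
    planted_matches: tuple = ()  # of (segment_id, sector, k, n_copies)
    min_sector_nt: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if any(not (0.0 <= g <= 100.0) for g in self.sector_gc):
            raise ValueError("sector GC percents must lie in [0, 100]")
        if any(not (0.0 <= s.gc_percent <= 100.0) for s in self.segment_specs):
            raise ValueError("segment GC percents must lie in [0, 100]")


def full_scale(config: GeneratorConfig | None = None) -> GeneratorConfig:
    """Full-size preset (18,810 transcripts) for benchmarking only."""
    return replace(config or GeneratorConfig(), n_transcripts=18810)


def _gc_probs(gc_percent: float) -> np.ndarray:
    """Per-base draw probabilities with even G/C and A/U split (order GCAU)."""
    g = gc_percent / 200.0
    a = (100.0 - gc_percent) / 200.0
    return np.array([g, g, a, a])


def _random_seq(rng: np.random.Generator, n: int, gc_percent: float) -> str:
    arr = rng.choice(_BASES, size=n, p=_gc_probs(gc_percent))
    return arr.tobytes().decode("ascii")


def generate_transcripts(config: GeneratorConfig) -> list[SectoredTranscript]:
    """Draw the sectored transcript collection specified by the config.

    Sector lengths are lognormal with the configured arithmetic mean (the
    lognormal mu is mean-corrected: mu = ln(mean) - sigma^2/2) and never
    below ``min_sector_nt``; bases are iid at the sector's GC.
    """
    rng = np.random.default_rng(config.seed)
    out: list[SectoredTranscript] = []
    means = config.sector_length_means
    sigma = config.sector_length_sigma
    for i in range(config.n_transcripts):
        tid = f"t{i:05d}"
        parts = {}
        for sector, mean, gc in zip(SECTORS, means, config.sector_gc):
            if sigma > 0:
                mu = np.log(mean) - sigma**2 / 2.0
                length = int(round(rng.lognormal(mu, sigma)))
            else:
                length = int(mean)
            length = max(length, config.min_sector_nt)
            parts[sector] = NucleotideSequence(
                f"{tid}|{sector}", _random_seq(rng, length, gc)
            )
        out.append(
            SectoredTranscript(
                transcript_id=tid,
                utr5=parts["utr5"],
                cds=parts["cds"],
                utr3=parts["utr3"],
            )
        )
    return out


@dataclass
class SyntheticSegments:
    """Generated segments plus the pseudo-rRNAs and boundary table they tile."""

    segment_set: SegmentSet
    boundaries: list
    rrnas: dict  # subunit -> NucleotideSequence


_SUBUNIT_OF_GROUP = {"ESL": "LSU", "CSL": "LSU", "ESS": "SSU", "CSS": "SSU"}


def generate_segments(config: GeneratorConfig) -> SyntheticSegments:
    """Draw the segment panel and emit a consistent boundary table.

    Segments of each subunit are concatenated (in the given order) into one
    pseudo-rRNA per subunit, so the boundary table round-trips through
    segment extraction to the identical sequences.
    """
    rng = np.random.default_rng(config.seed + 1)
    segments: list[RnaSegment] = []
    boundaries: list[SegmentBoundaryRecord] = []
    rrna_parts: dict = {"LSU": [], "SSU": []}
    cursor = {"LSU": 0, "SSU": 0}
    for spec in config.segment_specs:
        seq = _random_seq(rng, spec.n_nt, spec.gc_percent)
        for base, run_len, n_runs in spec.homoiterons:
            if run_len > spec.n_nt:
                raise ValueError(
                    f"{spec.segment_id}: homoiteron of {run_len} nt exceeds "
                    f"segment length {spec.n_nt}"
                )
            for _ in range(n_runs):
                pos = int(rng.integers(0, spec.n_nt - run_len + 1))
                seq = seq[:pos] + base * run_len + seq[pos + run_len :]
        subunit = _SUBUNIT_OF_GROUP[spec.group]
        start = cursor[subunit] + 1
        segments.append(
            RnaSegment(
                segment_id=spec.segment_id,
                group=spec.group,
                sequence=NucleotideSequence(spec.segment_id, seq),
                start=start,
            )
        )
        boundaries.append(
            SegmentBoundaryRecord(
                segment_id=spec.segment_id,
                subunit=subunit,
                seg_class="ES" if spec.group.startswith("ES") else "CS",
                start=start,
                end=start + spec.n_nt - 1,
            )
        )
        rrna_parts[subunit].append(seq)
        cursor[subunit] += spec.n_nt
    rrnas = {
        su: NucleotideSequence(f"synthetic_{su}", "".join(parts))
        for su, parts in rrna_parts.items()
        if parts
    }
    return SyntheticSegments(
        segment_set=SegmentSet(parent_id="synthetic", segments=segments),
        boundaries=boundaries,
        rrnas=rrnas,
    )


def plant_matches(
    transcripts: Sequence[SectoredTranscript],
    segments: SegmentSet | Sequence[RnaSegment],
    planted: Sequence[tuple],
    seed: int = 0,
    max_retries: int = 1000,
) -> tuple[list[SectoredTranscript], list[MatchSite]]:
    """Overwrite reverse-complement copies of segment windows into transcripts.

    ``planted`` holds (segment_id, sector, k, n_copies) tuples; each copy
    picks a random segment window and a random transcript/position, redrawing
    on overlap with an earlier plant (bounded retries). Returns the modified
    transcripts and a truth table of every planted site.
    """
    rng = np.random.default_rng(seed)
    seg_by_id = {s.segment_id: s for s in segments}
    residues = {
        (t.transcript_id, sector): list(t.sector(sector).residues)
        for t in transcripts
        for sector in SECTORS
    }
    occupied: dict = {key: [] for key in residues}
    truth: list[MatchSite] = []
    for segment_id, sector, k, n_copies in planted:
        seg = seg_by_id[segment_id]
        n_windows = window_count(seg.n_nt, k)
        if n_windows < 1:
            raise ValueError(f"{segment_id}: shorter than requested tract ({k} nt)")
        for _ in range(n_copies):
            for attempt in range(max_retries):
                offset = int(rng.integers(0, n_windows))
                tract = reverse_complement(
                    seg.sequence.residues[offset : offset + k]
                )
                t = transcripts[int(rng.integers(0, len(transcripts)))]
                target = residues[(t.transcript_id, sector)]
                if len(target) < k:
                    continue
                pos = int(rng.integers(0, len(target) - k + 1))
                spans = occupied[(t.transcript_id, sector)]
                if any(pos < e and s < pos + k for s, e in spans):
                    continue
                target[pos : pos + k] = list(tract)
                spans.append((pos, pos + k))
                truth.append(
                    MatchSite(
                        segment_id=segment_id,
                        segment_offset=offset,
                        transcript_id=t.transcript_id,
                        sector=sector,
                        position=pos,
                        k=k,
                        orientation="antisense",
                    )
                )
                break
            else:
                raise RuntimeError(
                    f"could not place planted match for {segment_id}/{sector} "
                    f"after {max_retries} retries"
                )
    rebuilt = [
        SectoredTranscript(
            transcript_id=t.transcript_id,
            utr5=NucleotideSequence(
                t.utr5.id, "".join(residues[(t.transcript_id, "utr5")])
            ),
            cds=NucleotideSequence(
                t.cds.id, "".join(residues[(t.transcript_id, "cds")])
            ),
            utr3=NucleotideSequence(
                t.utr3.id, "".join(residues[(t.transcript_id, "utr3")])
            ),
        )
        for t in transcripts
    ]
    return rebuilt, truth


def generate_inputs(config: GeneratorConfig) -> tuple[list, SyntheticSegments, list]:
    """Transcripts + segments (+ planted truth, possibly empty) in one call."""
    transcripts = generate_transcripts(config)
    synth = generate_segments(config)
    truth: list = []
    if config.planted_matches:
        transcripts, truth = plant_matches(
            transcripts, synth.segment_set, config.planted_matches, seed=config.seed + 2
        )
    return transcripts, synth, truth
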