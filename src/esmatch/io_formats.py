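"""Readers and writers for every external representation used by the pipeline.

Sequences arrive as FASTA (DNA or RNA alphabet; T is normalized to U at read
time), segment boundaries and interaction parameters as TSV, sectored mRNA
sets as either three FASTA files keyed by transcript id or a single TSV.
All coordinates in boundary tables are 1-based inclusive, following the
rRNA-literature convention; conversion to Python half-open indexing happens
exactly once, inside :mod:`esmatch.segmentation`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: residue codes accepted after T->U normalization. N is retained but never
#: participates in matching; other IUPAC ambiguity codes are rejected.
RNA_ALPHABET = frozenset("ACGUN")

SECTORS = ("utr5", "cds", "utr3")
SUBUNITS = ("LSU", "SSU")
SEG_CLASSES = ("ES", "CS")


class FastaParseError(ValueError):
    """Raised when a FASTA record is malformed or uses a non-nucleotide alphabet."""


class BoundaryTableError(ValueError):
    """Raised when a segment boundary table violates its invariants."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence with an identifier, normalized to uppercase U-alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid residues {sorted(bad)} "
                "(expected A, C, G, U or N)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and convert the DNA alphabet to RNA (T -> U)."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into normalized :class:`NucleotideSequence` records.

    Order is preserved. A record with an empty sequence or characters outside
    the IUPAC nucleotide alphabet raises :class:`FastaParseError` naming the
    record.
    """
    out: list[NucleotideSequence] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        residues = normalize_residues(str(rec.seq))
        if not rec.id:
            raise FastaParseError(f"{path}: record #{i} has an empty header")
        if not residues:
            raise FastaParseError(f"{path}: record #{i} ({rec.id!r}) is empty")
        bad = set(residues) - RNA_ALPHABET
        if bad:
            raise FastaParseError(
                f"{path}: record #{i} ({rec.id!r}) contains invalid residues "
                f"{sorted(bad)}"
            )
        out.append(NucleotideSequence(rec.id, residues))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class SegmentBoundaryRecord:
    """One named rRNA interval: expansion (ES) or core (CS), 1-based inclusive."""

    segment_id: str
    subunit: str
    seg_class: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.subunit not in SUBUNITS:
            raise BoundaryTableError(
                f"{self.segment_id}: subunit must be one of {SUBUNITS}, got {self.subunit!r}"
            )
        if self.seg_class not in SEG_CLASSES:
            raise BoundaryTableError(
                f"{self.segment_id}: seg_class must be one of {SEG_CLASSES}, got {self.seg_class!r}"
            )
        if self.start < 1 or self.end < self.start:
            raise BoundaryTableError(
                f"{self.segment_id}: invalid interval [{self.start}, {self.end}] "
                "(need 1 <= start <= end)"
            )

    @property
    def n_nt(self) -> int:
        return self.end - self.start + 1


BOUNDARY_COLUMNS = ["segment_id", "subunit", "seg_class", "start", "end"]


def validate_boundaries(records: Sequence[SegmentBoundaryRecord]) -> None:
    """Check non-overlap within each subunit; raises naming both offenders."""
    for subunit in SUBUNITS:
        recs = sorted(
            (r for r in records if r.subunit == subunit), key=lambda r: r.start
        )
        for a, b in zip(recs, recs[1:]):
            if b.start <= a.end:
                raise BoundaryTableError(
                    f"overlapping segments {a.segment_id!r} "
                    f"[{a.start},{a.end}] and {b.segment_id!r} [{b.start},{b.end}]"
                )


def read_boundary_table(path: str | Path) -> list[SegmentBoundaryRecord]:
    """Read a TSV boundary table; validates and returns records sorted by start."""
    df = pd.read_csv(path, sep="\t", dtype={"segment_id": str})
    missing = set(BOUNDARY_COLUMNS) - set(df.columns)
    if missing:
        raise BoundaryTableError(f"{path}: missing columns {sorted(missing)}")
    records = [
        SegmentBoundaryRecord(
            segment_id=str(row.segment_id),
            subunit=str(row.subunit),
            seg_class=str(row.seg_class),
            start=int(row.start),
            end=int(row.end),
        )
        for row in df.itertuples()
    ]
    validate_boundaries(records)
    return sorted(records, key=lambda r: (r.subunit, r.start))


def write_boundary_table(records: Iterable[SegmentBoundaryRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "segment_id": r.segment_id,
                "subunit": r.subunit,
                "seg_class": r.seg_class,
                "start": r.start,
                "end": r.end,
            }
            for r in records
        ],
        columns=BOUNDARY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SectoredTranscript:
    """One mRNA split into its three sectors (5'utr, cds, 3'utr)."""

    transcript_id: str
    utr5: NucleotideSequence
    cds: NucleotideSequence
    utr3: NucleotideSequence
    gene_id: str | None = None

    def sector(self, name: str) -> NucleotideSequence:
        if name not in SECTORS:
            raise KeyError(f"unknown sector {name!r}; expected one of {SECTORS}")
        return getattr(self, name)

    @property
    def total_nt(self) -> int:
        return len(self.utr5) + len(self.cds) + len(self.utr3)


def read_sectored_transcripts(
    utr5_path: str | Path,
    cds_path: str | Path,
    utr3_path: str | Path,
    *,
    strict: bool = False,
) -> list[SectoredTranscript]:
    """Assemble transcripts from three FASTA files keyed by identical IDs.

    Only IDs present in all three files are returned (the number dropped is
    logged). In strict mode a non-empty dropped set is an error instead.
    """
    by_sector = {
        "utr5": {s.id: s for s in read_fasta(utr5_path)},
        "cds": {s.id: s for s in read_fasta(cds_path)},
        "utr3": {s.id: s for s in read_fasta(utr3_path)},
    }
    shared = set(by_sector["utr5"]) & set(by_sector["cds"]) & set(by_sector["utr3"])
    if not shared:
        raise ValueError(
            "no transcript IDs shared between the three sector FASTA files"
        )
    dropped = (
        set().union(*(set(d) for d in by_sector.values())) - shared
    )
    if dropped:
        if strict:
            raise ValueError(
                f"{len(dropped)} transcript IDs missing from at least one sector file "
                f"(strict mode): e.g. {sorted(dropped)[:5]}"
            )
        logger.warning(
            "dropped %d transcript IDs missing from at least one sector file",
            len(dropped),
        )
    # order follows the utr5 file for determinism
    ordered = [tid for tid in by_sector["utr5"] if tid in shared]
    return [
        SectoredTranscript(
            transcript_id=tid,
            utr5=by_sector["utr5"][tid],
            cds=by_sector["cds"][tid],
            utr3=by_sector["utr3"][tid],
        )
        for tid in ordered
    ]


def read_sectored_tsv(path: str | Path) -> list[SectoredTranscript]:
    """Read a single-TSV sectored transcript table (synthetic-data convenience).

    Columns: transcript_id, utr5, cds, utr3 (sequence strings; DNA or RNA).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"transcript_id", "utr5", "cds", "utr3"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        tid = str(row.transcript_id)
        out.append(
            SectoredTranscript(
                transcript_id=tid,
                utr5=NucleotideSequence(f"{tid}|utr5", normalize_residues(row.utr5)),
                cds=NucleotideSequence(f"{tid}|cds", normalize_residues(row.cds)),
                utr3=NucleotideSequence(f"{tid}|utr3", normalize_residues(row.utr3)),
            )
        )
    return out


def write_sectored_tsv(transcripts: Iterable[SectoredTranscript], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "utr5": t.utr5.residues,
                "cds": t.cds.residues,
                "utr3": t.utr3.residues,
            }
            for t in transcripts
        ],
        columns=["transcript_id", "utr5", "cds", "utr3"],
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class InteractionParamTable:
    """Per-base amino-acid interaction weights (hydrogen bonding, van der Waals)."""

    hbond: dict = field(default_factory=dict)
    vdw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mode, weights in (("hbond", self.hbond), ("vdw", self.vdw)):
            if set(weights) != set("ACGU"):
                raise ValueError(f"{mode}: weights required for exactly A,C,G,U")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{mode}: weights must be non-negative")
            if all(w == 0 for w in weights.values()):
                raise ValueError(f"{mode}: at least one weight must be positive")

    def weights(self, mode: str) -> dict:
        if mode == "hbond":
            return self.hbond
        if mode == "vdw":
            return self.vdw
        raise KeyError(f"unknown mode {mode!r}; expected 'hbond' or 'vdw'")


def read_interaction_params(path: str | Path) -> InteractionParamTable:
    """Read a TSV with columns base, hbond_weight, vdw_weight (one row per base)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"base", "hbond_weight", "vdw_weight"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    hbond = {str(r.base).upper(): float(r.hbond_weight) for r in df.itertuples()}
    vdw = {str(r.base).upper(): float(r.vdw_weight) for r in df.itertuples()}
    return InteractionParamTable(hbond=hbond, vdw=vdw)


def write_interaction_params(params: InteractionParamTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"base": b, "hbond_weight": params.hbond[b], "vdw_weight": params.vdw[b]}
            for b in "ACGU"
        ]
    )
    df.to_csv(path, sep="\t", index=False)


TALLY_COLUMNS = ["segment_id", "sector", "match_length", "orientation", "count"]


def write_tally(tally, path: str | Path) -> None:
    """Write the per-cell match counts as TSV in deterministic row order."""
    rows = [
        {
            "segment_id": seg,
            "sector": sector,
            "match_length": k,
            "orientation": orientation,
            "count": count,
        }
        for (seg, sector, k, orientation), count in sorted(tally.cells.items())
    ]
    pd.DataFrame(rows, columns=TALLY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tally(path: str | Path):
    """Re-read a tally TSV into a MatchTally (cells only; no per-transcript data)."""
    from .match_engine import MatchTally  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"segment_id": str, "sector": str})
    missing = set(TALLY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    cells = {
        (str(r.segment_id), str(r.sector), int(r.match_length), str(r.orientation)): int(
            r.count
        )
        for r in df.itertuples()
    }
    return MatchTally(cells=cells, per_transcript={}, n_transcripts=0)


def write_run_metadata(path: str | Path, metadata: dict) -> None:
    """JSON sidecar recording inputs, configuration, seed and package version."""
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
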