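"""Summary statistics derived from a match tally.

Covers the published summary shapes: per-group match totals over a k range,
match densities (per segment nucleotide, optionally per 1,000 transcripts),
percentages relative to a reference group, per-k sector ratios, GC content of
matched tracts and of the matched sectors, and the log-linear decay of match
counts with match length.

A note on the density convention: total matches divided by segment
nucleotides, with NO extra factor (a 2,387-nt group with 19.312e6 matches has
density ~8,090 per nt). ``density`` exposes an explicit scale argument so the
caller always knows which units a number carries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import SECTORS, SectoredTranscript
from .match_engine import MatchTally
from .segmentation import GROUPS, RnaSegment, gc_content

logger = logging.getLogger(__name__)

DENSITY_SCALES = ("per_nt", "per_nt_per_1000_mrna")


@dataclass
class DecayRegressionFit:
    """OLS fit of log10(match count) on match length k."""

    slope: float
    intercept: float
    slope_sd: float
    r_squared: float
    n_points: int
    excluded_ks: tuple = ()
    group: str | None = None
    sector: str | None = None

    @property
    def fold_decrease_per_nt(self) -> float:
        """Multiplicative drop in match count per added nucleotide: 10**(-slope)."""
        return 10.0 ** (-self.slope)


@dataclass
class SegmentGroupSummary:
    """Aggregated totals, densities and percentages for one segment group."""

    group: str
    total_nt: int
    matches: dict = field(default_factory=dict)  # sector -> count; "all" -> pooled
    density: dict = field(default_factory=dict)
    pct_of_reference: dict = field(default_factory=dict)
    regressions: dict = field(default_factory=dict)  # sector -> DecayRegressionFit


def group_totals(
    tally: MatchTally,
    group_of: Mapping[str, str],
    k_lo: int = 7,
    k_hi: int = 15,
    orientation: str = "antisense",
    expected_groups: Sequence[str] | None = None,
) -> dict:
    """Sum cell counts over member segments and k in [k_lo, k_hi].

    Returns {(group, sector): count} plus pooled {(group, "all"): count}.
    ``expected_groups`` widens the output to groups that must be present; an
    expected group with no member segments is an error (it cannot be
    distinguished from a typo'd label).
    """
    if not group_of:
        raise ValueError("group_of is empty: no segments assigned to any group")
    groups = sorted(set(group_of.values()) | set(expected_groups or ()))
    members: dict = {g: [s for s, gg in group_of.items() if gg == g] for g in groups}
    for g, segs in members.items():
        if not segs:
            raise ValueError(f"group {g!r} has no member segments")
    totals = {(g, sector): 0 for g in groups for sector in SECTORS + ("all",)}
    for (seg, sector, k, orient), c in tally.cells.items():
        if orient != orientation or not (k_lo <= k <= k_hi):
            continue
        g = group_of.get(seg)
        if g is None:
            continue
        totals[(g, sector)] += c
        totals[(g, "all")] += c
    return totals


def density(
    total_matches: float,
    total_nt: int,
    n_transcripts: int | None = None,
    scale: str = "per_nt",
) -> float:
    """Match density per segment nucleotide, optionally per 1,000 transcripts."""
    if total_nt < 1:
        raise ValueError("total_nt must be >= 1")
    if scale not in DENSITY_SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {DENSITY_SCALES}")
    d = total_matches / total_nt
    if scale == "per_nt_per_1000_mrna":
        if not n_transcripts:
            raise ValueError("per_nt_per_1000_mrna scale requires n_transcripts")
        d /= n_transcripts / 1000.0
    return d


def percent_of_reference(value: float, reference_value: float) -> float:
    """100 * value / reference_value."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * value / reference_value


def sector_ratio(
    tally: MatchTally,
    group_of: Mapping[str, str],
    group: str,
    numerator_sector: str,
    denominator_sector: str,
    k_values: Sequence[int],
    orientation: str = "antisense",
) -> dict:
    """Per-k ratio of group match counts between two sectors.

    A zero denominator at some k yields NaN for that k (undefined, not an
    exception), so decay curves can run into the sparse tail gracefully.
    """
    out: dict = {}
    for k in k_values:
        totals = group_totals(tally, group_of, k_lo=k, k_hi=k, orientation=orientation)
        num = totals[(group, numerator_sector)]
        den = totals[(group, denominator_sector)]
        out[k] = num / den if den > 0 else float("nan")
    return out


def gc_of_matches(
    tally: MatchTally,
    group_of: Mapping[str, str],
    group: str,
    sector: str,
    k: int,
    orientation: str = "antisense",
    *,
    weighting: str = "occurrence",
) -> float:
    """GC percent of matched mRNA tracts, pooled over a segment group.

    ``occurrence`` weighting counts each match instance once (a tract matched
    five times contributes five times); ``unique`` counts each distinct tract
    once. Requires tract recording at count time. With no matches the value
    is undefined and NaN is returned (flagged via log).
    """
    if tally.tract_counts is None:
        raise ValueError("tract recording was not enabled for this tally")
    if weighting not in ("occurrence", "unique"):
        raise ValueError("weighting must be 'occurrence' or 'unique'")
    gc_nt = 0
    total_nt = 0
    for (seg, sec, kk, orient), counter in tally.tract_counts.items():
        if sec != sector or kk != k or orient != orientation:
            continue
        if group_of.get(seg) != group:
            continue
        for tract, n in counter.items():
            w = n if weighting == "occurrence" else 1
            gc_nt += w * (tract.count("G") + tract.count("C"))
            total_nt += w * len(tract)
    if total_nt == 0:
        logger.warning("gc_of_matches undefined: no %s matches for %s/%s k=%d",
                       orientation, group, sector, k)
        return float("nan")
    return 100.0 * gc_nt / total_nt


def gc_of_matched_sectors(
    tally: MatchTally,
    transcripts: Sequence[SectoredTranscript],
    group_of: Mapping[str, str],
    group: str,
    sector: str,
    k: int,
    orientation: str = "antisense",
    *,
    weighting: str = "unweighted",
) -> float:
    """Mean GC of the full sector sequences of transcripts matched by the group.

    A transcript qualifies when it has >= 1 match at length k, in this sector,
    to any member segment. ``unweighted`` averages one value per qualifying
    sector; ``nt_weighted`` weights by sector length. NaN when nothing
    qualifies.
    """
    if weighting not in ("unweighted", "nt_weighted"):
        raise ValueError("weighting must be 'unweighted' or 'nt_weighted'")
    matched_ids = {
        tid
        for (seg, sec, kk, orient, tid), c in tally.per_transcript.items()
        if sec == sector
        and kk == k
        and orient == orientation
        and c > 0
        and group_of.get(seg) == group
    }
    if not matched_ids:
        logger.warning("gc_of_matched_sectors undefined: no qualifying %s/%s k=%d",
                       group, sector, k)
        return float("nan")
    values, weights = [], []
    for t in transcripts:
        if t.transcript_id in matched_ids:
            seq = t.sector(sector)
            values.append(gc_content(seq))
            weights.append(len(seq) if weighting == "nt_weighted" else 1.0)
    return float(np.average(values, weights=weights))


def decay_regression(
    counts_by_k: Mapping[int, float],
    k_lo: int = 7,
    k_hi: int = 15,
    *,
    group: str | None = None,
    sector: str | None = None,
) -> DecayRegressionFit:
    """OLS of log10(count) on match length k over [k_lo, k_hi].

    Zero (or missing) counts cannot enter the log and are excluded with a
    logged warning; fewer than 3 usable points is an error.
    """
    xs, ys, excluded = [], [], []
    for k in range(k_lo, k_hi + 1):
        c = counts_by_k.get(k, 0)
        if c > 0:
            xs.append(float(k))
            ys.append(math.log10(c))
        else:
            excluded.append(k)
    if excluded:
        logger.warning("decay_regression: excluded zero-count k values %s", excluded)
    if len(xs) < 3:
        raise ValueError(
            f"decay_regression needs >= 3 nonzero counts in [{k_lo},{k_hi}]; "
            f"got {len(xs)}"
        )
    fit = sps.linregress(xs, ys)
    return DecayRegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_sd=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        n_points=len(xs),
        excluded_ks=tuple(excluded),
        group=group,
        sector=sector,
    )


def summarize_groups(
    tally: MatchTally,
    segments: Sequence[RnaSegment],
    *,
    k_lo: int = 7,
    k_hi: int = 15,
    reference_group: str = "ESL",
    orientation: str = "antisense",
    density_scale: str = "per_nt",
) -> dict:
    """Build one :class:`SegmentGroupSummary` per group present in ``segments``.

    Percentages are taken against ``reference_group`` for both totals and
    densities; decay regressions are fitted per group and sector over the
    same k range.
    """
    group_of = {s.segment_id: s.group for s in segments}
    present = sorted(set(group_of.values()), key=GROUPS.index)
    if reference_group not in present:
        raise ValueError(
            f"reference group {reference_group!r} absent from segments "
            f"(present: {present})"
        )
    nt_by_group = {g: 0 for g in present}
    for s in segments:
        nt_by_group[s.group] += s.n_nt
    totals = group_totals(tally, group_of, k_lo=k_lo, k_hi=k_hi, orientation=orientation)

    summaries: dict = {}
    for g in present:
        summary = SegmentGroupSummary(group=g, total_nt=nt_by_group[g])
        for sector in SECTORS + ("all",):
            total = totals[(g, sector)]
            summary.matches[sector] = total
            summary.density[sector] = density(
                total,
                nt_by_group[g],
                n_transcripts=tally.n_transcripts or None,
                scale=density_scale,
            )
        members = [s for s, gg in group_of.items() if gg == g]
        for sector in SECTORS:
            by_k = {
                k: sum(tally.count(seg, sector, k, orientation) for seg in members)
                for k in range(k_lo, k_hi + 1)
            }
            try:
                summary.regressions[sector] = decay_regression(
                    by_k, k_lo, k_hi, group=g, sector=sector
                )
            except ValueError:
                logger.warning("no decay regression for %s/%s (sparse counts)", g, sector)
        summaries[g] = summary

    ref = summaries[reference_group]
    for g, summary in summaries.items():
        for sector in SECTORS + ("all",):
            if ref.matches[sector] > 0:
                summary.pct_of_reference[sector] = percent_of_reference(
                    summary.matches[sector], ref.matches[sector]
                )
            else:
                summary.pct_of_reference[sector] = float("nan")
    return summaries
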