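"""Composition-weighted nucleobase-protein interaction frequencies.

Given per-base interaction weights for a mode (hydrogen bonding or van der
Waals contact of amino acids with nucleobases), the profile of a segment
group is its pooled base composition reweighted by those parameters and
renormalized to 100%:

    freq[b] = 100 * n_b * w(b) / sum_b' n_b' * w(b')

Backbone (ribose/phosphate) contributions are excluded: the score covers
nucleobases only, which is recorded in the output metadata. The weight table
is an external input; the repo ships only a synthetic stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import InteractionParamTable
from .segmentation import RnaSegment

MODES = ("hbond", "vdw")

#: synthetic per-base weights (NOT the published parameter source) with the
#: qualitative structure of amino-acid/nucleobase contact statistics: guanine
#: the most contacted base in both modes, pyrimidines intermediate.
SYNTHETIC_PARAMS = InteractionParamTable(
    hbond={"A": 0.80, "C": 1.30, "G": 2.00, "U": 1.20},
    vdw={"A": 1.00, "C": 1.10, "G": 1.60, "U": 0.90},
)


@dataclass
class PotentialProfile:
    """Normalized interaction-frequency profile for one segment group."""

    group: str
    mode: str
    freq: dict = field(default_factory=dict)  # base -> percent, sums to 100

    @property
    def gc_sum(self) -> float:
        """Combined G+C contribution, the headline column of the profile."""
        return self.freq["G"] + self.freq["C"]


def pooled_base_counts(segments: Iterable[RnaSegment]) -> dict:
    counts = {b: 0 for b in "ACGU"}
    for s in segments:
        for b in "ACGU":
            counts[b] += s.sequence.residues.count(b)
    return counts


def interaction_profile(
    segments: Iterable[RnaSegment],
    params: InteractionParamTable,
    mode: str,
    *,
    group: str | None = None,
) -> PotentialProfile:
    """Weighted-composition interaction frequencies for a pool of segments."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    segs = list(segments)
    if not segs:
        raise ValueError("interaction_profile of an empty segment list is undefined")
    counts = pooled_base_counts(segs)
    if sum(counts.values()) == 0:
        raise ValueError("segments contain no unambiguous bases")
    weights = params.weights(mode)
    contributions: Mapping[str, float] = {
        b: counts[b] * weights[b] for b in "ACGU"
    }
    total = sum(contributions.values())
    if total == 0:
        raise ValueError("all weighted contributions are zero")
    label = group if group is not None else segs[0].group
    return PotentialProfile(
        group=label,
        mode=mode,
        freq={b: 100.0 * contributions[b] / total for b in "ACGU"},
    )


def group_profiles(
    segments: Iterable[RnaSegment], params: InteractionParamTable
) -> list[PotentialProfile]:
    """One profile per (group, mode) over the pooled member segments."""
    by_group: dict = {}
    for s in segments:
        by_group.setdefault(s.group, []).append(s)
    return [
        interaction_profile(members, params, mode, group=g)
        for g in sorted(by_group)
        for mode in MODES
        for members in [by_group[g]]
    ]
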