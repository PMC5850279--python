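"""End-to-end orchestration: segments -> match -> metrics -> null -> potential.

One :class:`RunConfig` (loadable from YAML) drives every stage; the output
directory receives the per-stage tables plus a JSON manifest that fully
serializes the configuration, the seed and the package version, so two runs
with equal manifests produce equal outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    SECTORS,
    read_boundary_table,
    read_fasta,
    read_interaction_params,
    read_sectored_transcripts,
    read_sectored_tsv,
    write_run_metadata,
    write_tally,
)
from .match_engine import count_matches
from .metrics import gc_of_matched_sectors, gc_of_matches, summarize_groups
from .null_models import pooled_scramble_stats, scramble_comparison
from .protein_potential import SYNTHETIC_PARAMS, group_profiles
from .segmentation import SegmentSet, extract_segments
from .synthetic_data import GeneratorConfig, generate_inputs

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; names the stage for actionable errors."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    out_dir: str = "esmatch_run"
    # input paths; when rrna_fasta is None the synthetic generator is used
    rrna_fasta: str | None = None
    boundary_table: str | None = None
    transcripts_tsv: str | None = None
    sector_fastas: tuple | None = None  # (utr5, cds, utr3)
    params_table: str | None = None
    # analysis settings (defaults follow the reference analysis: totals over
    # 7-15 nt within an extended 7-20 scan, reference group ESL, 10 shuffles)
    k_min: int = 7
    k_max: int = 20
    total_k_min: int = 7
    total_k_max: int = 15
    orientations: tuple = ("antisense", "sense")
    reference_group: str = "ESL"
    density_scale: str = "per_nt"
    gc_match_lengths: tuple = (7, 10)
    n_scramble_replicates: int = 10
    scramble_k: int = 7
    min_es_nt: int = 6
    strict: bool = False
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # GeneratorConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("orientations", "sector_fastas", "gc_match_lengths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_inputs(config: RunConfig):
    """Return (segments: SegmentSet, transcripts, manifest_inputs)."""
    if config.rrna_fasta is None:
        gen_kwargs = dict(config.synthetic)
        gen_kwargs.setdefault("seed", config.seed)
        gen = GeneratorConfig(**gen_kwargs)
        transcripts, synth, _truth = generate_inputs(gen)
        return (
            synth.segment_set,
            transcripts,
            {"source": "synthetic", "generator": str(asdict(gen))},
        )
    rrnas = read_fasta(config.rrna_fasta)
    boundaries = read_boundary_table(config.boundary_table)
    segments = []
    for rrna in rrnas:
        # match records to an rRNA by subunit tag in the sequence id when
        # present (e.g. ">synthetic_LSU"), otherwise apply the whole table
        recs = [b for b in boundaries if b.subunit in rrna.id] or boundaries
        seg_set = extract_segments(
            rrna, recs, min_es_nt=config.min_es_nt, strict=config.strict
        )
        segments.extend(seg_set.segments)
    segment_set = SegmentSet(parent_id="input", segments=segments)
    if config.transcripts_tsv:
        transcripts = read_sectored_tsv(config.transcripts_tsv)
    elif config.sector_fastas:
        transcripts = read_sectored_transcripts(
            *config.sector_fastas, strict=config.strict
        )
    else:
        raise ValueError("no transcript input configured")
    return (
        segment_set,
        transcripts,
        {
            "source": "files",
            "rrna_fasta": config.rrna_fasta,
            "boundary_table": config.boundary_table,
        },
    )


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        raise PipelineStageError(name, exc) from exc
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output tables; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    segment_set, transcripts, input_meta = _stage("segmentation", _load_inputs, config)

    seg_rows = [
        {
            "segment_id": s.segment_id,
            "group": s.group,
            "n_nt": s.n_nt,
            "gc_percent": round(s.gc_percent, 4),
            "sequence": s.sequence.residues,
        }
        for s in segment_set
    ]
    pd.DataFrame(seg_rows).to_csv(out / "segments.tsv", sep="\t", index=False)

    tally = _stage(
        "match",
        count_matches,
        segment_set,
        transcripts,
        k_range=(config.k_min, config.k_max),
        orientations=config.orientations,
        record_tracts=True,
    )
    tally.validate()
    write_tally(tally, out / "tally.tsv")

    summaries = _stage(
        "metrics",
        summarize_groups,
        tally,
        list(segment_set),
        k_lo=config.total_k_min,
        k_hi=config.total_k_max,
        reference_group=config.reference_group,
        density_scale=config.density_scale,
    )
    report_table1(summaries, out / "summary.tsv", reference_group=config.reference_group)

    reg_rows = []
    for g, summary in summaries.items():
        for sector, fit in summary.regressions.items():
            reg_rows.append(
                {
                    "group": g,
                    "sector": sector,
                    "slope": fit.slope,
                    "slope_sd": fit.slope_sd,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                }
            )
    pd.DataFrame(reg_rows).to_csv(out / "regressions.tsv", sep="\t", index=False)

    group_of = {s.segment_id: s.group for s in segment_set}
    gc_rows = []
    for k in config.gc_match_lengths:
        for g in sorted({s.group for s in segment_set}):
            row = {"group": g, "match_length": k}
            for sector in SECTORS:
                row[f"{sector}_match_gc"] = gc_of_matches(
                    tally, group_of, g, sector, k
                )
                row[f"{sector}_matched_sector_gc"] = gc_of_matched_sectors(
                    tally, transcripts, group_of, g, sector, k
                )
            gc_rows.append(row)
    pd.DataFrame(gc_rows).to_csv(out / "gc.tsv", sep="\t", index=False)

    def _null_stage():
        reports = []
        for s in segment_set:
            if s.group.startswith("ES") and s.n_nt >= config.scramble_k:
                reports.append(
                    scramble_comparison(
                        s,
                        transcripts,
                        n_replicates=config.n_scramble_replicates,
                        k=config.scramble_k,
                        seed=config.seed + 10_000,
                    )
                )
        return reports

    null_reports = _stage("null", _null_stage)
    null_rows = [
        {
            "segment_id": r.segment_id,
            "k": r.k,
            "n_replicates": r.n_replicates,
            "native_matched": r.native_matched,
            "replicate_matched_mean": sum(r.replicate_matched) / len(r.replicate_matched),
            "mean_abs_pct_diff": r.mean_abs_pct_diff,
            "cv_pct": r.cv_pct,
        }
        for r in null_reports
    ]
    pd.DataFrame(null_rows).to_csv(out / "null_report.tsv", sep="\t", index=False)
    null_pooled = pooled_scramble_stats(null_reports) if null_reports else {}

    params_source = "synthetic_default"
    params = SYNTHETIC_PARAMS
    if config.params_table:
        params = _stage("potential", read_interaction_params, config.params_table)
        params_source = str(config.params_table)
    profiles = _stage("potential", group_profiles, list(segment_set), params)
    pot_rows = [
        {
            "group": p.group,
            "mode": p.mode,
            "base": b,
            "freq_percent": p.freq[b],
            "gc_sum": p.gc_sum,
        }
        for p in profiles
        for b in "ACGU"
    ]
    pd.DataFrame(pot_rows).to_csv(out / "potential.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "inputs": input_meta,
        "seed": config.seed,
        "n_transcripts": len(transcripts),
        "n_segments": len(segment_set),
        "interaction_params_source": params_source,
        "scramble_pooled": null_pooled,
        "notes": "protein-interaction profile covers nucleobases only (no backbone)",
    }
    write_run_metadata(out / "manifest.json", manifest)
    return manifest


def report_table1(
    summaries: dict, path: str | Path, reference_group: str = "ESL"
) -> pd.DataFrame:
    """Per-group summary table: nt, match totals, densities, % of reference, slopes."""
    if len(summaries) < 2:
        raise ValueError("need summaries for at least 2 groups")
    if reference_group not in summaries:
        raise ValueError(f"reference group {reference_group!r} missing from summaries")
    rows = []
    for g, s in summaries.items():
        row = {"group": g, "total_nt": s.total_nt}
        for sector in ("all",) + SECTORS:
            row[f"matches_{sector}"] = s.matches[sector]
            row[f"density_{sector}"] = s.density[sector]
            row[f"pct_of_{reference_group}_{sector}"] = s.pct_of_reference[sector]
        for sector in SECTORS:
            fit = s.regressions.get(sector)
            row[f"slope_{sector}"] = fit.slope if fit else float("nan")
            row[f"slope_sd_{sector}"] = fit.slope_sd if fit else float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
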