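"""End-to-end orchestration: simulate/load -> count -> normalize -> segment -> call -> report.

Everything here is plumbing over the library modules; every number in a
report is recomputable by calling the module operations directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import coverage as cov_mod
from . import segmentation as seg_mod
from .events import (
    InversionCall,
    arm_status,
    call_centric_fusions,
    call_deletions,
    infer_pericentric_inversion,
    parse_translocation_name,
    summarize_introgression,
)
from .reference import BARLEY, HybridReference, default_hybrid_reference, read_chromosome_specs
from .segmentation import SegmentationParams, SegmentCall, label_1based
from .simulate import SimParams, apply_events, get_scenario, simulate_bin_counts, write_truth_bed

logger = logging.getLogger("introcov")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """One pipeline run: exactly one input mode, thresholds, seed, output dir."""

    out_dir: Path
    reference_path: Optional[Path] = None
    bin_size_mb: int = 1
    scenario: Optional[str] = None
    placements_path: Optional[Path] = None
    counts_path: Optional[Path] = None
    sim: SimParams = field(default_factory=SimParams)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    min_deletion_mb: float = 5.0

    def __post_init__(self) -> None:
        modes = [m for m in (self.scenario, self.placements_path, self.counts_path) if m]
        if len(modes) != 1:
            raise ValueError(
                "exactly one input mode required: scenario, placements or counts"
            )


def load_reference(path: Optional[Path], bin_size_mb: int = 1) -> HybridReference:
    if path is None:
        return default_hybrid_reference(bin_size_mb=bin_size_mb)
    return HybridReference(read_chromosome_specs(path), bin_size_mb=bin_size_mb)


def _coverage_for(config: RunConfig, ref: HybridReference) -> cov_mod.BinCoverage:
    if config.scenario:
        scenario = get_scenario(config.scenario)
        karyotype = apply_events(ref, scenario.events)
        raw = simulate_bin_counts(karyotype, config.sim)
        write_truth_bed(karyotype, Path(config.out_dir) / "truth.bed")
        return cov_mod.BinCoverage(ref=ref, raw=raw)
    if config.placements_path:
        placements = cov_mod.read_placements_bed(config.placements_path)
        return cov_mod.count_reads(placements, ref)
    return cov_mod.read_bin_table(config.counts_path, ref)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write bins.tsv / segments.{bed,tsv} / report.json.

    Returns the report dict; raises on any stage failure (partial outputs are
    removed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        ref = load_reference(config.reference_path, config.bin_size_mb)
        logger.info("reference: %d chromosomes, %d bins", len(ref.chromosomes), ref.n_bins)

        cov = _coverage_for(config, ref)
        cov = cov_mod.normalize(cov)
        bins_path = out / "bins.tsv"
        cov_mod.write_bin_table(cov, bins_path)
        written.append(bins_path)
        logger.info("normalization constant M = %s (%s)", cov.norm_constant, cov.method)

        segments = seg_mod.segment_all(cov, config.seg)
        seg_mod.write_segments_bed(segments, out / "segments.bed")
        seg_mod.write_segments_tsv(segments, out / "segments.tsv")
        written += [out / "segments.bed", out / "segments.tsv"]

        report = build_report(segments, ref, cov, config)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(report_path)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def build_report(
    segments: dict[str, list[SegmentCall]],
    ref: HybridReference,
    cov: cov_mod.BinCoverage,
    config: RunConfig,
) -> dict:
    statuses = []
    for chrom in ref.chrom_names():
        s, l = arm_status(segments[chrom], ref, chrom)
        statuses += [s, l]
    fusions, diagnostics = call_centric_fusions(statuses, ref)

    # mask arms lost to a called fusion so they are not re-reported as deletions
    exclude: dict[str, list[tuple[float, float]]] = {}
    for call in fusions:
        wheat_arm = call.wheat_arm  # the surviving arm; the *other* arm was lost
        chrom, kept = wheat_arm[:-1], wheat_arm[-1]
        spec = ref.spec(chrom)
        lost_interval = (
            (float(spec.centromere_mb), float(spec.length_mb))
            if kept == "S"
            else (0.0, float(spec.centromere_mb))
        )
        exclude.setdefault(chrom, []).append(lost_interval)

    deletions = []
    for chrom in ref.chrom_names():
        deletions += call_deletions(
            segments[chrom], ref, chrom,
            min_length_mb=config.min_deletion_mb,
            exclude=exclude.get(chrom, ()),
        )

    summaries = []
    for spec in ref.chromosomes:
        if spec.subgenome != BARLEY:
            continue
        summary = summarize_introgression(segments[spec.name], ref, spec.name)
        if summary.total_present_mb > 0:
            summaries.append(summary)

    return {
        "schema": SCHEMA_VERSION,
        "parameters": {
            "bin_size_mb": ref.bin_size_mb,
            "tau_absent": config.seg.tau_absent,
            "tau_present": config.seg.tau_present,
            "min_run": config.seg.min_run,
            "min_deletion_mb": config.min_deletion_mb,
            "normalization": cov.method,
            "norm_constant": cov.norm_constant,
        },
        "provenance": {
            "input_mode": (
                f"simulate:{config.scenario}" if config.scenario
                else ("placements" if config.placements_path else "counts")
            ),
            "reference": str(config.reference_path) if config.reference_path else "builtin",
            "seed": config.sim.seed if config.scenario else None,
            "depth_per_bin": config.sim.depth_per_bin if config.scenario else None,
        },
        "translocations": [dataclasses.asdict(c) for c in fusions],
        "deletions": [
            {**dataclasses.asdict(d), "length_mb": d.length_mb} for d in deletions
        ],
        "inversions": [],
        "summaries": [
            {
                "chrom": s.chrom,
                "total_present_mb": s.total_present_mb,
                "percent_of_chromosome": s.percent_of_chromosome,
                "segments": [
                    {
                        "start_mb": seg.start_mb,
                        "end_mb": seg.end_mb,
                        "length_mb": seg.length_mb,
                        "label": label_1based(seg),
                    }
                    for seg in s.segments
                ],
            }
            for s in summaries
        ],
        "diagnostics": diagnostics,
    }


def compare_lines(
    run_dir_a: Path, run_dir_b: Path, chrom: str, reference_path: Optional[Path] = None,
    bin_size_mb: int = 1,
) -> tuple[Optional[InversionCall], str, pd.DataFrame]:
    """Joint view of two completed runs on one chromosome + inversion inference.

    Reads each run's segments.tsv, builds a side-by-side per-bin table, and
    applies the complementary-carrier inversion test.
    """
    ref = load_reference(reference_path, bin_size_mb)
    segs_a = seg_mod.read_segments_tsv(Path(run_dir_a) / "segments.tsv")
    segs_b = seg_mod.read_segments_tsv(Path(run_dir_b) / "segments.tsv")
    if chrom not in segs_a or chrom not in segs_b:
        raise ValueError(f"chromosome {chrom!r} missing from one of the runs")
    call, reason = infer_pericentric_inversion(segs_a[chrom], segs_b[chrom], ref, chrom)

    sl = ref.chrom_slice(chrom)
    bins = ref.bins.iloc[sl.start : sl.stop][["start_mb", "end_mb"]].copy()

    def states(segs: list[SegmentCall]) -> list[str]:
        out = []
        for s0, _ in zip(bins["start_mb"], bins["end_mb"]):
            state = next(
                (s.state for s in segs if s.start_mb <= s0 < s.end_mb), "?"
            )
            out.append(state)
        return out

    bins["line_a"] = states(segs_a[chrom])
    bins["line_b"] = states(segs_b[chrom])
    return call, reason, bins.reset_index(drop=True)
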