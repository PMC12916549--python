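#!/usr/bin/env python
"""Segment the simulated lines and call their structural events.

Reads the bin tables written by 01_simulate_lines.py, segments every
chromosome into present/absent blocks, and interprets them: centric-fusion
nomenclature, background deletions, and per-line barley-chromatin summaries.
Writes segments.{bed,tsv} and report.json under results/<line>/ and prints
what it found.
"""

import json
from pathlib import Path

import introcov as ic
from introcov.coverage import read_bin_table
from introcov.pipeline import RunConfig, build_report
from introcov.segmentation import label_1based, write_segments_bed, write_segments_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ref = ic.default_hybrid_reference()
    for name in ("T6HS.6BL", "T6BS.6HL", "T4BS.4HL"):
        out = OUT / name
        cov = read_bin_table(out / "bins.tsv", ref)
        segments = ic.segment_all(cov)
        write_segments_bed(segments, out / "segments.bed")
        write_segments_tsv(segments, out / "segments.tsv")

        config = RunConfig(out_dir=out, scenario=name)
        report = build_report(segments, ref, cov, config)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

        print(f"\n== {name} ==")
        for t in report["translocations"]:
            print(f"  centric fusion: {t['name']} (group {t['homoeologous_group']})")
        for d in report["deletions"]:
            print(f"  deletion: {d['chrom']} {d['kind']} {d['length_mb']:g} Mb "
                  f"[{d['start_mb']:g}, {d['end_mb']:g})")
        for s in report["summaries"]:
            blocks = ", ".join(
                f"{b['length_mb']:g} Mb ({b['label']})" for b in s["segments"]
            )
            print(f"  barley chromatin on {s['chrom']}: {s['total_present_mb']:g} Mb "
                  f"= {s['percent_of_chromosome']}% of the chromosome; blocks: {blocks}")


if __name__ == "__main__":
    main()
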