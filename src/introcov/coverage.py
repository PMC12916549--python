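"""Per-Mb-bin read counting and normalization on the hybrid reference.

Mapped-read positions (BED-like text or SAM text) are reduced to raw counts
per bin and then normalized so that a fully present, disomic region of the
genome centres near 1.0 -- the unit in which present/absent calls and all
reported coverage values are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reference import HybridReference

NORMALIZATION_METHODS = ("median_nonzero", "mean_top_half")


@dataclass
class BinCoverage:
    """Raw and (once filled) normalized read counts per bin, reference order."""

    ref: HybridReference
    raw: np.ndarray
    normalized: Optional[np.ndarray] = None
    norm_constant: Optional[float] = None
    method: Optional[str] = None

    def chrom_raw(self, chrom: str) -> np.ndarray:
        return self.raw[self.ref.chrom_slice(chrom)]

    def chrom_normalized(self, chrom: str) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("coverage not normalized yet")
        return self.normalized[self.ref.chrom_slice(chrom)]

    def to_frame(self) -> pd.DataFrame:
        df = self.ref.bins[["chrom", "start_mb", "end_mb"]].copy()
        df["raw_count"] = self.raw
        df["normalized"] = np.nan if self.normalized is None else self.normalized
        return df


@dataclass(frozen=True)
class SequencingSummary:
    n_reads: int
    sum_length_bp: int
    average_coverage: float


def count_reads(placements: pd.DataFrame, ref: HybridReference) -> BinCoverage:
    """Assign each read to the bin containing its start position.

    ``placements`` needs columns chrom, start_bp (end_bp ignored for binning).
    Every placement lands in exactly one bin, so bin counts sum to the number
    of reads.
    """
    raw = np.zeros(ref.n_bins, dtype=np.int64)
    if len(placements) == 0:
        return BinCoverage(ref=ref, raw=raw)
    known = {s.name for s in ref.chromosomes}
    chroms = placements["chrom"].to_numpy()
    bad = ~np.isin(chroms, list(known))
    if bad.any():
        record = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"placement record {record} maps to unknown chromosome {chroms[record]!r}"
        )
    start_mb = placements["start_bp"].to_numpy(np.float64) / 1_000_000
    bin_size = ref.bin_size_mb
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        spec = ref.spec(chrom)
        pos = start_mb[sel]
        if (pos < 0).any() or (pos >= spec.length_mb).any():
            raise ValueError(f"placement outside chromosome {chrom} (length {spec.length_mb} Mb)")
        local = (pos // bin_size).astype(np.int64)
        sl = ref.chrom_slice(chrom)
        raw[sl.start : sl.stop] += np.bincount(local, minlength=sl.stop - sl.start)
    return BinCoverage(ref=ref, raw=raw)


def normalize(cov: BinCoverage, method: str = "median_nonzero") -> BinCoverage:
    """Fill normalized values: raw / (M * bin_length_fraction).

    The scaling constant M is the median raw count over non-empty bins
    (default) -- robust when a large fraction of the reference is absent, and
    it lands present euploid bins near 1.0.  ``mean_top_half`` (mean of the
    upper half of non-empty bin counts) is available as an alternative.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    nonzero = cov.raw[cov.raw > 0]
    if nonzero.size == 0:
        raise ValueError("no informative bins: every bin has zero reads")
    if method == "median_nonzero":
        m = float(np.median(nonzero))
    else:
        top = np.sort(nonzero)[nonzero.size // 2 :]
        m = float(top.mean())
    normalized = cov.raw / (m * cov.ref.bin_fraction)
    return BinCoverage(
        ref=cov.ref, raw=cov.raw, normalized=normalized, norm_constant=m, method=method
    )


def chromosome_mean(cov: BinCoverage, chrom: str) -> float:
    """Mean normalized coverage over one chromosome's bins."""
    return float(cov.chrom_normalized(chrom).mean())


def sequencing_summary(
    read_lengths_bp: Sequence[int] | np.ndarray, reference_length_bp: int
) -> SequencingSummary:
    """Read count, summed read length, and genome-wide average depth."""
    if reference_length_bp <= 0:
        raise ValueError(f"reference length must be positive, got {reference_length_bp}")
    lengths = np.asarray(read_lengths_bp, dtype=np.int64)
    total = int(lengths.sum()) if lengths.size else 0
    return SequencingSummary(
        n_reads=int(lengths.size),
        sum_length_bp=total,
        average_coverage=total / reference_length_bp,
    )


# -- input readers ---------------------------------------------------------


def read_placements_bed(path: str | Path) -> pd.DataFrame:
    """BED3-like delimited text -> placements DataFrame (chrom, start_bp, end_bp)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start_bp", "end_bp"],
        usecols=[0, 1, 2],
        dtype={0: str, 1: np.int64, 2: np.int64},
    )
    return df


def read_placements_sam(path: str | Path, min_mapq: int = 20) -> pd.DataFrame:
    """Mapped records from SAM text -> placements, MAPQ-filtered.

    Unmapped reads and records below ``min_mapq`` are dropped; POS (1-based)
    becomes a 0-based start.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            end = rec.reference_end
            if end is None:
                end = rec.reference_start + (rec.query_length or 1)
            rows.append((rec.reference_name, rec.reference_start, end))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp"])


def write_bin_table(cov: BinCoverage, path: str | Path) -> None:
    """TSV with columns chrom, bin_start_mb, bin_end_mb, raw_count, normalized."""
    df = cov.to_frame().rename(columns={"start_mb": "bin_start_mb", "end_mb": "bin_end_mb"})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bin_table(path: str | Path, ref: HybridReference) -> BinCoverage:
    df = pd.read_csv(path, sep="\t")
    if len(df) != ref.n_bins:
        raise ValueError(
            f"bin table has {len(df)} rows but reference has {ref.n_bins} bins"
        )
    raw = df["raw_count"].to_numpy(np.int64)
    normalized = None
    if "normalized" in df and not df["normalized"].isna().all():
        normalized = df["normalized"].to_numpy(float)
    return BinCoverage(ref=ref, raw=raw, normalized=normalized)
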