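"""Present/absent classification of bins and merging into maximal segments.

Normalized coverage separates cleanly into present (near 1.0) and absent
(near the cross-mapping background) bins, so segmentation is a deterministic
two-threshold classifier followed by a short-run smoothing pass and a merge
into maximal equal-state runs.  Coordinates are internal 0-based half-open
Mb; printed labels are 1-based inclusive ("218-253" for [217, 253)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .coverage import BinCoverage
from .reference import HybridReference

PRESENT = 1
ABSENT = 0
_UNRESOLVED = -1


@dataclass(frozen=True)
class SegmentationParams:
    """Classifier thresholds (normalized-coverage units) and smoothing span.

    Bins at or below ``tau_absent`` are absent, at or above ``tau_present``
    present; the gap between them is resolved from flanking bins.  ``min_run``
    is the shortest run of bins the smoother will keep.
    """

    tau_absent: float = 0.15
    tau_present: float = 0.4
    min_run: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.tau_absent < self.tau_present):
            raise ValueError(
                f"need 0 <= tau_absent < tau_present, got {self.tau_absent}, {self.tau_present}"
            )
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass(frozen=True)
class SegmentCall:
    """Maximal equal-state run on one chromosome, 0-based half-open Mb."""

    chrom: str
    start_mb: float
    end_mb: float
    state: str  # 'present' | 'absent'
    mean_normalized: float

    @property
    def length_mb(self) -> float:
        return self.end_mb - self.start_mb

    @property
    def is_present(self) -> bool:
        return self.state == "present"


def label_1based(seg: SegmentCall) -> str:
    """1-based inclusive Mb label, e.g. [217, 253) -> '218-253'."""

    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else f"{x:g}"

    return f"{fmt(seg.start_mb + 1)}–{fmt(seg.end_mb)}"


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (state, start, end) with end exclusive."""
    out = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j + 1 < n and states[j + 1] == states[i]:
            j += 1
        out.append((int(states[i]), i, j + 1))
        i = j + 1
    return out


def classify_chromosome(values: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Two-threshold bin classification with flank-based resolution.

    Bins strictly between the thresholds take the state of the nearer
    resolved bin on the same chromosome; at equal distance, the flank whose
    run mean is closer in normalized value wins (left on a residual tie).  An
    intermediate run touching a chromosome end takes its single flank's
    state.  A chromosome with no resolved bin at all falls back to the
    threshold midpoint.
    """
    n = len(values)
    states = np.full(n, _UNRESOLVED, dtype=np.int8)
    states[values <= params.tau_absent] = ABSENT
    states[values >= params.tau_present] = PRESENT

    if not (states != _UNRESOLVED).any():
        mid = (params.tau_absent + params.tau_present) / 2
        return np.where(values >= mid, PRESENT, ABSENT).astype(np.int8)

    resolved_runs = [(s, a, b) for s, a, b in _runs(states) if s != _UNRESOLVED]

    def run_of(index: int) -> tuple[int, int, int]:
        for s, a, b in resolved_runs:
            if a <= index < b:
                return s, a, b
        raise AssertionError("index not in a resolved run")

    resolved_idx = np.flatnonzero(states != _UNRESOLVED)
    for i in np.flatnonzero(states == _UNRESOLVED):
        left_candidates = resolved_idx[resolved_idx < i]
        right_candidates = resolved_idx[resolved_idx > i]
        left = int(left_candidates[-1]) if left_candidates.size else None
        right = int(right_candidates[0]) if right_candidates.size else None
        if left is None:
            states[i] = states[right]
        elif right is None:
            states[i] = states[left]
        else:
            dl, dr = i - left, right - i
            if dl < dr:
                states[i] = states[left]
            elif dr < dl:
                states[i] = states[right]
            else:
                _, la, lb = run_of(left)
                _, ra, rb = run_of(right)
                dev_left = abs(values[i] - values[la:lb].mean())
                dev_right = abs(values[i] - values[ra:rb].mean())
                states[i] = states[left] if dev_left <= dev_right else states[right]
    return states


def classify_bins(cov: BinCoverage, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Per-bin present/absent states over the whole reference."""
    if cov.normalized is None:
        raise ValueError("coverage must be normalized before classification")
    states = np.empty(cov.ref.n_bins, dtype=np.int8)
    for spec in cov.ref.chromosomes:
        sl = cov.ref.chrom_slice(spec.name)
        states[sl] = classify_chromosome(cov.normalized[sl], params)
    return states


def smooth(states: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Flip interior runs shorter than ``min_run`` whose flanks agree.

    One (leftmost, shortest-first) run is flipped per iteration until a
    fixpoint; runs touching a chromosome end are never flipped, so terminal
    blocks survive.  Idempotent.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    out = states.copy()
    while True:
        runs = _runs(out)
        candidates = [
            (b - a, a, b, runs[k - 1][0])
            for k, (s, a, b) in enumerate(runs)
            if 0 < k < len(runs) - 1
            and (b - a) < min_run
            and runs[k - 1][0] == runs[k + 1][0]
        ]
        if not candidates:
            return out
        _, a, b, flank_state = min(candidates)
        out[a:b] = flank_state


def segment_chromosome(
    cov: BinCoverage, chrom: str, params: SegmentationParams = SegmentationParams()
) -> list[SegmentCall]:
    """classify -> smooth -> merge into maximal SegmentCalls tiling ``chrom``."""
    sl = cov.ref.chrom_slice(chrom)
    values = cov.normalized[sl] if cov.normalized is not None else None
    if values is None:
        raise ValueError("coverage must be normalized before segmentation")
    states = smooth(classify_chromosome(values, params), params.min_run)
    bins = cov.ref.bins.iloc[sl.start : sl.stop]
    starts = bins["start_mb"].to_numpy(float)
    ends = bins["end_mb"].to_numpy(float)
    segs = []
    for state, a, b in _runs(states):
        segs.append(
            SegmentCall(
                chrom=chrom,
                start_mb=float(starts[a]),
                end_mb=float(ends[b - 1]),
                state="present" if state == PRESENT else "absent",
                mean_normalized=float(values[a:b].mean()),
            )
        )
    return segs


def segment_all(
    cov: BinCoverage, params: SegmentationParams = SegmentationParams()
) -> dict[str, list[SegmentCall]]:
    return {
        spec.name: segment_chromosome(cov, spec.name, params)
        for spec in cov.ref.chromosomes
    }


# -- I/O -------------------------------------------------------------------


def segments_to_frame(segments: dict[str, list[SegmentCall]]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.chrom,
            "start_mb": s.start_mb,
            "end_mb": s.end_mb,
            "state": s.state,
            "length_mb": s.length_mb,
            "mean_normalized": s.mean_normalized,
            "label": label_1based(s),
        }
        for segs in segments.values()
        for s in segs
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_mb", "end_mb", "state", "length_mb", "mean_normalized", "label"],
    )


def write_segments_bed(segments: dict[str, list[SegmentCall]], path: str | Path) -> None:
    """BED: chrom, start_bp, end_bp, state, mean_normalized (0-based bp)."""
    with open(path, "w") as fh:
        for segs in segments.values():
            for s in segs:
                fh.write(
                    f"{s.chrom}\t{int(s.start_mb * 1_000_000)}\t{int(s.end_mb * 1_000_000)}"
                    f"\t{s.state}\t{s.mean_normalized:.4f}\n"
                )


def write_segments_tsv(segments: dict[str, list[SegmentCall]], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_segments_tsv(path: str | Path) -> dict[str, list[SegmentCall]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[SegmentCall]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), []).append(
            SegmentCall(
                chrom=str(row.chrom),
                start_mb=float(row.start_mb),
                end_mb=float(row.end_mb),
                state=str(row.state),
                mean_normalized=float(row.mean_normalized),
            )
        )
    return out
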