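"""Structural interpretation of present/absent segments.

Turns segment calls into arm-level statuses, compensating centric-fusion
(Robertsonian translocation) nomenclature such as "T6BS.6HL", deletion calls
in the wheat background, introgression summaries, and the complementary-line
inference of a pericentric inversion: when two lines carry the two arms of
the same barley chromosome and their present-sets interlock in a 2x2
crossover pattern around the centromere, the two interior blocks must have
swapped arms before the centric fission.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .reference import BARLEY, WHEAT, HybridReference
from .segmentation import SegmentCall

_ARM_RE = re.compile(r"^T(?P<a>[0-9][A-Z]+?)(?P<a_arm>[SL])\.(?P<b>[0-9][A-Z]+?)(?P<b_arm>[SL])$")


@dataclass(frozen=True)
class ArmStatus:
    chrom: str
    arm: str  # 'S' | 'L'
    fraction_present: float
    status: str  # 'present' | 'absent' | 'partial'


@dataclass(frozen=True)
class TranslocationCall:
    """Compensating centric fusion, named short arm first (e.g. T4BS.4HL)."""

    name: str
    wheat_arm: str  # e.g. '6BS'
    barley_arm: str  # e.g. '6HL'
    homoeologous_group: int


@dataclass(frozen=True)
class DeletionCall:
    chrom: str
    start_mb: float
    end_mb: float
    kind: str  # 'interstitial' | 'terminal'

    @property
    def length_mb(self) -> float:
        return self.end_mb - self.start_mb


@dataclass(frozen=True)
class InversionCall:
    """Pericentric inversion inferred from two complementary carriers.

    The inverted interval is [start_mb, end_mb); block_a and block_b are the
    two sub-blocks whose arm assignment is swapped relative to the reference.
    """

    chrom: str
    start_mb: float
    end_mb: float
    block_a: tuple[float, float]
    block_b: tuple[float, float]
    spans_centromere: bool

    @property
    def length_mb(self) -> float:
        return self.end_mb - self.start_mb


@dataclass(frozen=True)
class IntrogressionSummary:
    chrom: str
    total_present_mb: float
    percent_of_chromosome: int
    segments: tuple[SegmentCall, ...] = field(default=())


def _check_tiling(segments: Sequence[SegmentCall], ref: HybridReference, chrom: str) -> None:
    spec = ref.spec(chrom)
    pos = 0.0
    for seg in segments:
        if seg.chrom != chrom:
            raise ValueError(f"segment on {seg.chrom} passed for chromosome {chrom}")
        if seg.start_mb != pos:
            raise ValueError(
                f"{chrom}: segments do not tile the chromosome (gap/overlap at {pos} Mb)"
            )
        pos = seg.end_mb
    if pos != spec.length_mb:
        raise ValueError(
            f"{chrom}: segments end at {pos} Mb, chromosome length is {spec.length_mb} Mb"
        )


def _status_from_fraction(fraction: float) -> str:
    if fraction >= 0.9:
        return "present"
    if fraction <= 0.1:
        return "absent"
    return "partial"


def arm_status(
    segments: Sequence[SegmentCall], ref: HybridReference, chrom: str
) -> tuple[ArmStatus, ArmStatus]:
    """Fraction of each arm covered by present segments, with a 0.9/0.1 call."""
    _check_tiling(segments, ref, chrom)
    spec = ref.spec(chrom)
    out = []
    for arm in ("S", "L"):
        if arm == "S":
            a0, a1 = 0.0, float(spec.centromere_mb)
        else:
            a0, a1 = float(spec.centromere_mb), float(spec.length_mb)
        present = sum(
            max(0.0, min(seg.end_mb, a1) - max(seg.start_mb, a0))
            for seg in segments
            if seg.is_present
        )
        frac = present / (a1 - a0)
        out.append(ArmStatus(chrom=chrom, arm=arm, fraction_present=frac,
                             status=_status_from_fraction(frac)))
    return out[0], out[1]


def parse_translocation_name(name: str) -> tuple[str, str]:
    """'T6BS.6HL' -> ('6BS', '6HL'); inverse of the caller's naming rule."""
    m = _ARM_RE.match(name)
    if not m:
        raise ValueError(f"not a centric-fusion name: {name!r}")
    return (m["a"] + m["a_arm"], m["b"] + m["b_arm"])


def call_centric_fusions(
    statuses: Sequence[ArmStatus],
    ref: HybridReference,
    barley_present_min: float = 0.75,
    barley_absent_max: float = 0.25,
) -> tuple[list[TranslocationCall], list[str]]:
    """Detect compensating wheat-barley centric fusions from arm statuses.

    A fusion is called when one wheat chromosome has exactly one absent arm
    with its partner arm present, and the same-group barley chromosome shows
    the complementary pattern: the arm replacing the lost wheat arm present
    (fraction >= ``barley_present_min``, relaxed below the 0.9 'present'
    cutoff because a pericentric inversion can shift blocks across the
    centromere) and the other barley arm near-absent.  Returns (calls,
    diagnostics); a wheat chromosome with both arms absent is reported as a
    whole loss in the diagnostics, never as a fusion.
    """
    by_chrom: dict[str, dict[str, ArmStatus]] = {}
    for st in statuses:
        by_chrom.setdefault(st.chrom, {})[st.arm] = st

    calls: list[TranslocationCall] = []
    diagnostics: list[str] = []
    for chrom, arms in sorted(by_chrom.items()):
        spec = ref.spec(chrom)
        if spec.subgenome != WHEAT or set(arms) != {"S", "L"}:
            continue
        s_st, l_st = arms["S"], arms["L"]
        if s_st.status == "absent" and l_st.status == "absent":
            diagnostics.append(f"{chrom}: both arms absent -> whole_loss, not a fusion")
            continue
        lost = [a for a in ("S", "L") if arms[a].status == "absent"]
        kept = [a for a in ("S", "L") if arms[a].status == "present"]
        if len(lost) != 1 or len(kept) != 1:
            continue
        lost_arm = lost[0]
        barley = [
            s for s in ref.chromosomes
            if s.subgenome == BARLEY and s.group == spec.group and s.name in by_chrom
        ]
        for bspec in barley:
            barms = by_chrom[bspec.name]
            if set(barms) != {"S", "L"}:
                continue
            other_arm = "L" if lost_arm == "S" else "S"
            if (
                barms[lost_arm].fraction_present >= barley_present_min
                and barms[other_arm].fraction_present <= barley_absent_max
            ):
                wheat_arm = f"{chrom}{kept[0]}"
                barley_arm = f"{bspec.name}{lost_arm}"
                first, second = (
                    (wheat_arm, barley_arm) if kept[0] == "S" else (barley_arm, wheat_arm)
                )
                calls.append(
                    TranslocationCall(
                        name=f"T{first}.{second}",
                        wheat_arm=wheat_arm,
                        barley_arm=barley_arm,
                        homoeologous_group=spec.group,
                    )
                )
    return calls, diagnostics


def call_deletions(
    segments: Sequence[SegmentCall],
    ref: HybridReference,
    chrom: str,
    min_length_mb: float = 5.0,
    exclude: Sequence[tuple[float, float]] = (),
) -> list[DeletionCall]:
    """Absent segments on a majority-present wheat chromosome become deletions.

    ``exclude`` intervals (e.g. an arm lost to a called centric fusion) mask
    absent segments that lie mostly (>= 80%) within them.  Chromosomes that
    are not majority-present -- translocation-lost arms dominate them -- and
    barley chromosomes yield no deletion calls.
    """
    spec = ref.spec(chrom)
    if spec.subgenome != WHEAT:
        return []
    _check_tiling(segments, ref, chrom)
    present_mb = sum(s.length_mb for s in segments if s.is_present)
    if present_mb <= spec.length_mb / 2:
        return []
    calls = []
    for seg in segments:
        if seg.is_present or seg.length_mb < min_length_mb:
            continue
        masked = sum(
            max(0.0, min(seg.end_mb, e) - max(seg.start_mb, s)) for s, e in exclude
        )
        if seg.length_mb > 0 and masked / seg.length_mb >= 0.8:
            continue
        kind = (
            "terminal"
            if seg.start_mb == 0 or seg.end_mb == spec.length_mb
            else "interstitial"
        )
        calls.append(DeletionCall(chrom=chrom, start_mb=seg.start_mb, end_mb=seg.end_mb, kind=kind))
    return calls


def _present_mask(segments: Sequence[SegmentCall], ref: HybridReference, chrom: str) -> np.ndarray:
    sl = ref.chrom_slice(chrom)
    bins = ref.bins.iloc[sl.start : sl.stop]
    centers = (bins["start_mb"].to_numpy(float) + bins["end_mb"].to_numpy(float)) / 2
    mask = np.zeros(len(centers), dtype=bool)
    for seg in segments:
        if seg.is_present:
            mask |= (centers >= seg.start_mb) & (centers < seg.end_mb)
    return mask


def _present_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def infer_pericentric_inversion(
    segments_a: Sequence[SegmentCall],
    segments_b: Sequence[SegmentCall],
    ref: HybridReference,
    chrom: str,
    max_overlap_fraction: float = 0.05,
    boundary_tolerance_bins: int = 1,
) -> tuple[Optional[InversionCall], str]:
    """Infer a pericentric inversion from two complementary arm carriers.

    The two inputs are segment calls for the same chromosome in two lines
    that together carry both of its arms.  Their present-sets must be
    (near-)disjoint and jointly cover >= 95% of the bins, else the inputs are
    rejected.  A single terminal run in each line is a clean centric fission
    (no call).  The crossover pattern -- one carrier present on
    [0,p) u [q,r), the other on [p,q) u [r,L) -- yields an inversion call on
    [p,r) with blocks [p,q) and [q,r).  Returns (call or None, diagnostic).
    """
    _check_tiling(segments_a, ref, chrom)
    _check_tiling(segments_b, ref, chrom)
    mask_a = _present_mask(segments_a, ref, chrom)
    mask_b = _present_mask(segments_b, ref, chrom)
    n = len(mask_a)
    overlap = int((mask_a & mask_b).sum())
    gap = int((~mask_a & ~mask_b).sum())
    if overlap > max_overlap_fraction * n:
        raise ValueError(
            f"{chrom}: carriers are not complementary ({overlap}/{n} bins present in both)"
        )
    if gap > 0.05 * n:
        raise ValueError(
            f"{chrom}: carriers leave {gap}/{n} bins uncovered; not complementary arm carriers"
        )

    # orient so 's' is the carrier holding the chromosome start
    if mask_a[0]:
        mask_s, mask_l = mask_a, mask_b
    elif mask_b[0]:
        mask_s, mask_l = mask_b, mask_a
    else:
        return None, "neither carrier is present at the chromosome start"

    runs_s = _present_runs(mask_s)
    runs_l = _present_runs(mask_l)
    if len(runs_s) == 1 and len(runs_l) == 1:
        return None, "single boundary: clean centric fission, no inversion"
    if len(runs_s) > 2 or len(runs_l) > 2:
        return None, (
            f"pattern too fragmented for a single inversion "
            f"({len(runs_s)} and {len(runs_l)} present runs)"
        )
    if len(runs_s) != 2 or len(runs_l) != 2:
        return None, "present runs do not form the 2x2 crossover pattern"

    tol = boundary_tolerance_bins
    (s0a, s0b), (s1a, s1b) = runs_s
    (l0a, l0b), (l1a, l1b) = runs_l
    # expected: s runs [0,p) and [q,r); l runs [p,q) and [r, n)
    p, q, r = s0b, s1a, s1b
    if s0a != 0 or l1b != n:
        return None, "terminal runs not anchored at chromosome ends"
    if abs(l0a - p) > tol or abs(l0b - q) > tol or abs(l1a - r) > tol:
        return None, "run boundaries of the two carriers do not interlock"

    sl = ref.chrom_slice(chrom)
    bins = ref.bins.iloc[sl.start : sl.stop]
    starts = bins["start_mb"].to_numpy(float)
    ends = bins["end_mb"].to_numpy(float)
    p_mb, q_mb, r_mb = starts[p], starts[q], ends[r - 1]
    cen = ref.spec(chrom).centromere_mb
    return (
        InversionCall(
            chrom=chrom,
            start_mb=float(p_mb),
            end_mb=float(r_mb),
            block_a=(float(p_mb), float(q_mb)),
            block_b=(float(q_mb), float(r_mb)),
            spans_centromere=bool(p_mb <= cen < r_mb),
        ),
        "crossover pattern consistent with a pericentric inversion",
    )


def summarize_introgression(
    segments: Sequence[SegmentCall], ref: HybridReference, chrom: str
) -> IntrogressionSummary:
    """Total present chromatin on a chromosome and its rounded percent share."""
    _check_tiling(segments, ref, chrom)
    spec = ref.spec(chrom)
    total = sum(s.length_mb for s in segments if s.is_present)
    return IntrogressionSummary(
        chrom=chrom,
        total_present_mb=total,
        percent_of_chromosome=int(round(100 * total / spec.length_mb)),
        segments=tuple(s for s in segments if s.is_present),
    )


def carrier_frequency(n_carriers: int, n_screened: int) -> float:
    """Percent of screened plants carrying an event, to one decimal."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not (0 <= n_carriers <= n_screened):
        raise ValueError(f"n_carriers {n_carriers} outside [0, {n_screened}]")
    return round(100.0 * n_carriers / n_screened, 1)
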