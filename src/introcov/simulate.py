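"""Karyotypes from structural events, and GBS-like per-bin count simulation.

A karyotype is a per-bin copy-number function over the hybrid reference:
euploid wheat background bins are disomic (copy number 2), barley bins start
absent (0), and structural events -- centric fusions modelled as arm
replacements, deletions, whole-chromosome gains/losses, pericentric
inversions -- rewrite it.  The simulator then draws per-bin read counts with
a gamma-Poisson (negative-binomial-like) model whose background cross-mapping
rates emulate the low read densities a wheat line leaves on absent barley
bins and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .reference import BARLEY, WHEAT, ChromosomeSpec, HybridReference

EVENT_KINDS = (
    "arm_replacement",
    "terminal_loss",
    "interstitial_deletion",
    "pericentric_inversion",
    "whole_addition",
    "whole_loss",
)


@dataclass(frozen=True)
class StructuralEvent:
    """One structural change applied to the euploid hybrid karyotype.

    ``arm_replacement`` is the centric fusion: the named wheat arm is lost and
    the homoeologous barley arm (same group, same arm label) takes its place.
    Interval events carry [start_mb, end_mb) in reference coordinates of
    ``chrom``; ``pericentric_inversion`` intervals must span the centromere.
    """

    kind: str
    chrom: Optional[str] = None
    start_mb: Optional[int] = None
    end_mb: Optional[int] = None
    wheat_chrom: Optional[str] = None
    barley_chrom: Optional[str] = None
    arm: Optional[str] = None
    copy_number_change: int = 1

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if self.kind == "arm_replacement":
            if not (self.wheat_chrom and self.barley_chrom and self.arm in ("S", "L")):
                raise ValueError("arm_replacement needs wheat_chrom, barley_chrom and arm S/L")
        elif self.kind in ("whole_addition", "whole_loss"):
            if not self.chrom:
                raise ValueError(f"{self.kind} needs chrom")
        else:
            if not (self.chrom and self.start_mb is not None and self.end_mb is not None):
                raise ValueError(f"{self.kind} needs chrom, start_mb and end_mb")
            if not (0 <= self.start_mb < self.end_mb):
                raise ValueError(f"{self.kind}: bad interval [{self.start_mb}, {self.end_mb})")


@dataclass
class Karyotype:
    """Per-bin copy number (0/1/2) over the hybrid reference."""

    ref: HybridReference
    copy_number: np.ndarray  # int8, length ref.n_bins

    def chrom_copy_number(self, chrom: str) -> np.ndarray:
        return self.copy_number[self.ref.chrom_slice(chrom)]

    def truth_intervals(self) -> pd.DataFrame:
        """Maximal constant-copy-number runs that differ from the euploid default."""
        rows = []
        for spec in self.ref.chromosomes:
            default = 2 if spec.subgenome == WHEAT else 0
            cn = self.chrom_copy_number(spec.name)
            bins = self.ref.bins[self.ref.bins["chrom"] == spec.name]
            starts = bins["start_mb"].to_numpy()
            ends = bins["end_mb"].to_numpy()
            i = 0
            while i < len(cn):
                j = i
                while j + 1 < len(cn) and cn[j + 1] == cn[i]:
                    j += 1
                if cn[i] != default:
                    rows.append(
                        {
                            "chrom": spec.name,
                            "start_mb": int(starts[i]),
                            "end_mb": int(ends[j]),
                            "copy_number": int(cn[i]),
                        }
                    )
                i = j + 1
        return pd.DataFrame(rows, columns=["chrom", "start_mb", "end_mb", "copy_number"])


@dataclass(frozen=True)
class SimParams:
    """Noise model for low-pass GBS coverage.

    depth_per_bin
        Expected read count on a full-length disomic present bin.
    mappability_dispersion
        Variance of the unit-mean gamma mappability factor multiplying each
        bin's rate; 0 disables the gamma layer (pure Poisson).
    cross_map_to_barley / cross_map_to_wheat
        Fraction of ``depth_per_bin`` leaking onto absent bins of each
        subgenome, emulating cross-mapping between the homoeologous genomes.
    """

    depth_per_bin: float = 30.0
    mappability_dispersion: float = 0.005
    cross_map_to_barley: float = 0.011
    cross_map_to_wheat: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_bin < 0:
            raise ValueError("depth_per_bin must be >= 0")
        if self.mappability_dispersion < 0:
            raise ValueError("mappability_dispersion must be >= 0")
        for name in ("cross_map_to_barley", "cross_map_to_wheat"):
            rate = getattr(self, name)
            if not (0 <= rate < 1):
                raise ValueError(f"{name} must be in [0, 1), got {rate}")


class _ChromState:
    """Mutable per-chromosome geometry while events are applied.

    ``order[pos]`` is the reference bin index currently sitting at positional
    bin ``pos``; a pericentric inversion reverses a slice of ``order`` and
    reflects the centromere point, so later arm operations see the rearranged
    arm composition while copy number stays indexed by reference bins.
    """

    def __init__(self, ref: HybridReference, spec: ChromosomeSpec):
        self.spec = spec
        self.n = ref.n_chrom_bins(spec.name)
        self.bin = ref.bin_size_mb
        self.order = np.arange(self.n)
        self.centromere_mb = float(spec.centromere_mb)
        self.length_mb = spec.length_mb

    def invert(self, start_mb: int, end_mb: int) -> None:
        if not (start_mb < self.centromere_mb < end_mb):
            raise ValueError(
                f"{self.spec.name}: pericentric inversion [{start_mb}, {end_mb}) does not "
                f"span the centromere at {self.centromere_mb} Mb"
            )
        b0, b1 = start_mb // self.bin, -(-end_mb // self.bin)
        self.order[b0:b1] = self.order[b0:b1][::-1]
        self.centromere_mb = start_mb + end_mb - self.centromere_mb

    def arm_ref_bins(self, arm: str) -> np.ndarray:
        """Reference bin indices currently composing one arm."""
        cen_bin = self.centromere_mb / self.bin
        positions = np.arange(self.n)
        starts = positions * self.bin
        ends = np.minimum(starts + self.bin, self.length_mb)
        share_s = np.clip(self.centromere_mb - starts, 0, None)
        share_l = np.clip(ends - self.centromere_mb, 0, None)
        is_s = share_s >= share_l
        del cen_bin
        mask = is_s if arm == "S" else ~is_s
        return self.order[mask]


def apply_events(ref: HybridReference, events: Sequence[StructuralEvent]) -> Karyotype:
    """Build the per-bin copy-number function for a list of structural events.

    Events are applied in order.  Interval coordinates are interpreted on the
    reference; only arm-level operations (arm_replacement) see the effect of
    earlier pericentric inversions, which change which reference blocks travel
    with each arm.
    """
    cn = np.empty(ref.n_bins, dtype=np.int8)
    for spec in ref.chromosomes:
        cn[ref.chrom_slice(spec.name)] = 2 if spec.subgenome == WHEAT else 0

    states = {spec.name: _ChromState(ref, spec) for spec in ref.chromosomes}

    def interval_bins(chrom: str, start_mb: int, end_mb: int) -> slice:
        spec = ref.spec(chrom)
        if end_mb > spec.length_mb:
            raise ValueError(
                f"{chrom}: interval [{start_mb}, {end_mb}) exceeds length {spec.length_mb} Mb"
            )
        sl = ref.chrom_slice(chrom)
        b0 = start_mb // ref.bin_size_mb
        b1 = -(-end_mb // ref.bin_size_mb)
        return slice(sl.start + b0, sl.start + b1)

    for ev in events:
        if ev.kind == "whole_addition":
            sl = ref.chrom_slice(ev.chrom)
            cn[sl] = np.clip(cn[sl] + ev.copy_number_change, 0, 2)
        elif ev.kind == "whole_loss":
            cn[ref.chrom_slice(ev.chrom)] = 0
        elif ev.kind == "terminal_loss":
            spec = ref.spec(ev.chrom)
            if ev.start_mb != 0 and ev.end_mb != spec.length_mb:
                raise ValueError(
                    f"{ev.chrom}: terminal_loss [{ev.start_mb}, {ev.end_mb}) touches "
                    f"neither end of the chromosome"
                )
            cn[interval_bins(ev.chrom, ev.start_mb, ev.end_mb)] = 0
        elif ev.kind == "interstitial_deletion":
            cn[interval_bins(ev.chrom, ev.start_mb, ev.end_mb)] = 0
        elif ev.kind == "pericentric_inversion":
            spec = ref.spec(ev.chrom)
            if ev.end_mb > spec.length_mb:
                raise ValueError(
                    f"{ev.chrom}: inversion [{ev.start_mb}, {ev.end_mb}) exceeds "
                    f"length {spec.length_mb} Mb"
                )
            states[ev.chrom].invert(ev.start_mb, ev.end_mb)
        elif ev.kind == "arm_replacement":
            wspec = ref.spec(ev.wheat_chrom)
            bspec = ref.spec(ev.barley_chrom)
            if wspec.subgenome != WHEAT or bspec.subgenome != BARLEY:
                raise ValueError(
                    f"arm_replacement needs a wheat and a barley chromosome, got "
                    f"{wspec.name} ({wspec.subgenome}) and {bspec.name} ({bspec.subgenome})"
                )
            if wspec.group != bspec.group:
                raise ValueError(
                    f"arm_replacement across homoeologous groups: {wspec.name} is group "
                    f"{wspec.group}, {bspec.name} is group {bspec.group}"
                )
            wheat_arm = states[wspec.name].arm_ref_bins(ev.arm)
            barley_arm = states[bspec.name].arm_ref_bins(ev.arm)
            cn[ref.chrom_slice(wspec.name).start + wheat_arm] = 0
            cn[ref.chrom_slice(bspec.name).start + barley_arm] = 2
    return Karyotype(ref=ref, copy_number=cn)


# -- count simulation ------------------------------------------------------


def _bin_rates(karyotype: Karyotype, params: SimParams) -> np.ndarray:
    ref = karyotype.ref
    cross = np.where(
        (ref.bins["subgenome"] == BARLEY).to_numpy(),
        params.cross_map_to_barley,
        params.cross_map_to_wheat,
    )
    cn = karyotype.copy_number.astype(float)
    return params.depth_per_bin * cn / 2.0 + cross * params.depth_per_bin


def simulate_bin_counts(karyotype: Karyotype, params: SimParams) -> np.ndarray:
    """Draw per-bin raw read counts (reference order); deterministic in seed.

    count_b ~ Poisson(lambda_b * m_b * len_b) with lambda_b the dosage rate
    plus cross-mapping background, m_b a unit-mean gamma mappability factor,
    len_b the bin-length fraction.
    """
    ref = karyotype.ref
    rng = np.random.default_rng(params.seed)
    lam = _bin_rates(karyotype, params)
    if params.mappability_dispersion > 0:
        shape = 1.0 / params.mappability_dispersion
        m = rng.gamma(shape, 1.0 / shape, size=ref.n_bins)
    else:
        m = np.ones(ref.n_bins)
    return rng.poisson(lam * m * ref.bin_fraction).astype(np.int64)


def simulate_read_positions(
    karyotype: Karyotype, params: SimParams, read_length_bp: int = 150
) -> pd.DataFrame:
    """Emit individual read placements whose per-bin counts match
    :func:`simulate_bin_counts` under the same seed exactly.

    Reads start uniformly within their bin (so counting by start position
    recovers the simulated table bin-for-bin) and are clipped to chromosome
    ends.  Returns a DataFrame with columns chrom, start_bp, end_bp.
    """
    ref = karyotype.ref
    counts = simulate_bin_counts(karyotype, params)
    # independent stream for positions so the count draw stays bit-identical
    pos_rng = np.random.default_rng((params.seed, 0x9E3779B9))
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    bins = ref.bins
    for (chrom, s_mb, e_mb), k in zip(
        zip(bins["chrom"], bins["start_mb"], bins["end_mb"]), counts
    ):
        if k == 0:
            continue
        lo = int(s_mb * 1_000_000)
        hi = int(e_mb * 1_000_000)
        chroms.extend([chrom] * int(k))
        starts.append(pos_rng.integers(lo, hi, size=int(k)))
    if not starts:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp"])
    start_bp = np.concatenate(starts)
    df = pd.DataFrame({"chrom": chroms, "start_bp": start_bp})
    lengths = df["chrom"].map({s.name: s.length_mb * 1_000_000 for s in ref.chromosomes})
    df["end_bp"] = np.minimum(df["start_bp"] + read_length_bp, lengths).astype(np.int64)
    return df


# -- packaged translocation-line scenarios ---------------------------------


@dataclass(frozen=True)
class Scenario:
    """A named line: its structural events plus any chromosome-spec overrides."""

    name: str
    events: tuple[StructuralEvent, ...]
    spec_overrides: tuple[ChromosomeSpec, ...] = ()
    description: str = ""


def _scenario_table() -> dict[str, Scenario]:
    # the 6H pericentric inversion (a/b block swap around the 253 Mb
    # centromere) precedes both group-6 centric fissions, so each fusion
    # carries one small block from the "wrong" arm
    inv_6h = StructuralEvent(
        kind="pericentric_inversion", chrom="6H", start_mb=217, end_mb=281
    )
    return {
        "T6HS.6BL": Scenario(
            name="T6HS.6BL",
            events=(
                inv_6h,
                StructuralEvent(
                    kind="arm_replacement", wheat_chrom="6B", barley_chrom="6H", arm="S"
                ),
            ),
            description=(
                "Barley 6HS replaces wheat 6BS: 6H carries [0,217) and [253,281), "
                "6B keeps only its long arm [345,731)."
            ),
        ),
        "T6BS.6HL": Scenario(
            name="T6BS.6HL",
            events=(
                inv_6h,
                StructuralEvent(
                    kind="arm_replacement", wheat_chrom="6B", barley_chrom="6H", arm="L"
                ),
            ),
            description=(
                "Barley 6HL replaces wheat 6BL: 6H carries [217,253) and [281,560), "
                "6B keeps only its short arm [0,345)."
            ),
        ),
        "T4BS.4HL": Scenario(
            name="T4BS.4HL",
            events=(
                StructuralEvent(
                    kind="arm_replacement", wheat_chrom="4B", barley_chrom="4H", arm="L"
                ),
                StructuralEvent(
                    kind="interstitial_deletion", chrom="2D", start_mb=573, end_mb=622
                ),
                StructuralEvent(kind="terminal_loss", chrom="3B", start_mb=724, end_mb=851),
            ),
            description=(
                "Barley 4HL (last 335 Mb of 4H) replaces wheat 4BL (last 356 Mb of 4B); "
                "background deletions of 49 Mb on 2D and 127 Mb (terminal) on 3B."
            ),
        ),
    }


def translocation_scenarios() -> dict[str, Scenario]:
    """The three packaged wheat-barley translocation-line karyotypes."""
    return _scenario_table()


def get_scenario(name: str) -> Scenario:
    table = _scenario_table()
    if name not in table:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(table)}")
    return table[name]


# -- scenario / placement file I/O -----------------------------------------

_EVENT_FIELDS = (
    "kind", "chrom", "start_mb", "end_mb", "wheat_chrom", "barley_chrom", "arm",
    "copy_number_change",
)


def write_events(events: Iterable[StructuralEvent], path: str | Path) -> None:
    """Write events as key=value records, one event per line."""
    lines = []
    for ev in events:
        parts = []
        for f in _EVENT_FIELDS:
            v = getattr(ev, f)
            if v is not None and not (f == "copy_number_change" and v == 1):
                parts.append(f"{f}={v}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path: str | Path) -> list[StructuralEvent]:
    events = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kwargs: dict[str, object] = {}
        for token in line.split():
            if "=" not in token:
                raise ValueError(f"{path}:{lineno}: expected key=value tokens, got {token!r}")
            key, value = token.split("=", 1)
            if key not in _EVENT_FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown field {key!r}")
            if key in ("start_mb", "end_mb", "copy_number_change"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        events.append(StructuralEvent(**kwargs))
    return events


def write_truth_bed(karyotype: Karyotype, path: str | Path) -> None:
    """BED (0-based bp, half-open) of intervals deviating from the euploid default."""
    df = karyotype.truth_intervals()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start_mb * 1_000_000}\t{row.end_mb * 1_000_000}"
                f"\tcn{row.copy_number}\n"
            )


def write_placements_bed(placements: pd.DataFrame, path: str | Path) -> None:
    placements.to_csv(path, sep="\t", header=False, index=False,
                      columns=["chrom", "start_bp", "end_bp"])
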