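"""Coordinate geometry of the concatenated wheat x barley "in silico hybrid" reference.

Low-pass GBS reads from an introgression line are mapped against a single
reference built by concatenating the wheat and barley pseudomolecules, so that
reads partition between the two subgenomes at alignment.  This module models
that reference purely as coordinate geometry: chromosome names, subgenome
membership, lengths and centromere positions in megabases, and a regular bin
grid (1 Mb by default) on which read counts are aggregated.  No sequence is
ever handled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WHEAT = "wheat"
BARLEY = "barley"
_SUBGENOMES = (WHEAT, BARLEY)


@dataclass(frozen=True)
class ChromosomeSpec:
    """One parental chromosome: name, subgenome, size and centromere in Mb.

    ``group`` is the homoeologous group (1-7); wheat group-6 chromosomes and
    barley 6H compensate functionally, which is what makes centric fusions
    between them viable.
    """

    name: str
    subgenome: str
    length_mb: int
    centromere_mb: int
    group: int

    def __post_init__(self) -> None:
        if self.subgenome not in _SUBGENOMES:
            raise ValueError(
                f"{self.name}: subgenome must be one of {_SUBGENOMES}, got {self.subgenome!r}"
            )
        if self.length_mb < 1:
            raise ValueError(f"{self.name}: non-positive length ({self.length_mb} Mb)")
        if not (0 < self.centromere_mb < self.length_mb):
            raise ValueError(
                f"{self.name}: centromere at {self.centromere_mb} Mb must lie strictly "
                f"inside (0, {self.length_mb})"
            )
        if not (1 <= self.group <= 7):
            raise ValueError(f"{self.name}: homoeologous group must be 1-7, got {self.group}")


class HybridReference:
    """Ordered chromosomes (wheat first, then barley) with a shared bin grid.

    Bins are half-open intervals ``[i*bin, (i+1)*bin)`` in Mb tiling each
    chromosome; a trailing bin may be shorter than ``bin_size_mb``.  Bins get
    a stable global index (reference order), which the coverage, karyotype and
    segmentation layers all share.
    """

    def __init__(self, chromosomes: Sequence[ChromosomeSpec], bin_size_mb: int = 1):
        if bin_size_mb < 1:
            raise ValueError(f"bin_size_mb must be >= 1, got {bin_size_mb}")
        seen: set[str] = set()
        for spec in chromosomes:
            if spec.name in seen:
                raise ValueError(f"duplicate chromosome name: {spec.name!r}")
            seen.add(spec.name)
        self.chromosomes: tuple[ChromosomeSpec, ...] = tuple(chromosomes)
        self.bin_size_mb = int(bin_size_mb)
        self._by_name = {spec.name: spec for spec in self.chromosomes}

        offsets: dict[str, int] = {}
        rows = []
        offset = 0
        for spec in self.chromosomes:
            n = -(-spec.length_mb // self.bin_size_mb)  # ceil division
            offsets[spec.name] = offset
            starts = np.arange(n) * self.bin_size_mb
            ends = np.minimum(starts + self.bin_size_mb, spec.length_mb)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": spec.name,
                        "bin": np.arange(n),
                        "start_mb": starts,
                        "end_mb": ends,
                        "subgenome": spec.subgenome,
                    }
                )
            )
            offset += n
        self._offsets = offsets
        self.bins = pd.concat(rows, ignore_index=True)
        self.n_bins = offset
        # fraction of a full bin each bin covers (trailing bins < 1)
        self.bin_fraction = (
            (self.bins["end_mb"] - self.bins["start_mb"]).to_numpy(float) / self.bin_size_mb
        )

    # -- lookup ------------------------------------------------------------

    def spec(self, chrom: str) -> ChromosomeSpec:
        try:
            return self._by_name[chrom]
        except KeyError:
            raise KeyError(
                f"unknown chromosome {chrom!r}; reference has {sorted(self._by_name)}"
            ) from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_name

    def chrom_names(self) -> list[str]:
        return [s.name for s in self.chromosomes]

    def n_chrom_bins(self, chrom: str) -> int:
        spec = self.spec(chrom)
        return -(-spec.length_mb // self.bin_size_mb)

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global bin arrays covering one chromosome."""
        start = self._offsets[self.spec(chrom).name]
        return slice(start, start + self.n_chrom_bins(chrom))

    def global_index(self, chrom: str, bin_index: int) -> int:
        n = self.n_chrom_bins(chrom)
        if not (0 <= bin_index < n):
            raise IndexError(f"{chrom}: bin {bin_index} outside [0, {n})")
        return self._offsets[chrom] + bin_index

    def locate(self, chrom: str, position_mb: float) -> int:
        """Bin index containing a position (0-based half-open Mb)."""
        spec = self.spec(chrom)
        if not (0 <= position_mb < spec.length_mb):
            raise ValueError(
                f"position {position_mb} Mb outside chromosome {chrom} "
                f"(length {spec.length_mb} Mb)"
            )
        return int(position_mb // self.bin_size_mb)

    def arm_of(self, chrom: str, bin_index: int) -> str:
        """Arm label for a bin: 'S' before the centromere, 'L' at/after.

        The bin straddling the centromere goes to the arm holding the larger
        share of it; an exact tie goes to the short arm.
        """
        spec = self.spec(chrom)
        n = self.n_chrom_bins(chrom)
        if not (0 <= bin_index < n):
            raise IndexError(f"{chrom}: bin {bin_index} outside [0, {n})")
        start = bin_index * self.bin_size_mb
        end = min(start + self.bin_size_mb, spec.length_mb)
        if end <= spec.centromere_mb:
            return "S"
        if start >= spec.centromere_mb:
            return "L"
        return "S" if (spec.centromere_mb - start) >= (end - spec.centromere_mb) else "L"

    def arm_bins(self, chrom: str, arm: str) -> np.ndarray:
        """Local bin indices belonging to one arm."""
        if arm not in ("S", "L"):
            raise ValueError(f"arm must be 'S' or 'L', got {arm!r}")
        n = self.n_chrom_bins(chrom)
        labels = np.array([self.arm_of(chrom, i) for i in range(n)])
        return np.flatnonzero(labels == arm)

    def total_length_mb(self) -> int:
        return sum(s.length_mb for s in self.chromosomes)


def build_hybrid_reference(
    wheat_specs: Iterable[ChromosomeSpec],
    barley_specs: Iterable[ChromosomeSpec],
    bin_size_mb: int = 1,
) -> HybridReference:
    """Concatenate wheat then barley chromosomes into one hybrid reference."""
    wheat = list(wheat_specs)
    barley = list(barley_specs)
    for spec, expected in [(s, WHEAT) for s in wheat] + [(s, BARLEY) for s in barley]:
        if spec.subgenome != expected:
            raise ValueError(
                f"{spec.name}: listed as {expected} but subgenome is {spec.subgenome!r}"
            )
    return HybridReference(wheat + barley, bin_size_mb=bin_size_mb)


# -- built-in chromosome tables -------------------------------------------
#
# Lengths/centromeres in Mb at the scale of the CS wheat (RefSeq v2.1) and
# Morex barley assemblies.  The values that structural calls in the packaged
# scenarios depend on are pinned by printed region lengths (6B: 345+386=731,
# 6H: 217+36+28+279=560 with centromere at the 253 Mb block boundary,
# 4B: 673 with the last 356 Mb forming 4BL, 4H: 647 with the last 335 Mb
# forming 4HL, 3B: 851); the remainder are rounded assembly-scale defaults.

_WHEAT_TABLE = [
    # name, length_mb, centromere_mb, group
    ("1A", 599, 213, 1), ("1B", 700, 238, 1), ("1D", 499, 166, 1),
    ("2A", 788, 326, 2), ("2B", 813, 344, 2), ("2D", 665, 264, 2),
    ("3A", 754, 317, 3), ("3B", 851, 345, 3), ("3D", 619, 240, 3),
    ("4A", 754, 265, 4), ("4B", 673, 317, 4), ("4D", 510, 182, 4),
    ("5A", 713, 252, 5), ("5B", 715, 200, 5), ("5D", 566, 185, 5),
    ("6A", 623, 287, 6), ("6B", 731, 345, 6), ("6D", 495, 212, 6),
    ("7A", 744, 360, 7), ("7B", 764, 308, 7), ("7D", 643, 336, 7),
]

_BARLEY_TABLE = [
    ("1H", 522, 205, 1), ("2H", 665, 260, 2), ("3H", 622, 270, 3),
    ("4H", 647, 312, 4), ("5H", 597, 210, 5), ("6H", 560, 253, 6),
    ("7H", 657, 330, 7),
]


def wheat_specs() -> list[ChromosomeSpec]:
    """The 21 bread-wheat chromosomes at CS RefSeq scale."""
    return [ChromosomeSpec(n, WHEAT, ln, cen, g) for n, ln, cen, g in _WHEAT_TABLE]


def barley_specs() -> list[ChromosomeSpec]:
    """The 7 barley chromosomes at Morex scale."""
    return [ChromosomeSpec(n, BARLEY, ln, cen, g) for n, ln, cen, g in _BARLEY_TABLE]


def default_hybrid_reference(bin_size_mb: int = 1) -> HybridReference:
    """21 wheat + 7 barley chromosomes on a 1-Mb grid (~18,400 bins)."""
    return build_hybrid_reference(wheat_specs(), barley_specs(), bin_size_mb=bin_size_mb)


def read_chromosome_specs(path: str | Path) -> list[ChromosomeSpec]:
    """Read a tab-delimited chromosome spec table.

    Columns: name, subgenome, length_mb, centromere_mb, group.  Lines starting
    with '#' are comments.
    """
    specs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}")
        name, subgenome, length, cen, group = fields
        specs.append(ChromosomeSpec(name, subgenome, int(length), int(cen), int(group)))
    return specs


def write_chromosome_specs(specs: Iterable[ChromosomeSpec], path: str | Path) -> None:
    lines = ["#name\tsubgenome\tlength_mb\tcentromere_mb\tgroup"]
    for s in specs:
        lines.append(f"{s.name}\t{s.subgenome}\t{s.length_mb}\t{s.centromere_mb}\t{s.group}")
    Path(path).write_text("\n".join(lines) + "\n")
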