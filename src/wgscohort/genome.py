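"""Genome partitions and per-bin read-depth tracks.

A :class:`GenomeSpec` fixes the chromosome set and the bin size at which
read-depth (RD) signal is tabulated; an :class:`RDProfile` holds the binned
RD totals for one sample/tissue on that partition.  Coordinates are 0-based,
half-open everywhere, matching BED/bedGraph conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

__all__ = ["GenomeSpec", "RDProfile", "read_bedgraph", "write_bedgraph"]


@dataclass(frozen=True)
class GenomeSpec:
    """A genome partition: ordered chromosomes and a uniform bin size."""

    chromosomes: Tuple[Tuple[str, int], ...]
    bin_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(c), int(n)) for c, n in self.chromosomes))
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(n <= 0 for _, n in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def names(self) -> List[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for c, n in self.chromosomes:
            if c == chrom:
                return n
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_bins(self, chrom: str) -> int:
        # trailing partial bin counts as one bin
        return math.ceil(self.length(chrom) / self.bin_size)

    def total_length(self) -> int:
        return sum(n for _, n in self.chromosomes)


@dataclass
class RDProfile:
    """Binned read-depth totals for one sample/tissue.

    ``bins[chrom]`` is a float array of length ``ceil(chrom_length/bin_size)``
    holding total read depth per bin; values are non-negative.
    """

    sample_id: str
    tissue: str  # "tumor" | "normal"
    bins: Dict[str, np.ndarray]
    bin_size: int
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be 'tumor' or 'normal', got {self.tissue!r}")
        for chrom, arr in self.bins.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative read depth on {chrom}")
            self.bins[chrom] = arr
            self.chrom_lengths.setdefault(chrom, len(arr) * self.bin_size)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.bins.values()))

    def same_partition(self, other: "RDProfile") -> None:
        """Raise if the two profiles are not on the same genome partition."""
        if self.bin_size != other.bin_size:
            raise ValueError(f"bin_size mismatch: {self.bin_size} vs {other.bin_size}")
        if set(self.bins) != set(other.bins):
            missing = set(self.bins) ^ set(other.bins)
            raise ValueError(f"chromosome sets differ (offending: {sorted(missing)})")
        for chrom in self.bins:
            if len(self.bins[chrom]) != len(other.bins[chrom]):
                raise ValueError(f"bin counts differ on chromosome {chrom}")


def write_bedgraph(profile: RDProfile, path: str | Path) -> None:
    """Write a profile as 0-based half-open bedGraph (one row per bin)."""
    rows = []
    for chrom, arr in profile.bins.items():
        length = profile.chrom_lengths.get(chrom, len(arr) * profile.bin_size)
        starts = np.arange(len(arr)) * profile.bin_size
        ends = np.minimum(starts + profile.bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": arr}))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, sample_id: str = "", tissue: str = "tumor") -> RDProfile:
    """Read a bedGraph written on a uniform partition back into a profile.

    Rows must be per-bin (constant step except a trailing partial bin per
    chromosome); arbitrary run-length-encoded bedGraphs are not accepted.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"empty bedGraph: {path}")
    steps = (df["end"] - df["start"]).to_numpy()
    bin_size = int(steps.max())
    bins: Dict[str, np.ndarray] = {}
    lengths: Dict[str, int] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        expected = np.arange(len(sub)) * bin_size
        if not np.array_equal(sub["start"].to_numpy(), expected):
            raise ValueError(f"bedGraph rows on {chrom} are not a uniform {bin_size}-bp partition")
        bins[chrom] = sub["value"].to_numpy(dtype=float)
        lengths[chrom] = int(sub["end"].iloc[-1])
    return RDProfile(sample_id=sample_id, tissue=tissue, bins=bins,
                     bin_size=bin_size, chrom_lengths=lengths)
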