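"""Loss-of-heterozygosity detection from paired normal/tumor site calls.

A site is an LOH event when (i) the normal genotype is heterozygous and
(ii) the tumor allele fraction is (near) 0 or 1 at adequate depth.  The
germline side uses the genotype call rather than a literal allele-frequency
test (observed frequencies are never exactly 0.5), and the tumor side's
exact 0/1 is relaxed by ``af_tol`` to absorb residual non-tumor reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import pandas as pd

__all__ = ["PairedSiteCall", "detect_loh", "read_site_table", "write_loh_bed",
           "detect_loh_table"]

NORMAL_GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class PairedSiteCall:
    """One germline-variant site: normal genotype plus tumor allele counts.

    Positions are 1-based, matching variant-table convention.
    """

    chrom: str
    pos: int
    normal_genotype: str
    tumor_ref_count: int
    tumor_alt_count: int

    def __post_init__(self) -> None:
        if self.normal_genotype not in NORMAL_GENOTYPES:
            raise ValueError(f"unknown normal genotype {self.normal_genotype!r}")
        if self.tumor_ref_count < 0 or self.tumor_alt_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref_count + self.tumor_alt_count

    @property
    def tumor_alt_fraction(self) -> float:
        d = self.tumor_depth
        return self.tumor_alt_count / d if d else float("nan")


def detect_loh(sites: Sequence[PairedSiteCall], min_tumor_depth: int = 10,
               af_tol: float = 0.02) -> List[PairedSiteCall]:
    """Sites heterozygous in the normal whose tumor allele fraction is ~0 or ~1.

    Emits a site iff normal genotype is het, tumor depth >= min_tumor_depth,
    and the tumor alternate-allele fraction is <= af_tol or >= 1 - af_tol.
    The output is a subset of the input in input order.
    """
    out = []
    for s in sites:
        if s.normal_genotype != "het":
            continue
        d = s.tumor_depth
        if d < min_tumor_depth:
            continue
        af = s.tumor_alt_count / d
        if af <= af_tol or af >= 1.0 - af_tol:
            out.append(s)
    return out


def detect_loh_table(table: pd.DataFrame, min_tumor_depth: int = 10,
                     af_tol: float = 0.02) -> pd.DataFrame:
    """Vectorized :func:`detect_loh` over a site table.

    Expects columns chrom, pos, normal_gt, t_ref, t_alt; returns the LOH rows.
    """
    if (table["t_ref"] < 0).any() or (table["t_alt"] < 0).any():
        raise ValueError("allele counts must be non-negative")
    depth = table["t_ref"] + table["t_alt"]
    af = table["t_alt"] / depth.where(depth > 0)  # zero-depth sites -> NaN, never kept
    keep = (
        (table["normal_gt"] == "het")
        & (depth >= min_tumor_depth)
        & ((af <= af_tol) | (af >= 1.0 - af_tol))
    )
    return table.loc[keep.fillna(False)]


def read_site_table(path: str | Path) -> List[PairedSiteCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [PairedSiteCall(r.chrom, int(r.pos), str(r.normal_gt),
                           int(r.t_ref), int(r.t_alt)) for r in df.itertuples()]


def write_loh_bed(sites: Sequence[PairedSiteCall], path: str | Path) -> None:
    """BED-like output: chrom, 0-based start, end, tumor alt fraction."""
    rows = [(s.chrom, s.pos - 1, s.pos, f"{s.tumor_alt_fraction:.4f}") for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
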