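"""Read-depth CNV segmentation: normalize, bin, median-smooth, segment, classify.

The pipeline turns a paired tumor/normal read-depth profile into classified
copy-number segments:

1. scale the normal profile so its total signal matches the tumor's;
2. aggregate both profiles into 3000-bp bins and take the per-bin
   log2(tumor/normal) ratio (the LR track);
3. smooth the LR track with a sliding median (default window 1001 bins,
   i.e. half-window 500);
4. cut the smoothed track into maximal constant runs; each run's log ratio
   is recomputed from the raw binned totals, log2(sum tumor / sum normal);
5. call gain where lr > 0.2, loss where lr < -0.2, restricted to segments
   longer than 100 kb; everything else is neutral.

A note on resolution: a sliding median of half-window w exactly preserves
constant blocks of at least w+1 bins and completely removes isolated blocks
of w bins or fewer, so with the default half_window=500 on 3-kb bins the
pipeline detects events of about 1.5 Mb and larger; shrink ``half_window``
to target smaller events (see docs/methods.md).

Cohort-level summaries map each sample's gain/loss calls onto 1-Mb genome
bins and record, per bin and event type, how many cohort samples carry an
overlapping event.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeSpec, RDProfile

logger = logging.getLogger(__name__)

__all__ = [
    "LRTrack",
    "CNSegment",
    "BinFrequencyMap",
    "normalize_normal",
    "bin_and_log_ratio",
    "smooth_lr",
    "segment_constant",
    "classify_segments",
    "segment_sample",
    "intersect_with_caller",
    "bin_frequency_map",
    "segment_recovery",
    "write_segments_bed",
    "read_segments_bed",
    "write_frequency_map",
    "read_frequency_map",
]

DEFAULT_BIN_SIZE = 3000          # bp per LR bin
DEFAULT_HALF_WINDOW = 500        # bins each side; total window 1001 bins
DEFAULT_GAIN_THRESHOLD = 0.2     # log2 units, strict
DEFAULT_LOSS_THRESHOLD = -0.2
DEFAULT_MIN_LENGTH = 100_000     # bp, strict
DEFAULT_CONSTANCY_TOL = 1e-9


@dataclass
class LRTrack:
    """Per-chromosome log2(tumor/normal) arrays on a uniform bin grid.

    Masked bins (zero denominator or zero tumor signal) are NaN.  The raw
    binned tumor and normalized-normal totals ride along so segment log
    ratios can be recomputed from totals rather than from smoothed values.
    """

    values: Dict[str, np.ndarray]
    bin_size: int
    smoothed: bool = False
    tumor_sums: Dict[str, np.ndarray] = field(default_factory=dict)
    normal_sums: Dict[str, np.ndarray] = field(default_factory=dict)
    chrom_lengths: Dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CNSegment:
    """Contiguous region with an assigned log ratio and gain/loss/neutral call."""

    chrom: str
    start: int
    end: int
    lr: float
    call: str = "unset"  # gain | loss | neutral | unset
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BinFrequencyMap:
    """Per-1-Mb-bin gain/loss sample counts and frequencies for one cohort."""

    table: pd.DataFrame  # chrom, bin_start, bin_end, gain_count, loss_count, gain_freq, loss_freq
    n_samples: int
    map_bin: int


# ---------------------------------------------------------------------------
# Step 2: total-signal normalization of the normal profile
# ---------------------------------------------------------------------------

def normalize_normal(tumor: RDProfile, normal: RDProfile) -> RDProfile:
    """Scale the normal profile so its total read depth equals the tumor's.

    Implements RDn_hat(i) = RDn(i) * sum(RDt) / sum(RDn); afterwards the
    normalized normal conserves the tumor's total signal exactly.
    """
    tumor.same_partition(normal)
    total_n = normal.total()
    if total_n <= 0:
        raise ValueError("normal profile has zero total read depth")
    scale = tumor.total() / total_n
    bins = {chrom: arr * scale for chrom, arr in normal.bins.items()}
    return RDProfile(normal.sample_id, "normal", bins, normal.bin_size,
                     dict(normal.chrom_lengths))


# ---------------------------------------------------------------------------
# Steps 3-4: binning and the log-ratio track
# ---------------------------------------------------------------------------

def _aggregate(arr: np.ndarray, factor: int) -> np.ndarray:
    """Sum consecutive groups of ``factor`` bins (trailing partial group kept)."""
    if factor == 1:
        return arr.astype(float)
    n_out = math.ceil(len(arr) / factor)
    padded = np.zeros(n_out * factor)
    padded[: len(arr)] = arr
    return padded.reshape(n_out, factor).sum(axis=1)


def bin_and_log_ratio(tumor: RDProfile, normal_hat: RDProfile,
                      bin_size: int = DEFAULT_BIN_SIZE) -> LRTrack:
    """Aggregate both profiles into ``bin_size``-bp bins and take log2 ratios.

    Input profiles may be at base resolution or any finer bin size that
    divides ``bin_size``; a trailing partial bin per chromosome is allowed.
    Bins where either total is zero are masked (NaN) — the log ratio is
    undefined there — and stay excluded downstream.
    """
    tumor.same_partition(normal_hat)
    if bin_size % tumor.bin_size != 0:
        raise ValueError(
            f"target bin size {bin_size} not divisible by profile bin size {tumor.bin_size}")
    factor = bin_size // tumor.bin_size
    values: Dict[str, np.ndarray] = {}
    t_sums: Dict[str, np.ndarray] = {}
    n_sums: Dict[str, np.ndarray] = {}
    for chrom in tumor.bins:
        t = _aggregate(tumor.bins[chrom], factor)
        n = _aggregate(normal_hat.bins[chrom], factor)
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.log2(t / n)
        lr[(t <= 0) | (n <= 0)] = np.nan
        values[chrom] = lr
        t_sums[chrom] = t
        n_sums[chrom] = n
    lengths = {c: tumor.chrom_lengths.get(c, len(tumor.bins[c]) * tumor.bin_size)
               for c in tumor.bins}
    return LRTrack(values, bin_size, smoothed=False, tumor_sums=t_sums,
                   normal_sums=n_sums, chrom_lengths=lengths)


# ---------------------------------------------------------------------------
# Step 5: sliding-median smoothing
# ---------------------------------------------------------------------------

def _sliding_median(v: np.ndarray, w: int) -> np.ndarray:
    """Median over windows [b-w, b+w], truncated at the array edges.

    NaN entries are excluded from every window's median; windows with no
    finite value yield NaN.
    """
    n = len(v)
    if n == 0:
        return v.copy()
    if w >= n:
        logger.warning("smoothing window (%d bins half-width) exceeds chromosome "
                       "(%d bins); truncating to whole chromosome", w, n)
        w = n - 1
    out = np.empty(n)
    has_nan = bool(np.isnan(v).any())
    med = np.nanmedian if has_nan else np.median
    core = slice(w, n - w)
    if n >= 2 * w + 1:
        windows = np.lib.stride_tricks.sliding_window_view(v, 2 * w + 1)
        with np.errstate(all="ignore"):
            out[core] = med(windows, axis=1)
    for b in range(min(w, n)):
        with np.errstate(all="ignore"):
            out[b] = med(v[max(0, b - w): b + w + 1])
    for b in range(max(n - w, w), n):
        with np.errstate(all="ignore"):
            out[b] = med(v[max(0, b - w): b + w + 1])
    return out


def smooth_lr(lr: LRTrack, half_window: int = DEFAULT_HALF_WINDOW) -> LRTrack:
    """Replace each bin with the median of the bins within ``half_window``.

    Window is [b - half_window, b + half_window] (2*half_window + 1 bins),
    truncated at chromosome ends; masked bins are excluded from each
    window's median and remain masked in the output.
    """
    if half_window < 0:
        raise ValueError("half_window must be non-negative")
    values = {}
    for chrom, v in lr.values.items():
        sm = _sliding_median(v, half_window)
        sm[np.isnan(v)] = np.nan  # masked bins stay masked
        values[chrom] = sm
    return LRTrack(values, lr.bin_size, smoothed=True, tumor_sums=lr.tumor_sums,
                   normal_sums=lr.normal_sums, chrom_lengths=lr.chrom_lengths)


# ---------------------------------------------------------------------------
# Step 6: constant-run segmentation and classification
# ---------------------------------------------------------------------------

def segment_constant(smoothed: LRTrack, tol: float = DEFAULT_CONSTANCY_TOL,
                     sample_id: str = "") -> List[CNSegment]:
    """Cut each chromosome into maximal runs of (near-)constant smoothed LR.

    A run extends while each bin's smoothed value stays within ``tol`` of
    the run's first value.  Masked bins split runs and belong to no segment.
    Each segment's ``lr`` is recomputed from the raw binned totals as
    log2(sum tumor / sum normal) over the segment's bins.
    """
    segments: List[CNSegment] = []
    for chrom, v in smoothed.values.items():
        n = len(v)
        t_sums = smoothed.tumor_sums.get(chrom)
        n_sums = smoothed.normal_sums.get(chrom)
        chrom_len = smoothed.chrom_lengths.get(chrom, n * smoothed.bin_size)

        def flush(b0: int, b1: int) -> None:
            """Emit bins [b0, b1) as one segment."""
            start = b0 * smoothed.bin_size
            end = min(b1 * smoothed.bin_size, chrom_len)
            if t_sums is not None and n_sums is not None:
                ts = t_sums[b0:b1].sum()
                ns = n_sums[b0:b1].sum()
                lr_val = math.log2(ts / ns) if ts > 0 and ns > 0 else float("nan")
            else:
                lr_val = float(np.nanmean(v[b0:b1]))
            segments.append(CNSegment(chrom, start, end, lr_val, "unset", sample_id))

        run_start: Optional[int] = None
        anchor = 0.0
        for b in range(n):
            if np.isnan(v[b]):
                if run_start is not None:
                    flush(run_start, b)
                    run_start = None
                continue
            if run_start is None:
                run_start, anchor = b, v[b]
            elif abs(v[b] - anchor) > tol:
                flush(run_start, b)
                run_start, anchor = b, v[b]
        if run_start is not None:
            flush(run_start, n)
    return segments


def classify_segments(segments: Sequence[CNSegment],
                      gain_thr: float = DEFAULT_GAIN_THRESHOLD,
                      loss_thr: float = DEFAULT_LOSS_THRESHOLD,
                      min_len: int = DEFAULT_MIN_LENGTH) -> List[CNSegment]:
    """Assign gain/loss/neutral calls with strict thresholds and length filter.

    gain iff lr > gain_thr and length > min_len; loss iff lr < loss_thr and
    length > min_len; a log ratio exactly at a threshold is neutral.
    """
    out = []
    for seg in segments:
        if seg.length > min_len and not math.isnan(seg.lr) and seg.lr > gain_thr:
            call = "gain"
        elif seg.length > min_len and not math.isnan(seg.lr) and seg.lr < loss_thr:
            call = "loss"
        else:
            call = "neutral"
        out.append(replace(seg, call=call))
    return out


def segment_sample(tumor: RDProfile, normal: RDProfile,
                   bin_size: int = DEFAULT_BIN_SIZE,
                   half_window: int = DEFAULT_HALF_WINDOW,
                   tol: float = DEFAULT_CONSTANCY_TOL,
                   gain_thr: float = DEFAULT_GAIN_THRESHOLD,
                   loss_thr: float = DEFAULT_LOSS_THRESHOLD,
                   min_len: int = DEFAULT_MIN_LENGTH) -> List[CNSegment]:
    """Run the full pipeline: normalize -> bin -> smooth -> segment -> classify."""
    normal_hat = normalize_normal(tumor, normal)
    lr = bin_and_log_ratio(tumor, normal_hat, bin_size)
    sm = smooth_lr(lr, half_window)
    segs = segment_constant(sm, tol, sample_id=tumor.sample_id)
    return classify_segments(segs, gain_thr, loss_thr, min_len)


def intersect_with_caller(segments: Sequence[CNSegment],
                          caller_segments: Sequence[CNSegment]) -> List[CNSegment]:
    """Keep gain/loss segments that overlap (>= 1 bp) a same-sign external call.

    Plumbing for combining this filter with an external segmentation caller's
    output; neutral segments pass through unchanged.
    """
    kept = []
    for seg in segments:
        if seg.call not in ("gain", "loss"):
            kept.append(seg)
            continue
        for ext in caller_segments:
            if (ext.chrom == seg.chrom and ext.call == seg.call
                    and ext.start < seg.end and seg.start < ext.end):
                kept.append(seg)
                break
    return kept


# ---------------------------------------------------------------------------
# Cohort frequency maps
# ---------------------------------------------------------------------------

def _map_bins(genome: GenomeSpec, map_bin: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.chromosomes:
        starts = np.arange(0, length, map_bin)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "bin_start": starts,
            "bin_end": np.minimum(starts + map_bin, length),
        }))
    return pd.concat(rows, ignore_index=True)


def bin_frequency_map(calls: Mapping[str, Sequence[CNSegment]],
                      cohort: Sequence[str],
                      genome: GenomeSpec,
                      map_bin: int = 1_000_000) -> BinFrequencyMap:
    """Per-1-Mb-bin fraction of cohort samples carrying a gain/loss overlap.

    A sample counts toward a bin/event type when at least one of its
    segments of that type overlaps the bin by >= 1 bp; a segment straddling
    a bin boundary therefore counts in every bin it touches.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    grid = _map_bins(genome, map_bin)
    offsets = {}
    off = 0
    for chrom, length in genome.chromosomes:
        offsets[chrom] = off
        off += math.ceil(length / map_bin)
    n_bins = off
    counts = {"gain": np.zeros(n_bins, dtype=int), "loss": np.zeros(n_bins, dtype=int)}
    for sample in cohort:
        hit = {"gain": np.zeros(n_bins, dtype=bool), "loss": np.zeros(n_bins, dtype=bool)}
        for seg in calls.get(sample, ()):
            if seg.call not in ("gain", "loss") or seg.chrom not in offsets:
                continue
            b0 = offsets[seg.chrom] + seg.start // map_bin
            b1 = offsets[seg.chrom] + (seg.end - 1) // map_bin
            hit[seg.call][b0: b1 + 1] = True
        for kind in ("gain", "loss"):
            counts[kind] += hit[kind]
    table = grid.copy()
    n = len(cohort)
    table["gain_count"] = counts["gain"]
    table["loss_count"] = counts["loss"]
    table["gain_freq"] = counts["gain"] / n
    table["loss_freq"] = counts["loss"] / n
    return BinFrequencyMap(table, n_samples=n, map_bin=map_bin)


# ---------------------------------------------------------------------------
# Recovery scoring against planted truth
# ---------------------------------------------------------------------------

def segment_recovery(truth_events, segments: Sequence[CNSegment],
                     genome: GenomeSpec,
                     min_event_length: int = 0) -> Tuple[float, float]:
    """Bin-level precision/recall of gain/loss calls against planted events.

    Each LR-resolution bin gets a truth label from the planted events whose
    span covers its midpoint (restricted to events >= ``min_event_length``)
    and a called label from the classified segments; precision is the
    fraction of called gain/loss bins with the matching truth label, recall
    the fraction of truth gain/loss bins called with the matching label.
    Returns (precision, recall); either is 1.0 when its denominator is 0.
    """
    tp = fp = fn = 0
    for chrom in genome.names:
        n = genome.n_bins(chrom)
        mid = np.arange(n) * genome.bin_size + genome.bin_size / 2.0
        truth = np.zeros(n, dtype=int)  # 0 neutral, +1 gain, -1 loss
        for ev in truth_events:
            if ev.chrom == chrom and (ev.end - ev.start) >= min_event_length:
                inside = (mid >= ev.start) & (mid < ev.end)
                truth[inside] = 1 if ev.true_lr > 0 else -1
        called = np.zeros(n, dtype=int)
        for seg in segments:
            if seg.chrom == chrom and seg.call in ("gain", "loss"):
                b0 = seg.start // genome.bin_size
                b1 = math.ceil(seg.end / genome.bin_size)
                called[b0:b1] = 1 if seg.call == "gain" else -1
        tp += int(np.sum((called != 0) & (called == truth)))
        fp += int(np.sum((called != 0) & (called != truth)))
        fn += int(np.sum((truth != 0) & (called != truth)))
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_segments_bed(segments: Sequence[CNSegment], path: str | Path) -> None:
    """BED6: name = call, score = round(1000*|lr|) capped at 1000, strand '.'"""
    rows = [
        (s.chrom, s.start, s.end, s.call,
         min(1000, int(round(1000 * abs(s.lr)))) if not math.isnan(s.lr) else 0, ".")
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_segments_bed(path: str | Path, sample_id: str = "") -> List[CNSegment]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    return [
        CNSegment(r.chrom, int(r.start), int(r.end),
                  float(r.score) / 1000.0 * (-1 if r.name == "loss" else 1),
                  str(r.name), sample_id)
        for r in df.itertuples()
    ]


def write_frequency_map(fmap: BinFrequencyMap, path: str | Path) -> None:
    df = fmap.table.copy()
    df["n_samples"] = fmap.n_samples
    df.to_csv(path, sep="\t", index=False)


def read_frequency_map(path: str | Path) -> BinFrequencyMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    n = int(df["n_samples"].iloc[0])
    map_bin = int((df["bin_end"] - df["bin_start"]).max())
    return BinFrequencyMap(df.drop(columns=["n_samples"]), n_samples=n, map_bin=map_bin)
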