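"""Cohort statistics: Fisher exact, Wilcoxon rank-sum, two-proportion z with
Yates correction, Bonferroni adjustment, per-bin cohort comparison, and the
label-randomization null for significant-peak counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cnv import BinFrequencyMap, CNSegment, bin_frequency_map
from .genome import GenomeSpec

__all__ = [
    "ContingencyTable2x2",
    "RandomizationSummary",
    "fisher_exact_2x2",
    "bonferroni",
    "wilcoxon_rank_sum",
    "two_proportion_z_yates",
    "per_bin_fisher",
    "randomization_null",
    "write_randomization_json",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are cohorts, columns event/no-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the probability-mass rule: p is the sum of hypergeometric
    probabilities, over all tables with the observed margins, whose point
    probability does not exceed the observed table's.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


def bonferroni(p_values: Sequence[float], m: int | None = None) -> List[float]:
    """Bonferroni adjustment: p' = min(1, m*p), m defaulting to len(p_values)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if any(not (0 <= p <= 1) for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation distribution when the combined sample size is <= 12
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    if len(combined) <= 12 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                  use_continuity=True).pvalue)


def two_proportion_z_yates(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test with Yates' continuity correction.

    z = (|k1/n1 - k2/n2| - 0.5*(1/n1 + 1/n2)) / sqrt(phat*(1-phat)*(1/n1 + 1/n2))
    with the pooled phat; the corrected difference is clamped at 0, and a
    degenerate pooled proportion (0 or 1) yields p = 1 by convention.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("event counts must satisfy 0 <= k <= n")
    phat = (k1 + k2) / (n1 + n2)
    if phat in (0.0, 1.0):
        return 1.0
    inv = 1.0 / n1 + 1.0 / n2
    diff = abs(k1 / n1 - k2 / n2) - 0.5 * inv
    if diff < 0:
        diff = 0.0
    z = diff / math.sqrt(phat * (1 - phat) * inv)
    return float(2 * sps.norm.sf(z))


# ---------------------------------------------------------------------------
# Per-bin cohort comparison
# ---------------------------------------------------------------------------

def per_bin_fisher(map_a: BinFrequencyMap, map_b: BinFrequencyMap,
                   alpha: float = 0.05, adjust: str = "none",
                   _cache: Dict[Tuple[int, int, int, int], float] | None = None
                   ) -> pd.DataFrame:
    """Fisher test per (1-Mb bin, event type) between two cohorts.

    Each test compares samples-with-event vs samples-without across the two
    cohorts.  ``adjust`` is "none" (significance on raw p < alpha) or
    "bonferroni" (on adjusted p < alpha, over all bin/type tests).  Returns
    a table with columns chrom, bin_start, bin_end, type, p_raw, p_adj,
    significant.
    """
    ga = map_a.table
    gb = map_b.table
    if len(ga) != len(gb) or not (
        ga["chrom"].equals(gb["chrom"]) and ga["bin_start"].equals(gb["bin_start"])
    ):
        raise ValueError("frequency maps are on different bin grids")
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    cache = _cache if _cache is not None else {}
    rows = []
    n_a, n_b = map_a.n_samples, map_b.n_samples
    for kind in ("gain", "loss"):
        ka = ga[f"{kind}_count"].to_numpy()
        kb = gb[f"{kind}_count"].to_numpy()
        for i in range(len(ga)):
            key = (int(ka[i]), n_a - int(ka[i]), int(kb[i]), n_b - int(kb[i]))
            p = cache.get(key)
            if p is None:
                p = fisher_exact_2x2(ContingencyTable2x2(*key))
                cache[key] = p
            rows.append((ga["chrom"].iloc[i], int(ga["bin_start"].iloc[i]),
                         int(ga["bin_end"].iloc[i]), kind, p))
    out = pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "type", "p_raw"])
    if adjust == "bonferroni":
        out["p_adj"] = bonferroni(out["p_raw"].tolist())
    else:
        out["p_adj"] = out["p_raw"]
    out["significant"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# Label-randomization null
# ---------------------------------------------------------------------------

@dataclass
class RandomizationSummary:
    """Distribution of significant-peak counts under shuffled cohort labels."""

    n_iterations: int
    alpha: float
    counts: np.ndarray  # per-iteration significant-peak counts
    observed: int       # significant peaks under the true labels

    @property
    def median(self) -> float:
        return float(np.median(self.counts))

    @property
    def min(self) -> int:
        return int(self.counts.min())

    @property
    def max(self) -> int:
        return int(self.counts.max())


def randomization_null(per_sample_calls: Mapping[str, Sequence[CNSegment]],
                       labels: Mapping[str, str],
                       genome: GenomeSpec,
                       n_iter: int = 1000,
                       alpha: float = 0.05,
                       seed: int = 0,
                       map_bin: int = 1_000_000,
                       adjust: str = "none") -> RandomizationSummary:
    """Null distribution of significant-peak counts by cohort-label shuffling.

    Samples are pooled and randomly re-assigned to two groups of the original
    sizes (permutation without replacement); for each iteration both
    frequency maps are rebuilt from the fixed per-sample calls and the
    per-bin Fisher comparison is re-run, recording the number of significant
    (bin, event type) peaks.  Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    samples = list(per_sample_calls)
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two cohort labels, got {groups}")
    in_a = np.array([labels[s] == groups[0] for s in samples])
    n_a = int(in_a.sum())
    if n_a == 0 or n_a == len(samples):
        raise ValueError("each cohort needs at least one sample")

    cache: Dict[Tuple[int, int, int, int], float] = {}

    def count_significant(mask_a: np.ndarray) -> int:
        cohort_a = [s for s, m in zip(samples, mask_a) if m]
        cohort_b = [s for s, m in zip(samples, mask_a) if not m]
        map_a = bin_frequency_map(per_sample_calls, cohort_a, genome, map_bin)
        map_b = bin_frequency_map(per_sample_calls, cohort_b, genome, map_bin)
        peaks = per_bin_fisher(map_a, map_b, alpha=alpha, adjust=adjust, _cache=cache)
        return int(peaks["significant"].sum())

    observed = count_significant(in_a)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter, dtype=int)
    idx = np.arange(len(samples))
    for it in range(n_iter):
        perm = rng.permutation(idx)
        mask = np.zeros(len(samples), dtype=bool)
        mask[perm[:n_a]] = True
        counts[it] = count_significant(mask)
    return RandomizationSummary(n_iterations=n_iter, alpha=alpha,
                                counts=counts, observed=observed)


def write_randomization_json(summary: RandomizationSummary, path: str | Path) -> None:
    payload = {
        "n_iter": summary.n_iterations,
        "alpha": summary.alpha,
        "observed": summary.observed,
        "median": summary.median,
        "min": summary.min,
        "max": summary.max,
        "counts": summary.counts.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
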