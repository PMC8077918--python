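"""Clonal architecture from somatic VAFs: MATH score, the clustering input
filters, a binomial-mixture clone-count estimator, tree-topology
classification, and cohort comparisons of binary clonality summaries.

The clone-count estimator fits one-dimensional binomial mixture models to
(alt_count, depth) pairs by expectation-maximization for k = 1..k_max
(multiple restarts) and picks k by the Bayesian information criterion.  It
is a transparent stand-in for variational VAF-clustering tools: the input
filters those tools prescribe (VAF above 0.6 removed as copy-number
affected, minimum depth 14) are applied exactly, while the clustering model
itself is the simpler binomial mixture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .stats import ContingencyTable2x2, fisher_exact_2x2

__all__ = [
    "SomaticVAFRecord",
    "CloneTree",
    "math_score",
    "filter_for_clustering",
    "filter_for_trees",
    "estimate_clone_count",
    "classify_tree",
    "compare_clonality",
    "read_vaf_table",
    "read_clone_tree_json",
]

MAD_SCALE = 1.4826  # consistency constant: scaled MAD estimates sigma under normality


@dataclass(frozen=True)
class SomaticVAFRecord:
    """One somatic SNV with ref/alt read counts and optional CNV annotation."""

    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    overlapping_cnv_lr: Optional[float] = None
    cnv_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        d = self.depth
        return self.alt_count / d if d else float("nan")


def math_score(vafs: Sequence[float]) -> float:
    """Mutant-allele tumor heterogeneity: 100 * scaled MAD(VAF) / median(VAF).

    MAD is scaled by 1.4826 (the normal-consistency convention of the MATH
    literature).  Scale-invariant and >= 0; requires at least two VAFs and a
    positive median.
    """
    v = np.asarray(list(vafs), dtype=float)
    if len(v) < 2:
        raise ValueError("MATH needs at least two VAF values")
    med = float(np.median(v))
    if med <= 0:
        raise ValueError("median VAF must be positive")
    mad = float(np.median(np.abs(v - med)))
    return 100.0 * (MAD_SCALE * mad) / med


def filter_for_clustering(records: Sequence[SomaticVAFRecord],
                          max_vaf: float = 0.6,
                          min_depth: int = 14) -> List[SomaticVAFRecord]:
    """Clustering input filter: drop VAF > 0.6 (copy-number affected) and
    depth < 14."""
    return [r for r in records if r.depth >= min_depth and r.vaf <= max_vaf]


def filter_for_trees(records: Sequence[SomaticVAFRecord],
                     max_abs_lr: float = 0.2,
                     max_p: float = 0.01) -> List[SomaticVAFRecord]:
    """Tree-building input filter: drop SNVs inside confident CNV segments.

    A record is removed only when its overlapping segment has |lr| >
    ``max_abs_lr`` AND the segment's p-value is below ``max_p``; records
    without CNV annotation are kept.
    """
    out = []
    for r in records:
        if (r.overlapping_cnv_lr is not None and r.cnv_p is not None
                and abs(r.overlapping_cnv_lr) > max_abs_lr and r.cnv_p < max_p):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Binomial-mixture clone-count estimation
# ---------------------------------------------------------------------------

def _binomial_mixture_loglik(alt: np.ndarray, depth: np.ndarray,
                             theta: np.ndarray, pi: np.ndarray) -> Tuple[float, np.ndarray]:
    """Log-likelihood and responsibilities of a binomial mixture."""
    # log C(n, a) is shared across components and cancels in responsibilities,
    # but is kept so BIC values are comparable across k
    log_comb = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    t = np.clip(theta, 1e-6, 1 - 1e-6)
    comp = (log_comb[:, None] + alt[:, None] * np.log(t)[None, :]
            + (depth - alt)[:, None] * np.log1p(-t)[None, :]
            + np.log(np.clip(pi, 1e-12, None))[None, :])
    norm = logsumexp(comp, axis=1)
    resp = np.exp(comp - norm[:, None])
    return float(norm.sum()), resp


def _fit_binomial_mixture(alt: np.ndarray, depth: np.ndarray, k: int,
                          rng: np.random.Generator, n_restarts: int = 10,
                          max_iter: int = 200, rel_tol: float = 1e-8
                          ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Best-of-restarts EM fit; returns (loglik, theta, pi)."""
    vaf = alt / depth
    best: Tuple[float, np.ndarray, np.ndarray] | None = None
    quantiles = np.quantile(vaf, np.linspace(0.1, 0.9, k)) if k > 1 else np.array([vaf.mean()])
    for _ in range(n_restarts):
        theta = np.clip(quantiles + rng.normal(0, 0.02, k), 1e-3, 0.999)
        pi = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        for _ in range(max_iter):
            ll, resp = _binomial_mixture_loglik(alt, depth, theta, pi)
            w = resp.sum(axis=0)
            theta = (resp * alt[:, None]).sum(axis=0) / np.maximum((resp * depth[:, None]).sum(axis=0), 1e-12)
            pi = w / len(alt)
            if ll - ll_prev < rel_tol * max(1.0, abs(ll)):
                break
            ll_prev = ll
        ll, _ = _binomial_mixture_loglik(alt, depth, theta, pi)
        if best is None or ll > best[0]:
            best = (ll, theta, pi)
    assert best is not None
    return best


def estimate_clone_count(records: Sequence[SomaticVAFRecord], k_max: int = 5,
                         seed: int = 0, n_restarts: int = 10) -> int:
    """Number of clones by BIC over binomial-mixture fits with k = 1..k_max.

    Free parameters per model: k success probabilities plus k-1 mixture
    weights, so BIC = -2*loglik + (2k-1)*ln(n).  Deterministic given seed.
    """
    records = list(records)
    if len(records) < 10:
        raise ValueError(f"need >= 10 records to estimate clone count, got {len(records)}")
    alt = np.array([r.alt_count for r in records], dtype=float)
    depth = np.array([r.depth for r in records], dtype=float)
    if np.any(depth <= 0):
        raise ValueError("records with zero depth cannot be clustered")
    rng = np.random.default_rng(seed)
    n = len(records)
    best_k, best_bic = 1, math.inf
    for k in range(1, k_max + 1):
        ll, _, _ = _fit_binomial_mixture(alt, depth, k, rng, n_restarts=n_restarts)
        bic = -2.0 * ll + (2 * k - 1) * math.log(n)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


# ---------------------------------------------------------------------------
# Tree topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneTree:
    """Rooted clone tree as a parent vector with per-node mutation counts.

    The root's parent is itself (or -1); the tree must be connected and
    acyclic with exactly one root.
    """

    parents: Tuple[int, ...]
    mutations: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        parents = tuple(int(p) for p in self.parents)
        object.__setattr__(self, "parents", parents)
        if self.mutations:
            object.__setattr__(self, "mutations", tuple(int(m) for m in self.mutations))
            if len(self.mutations) != len(parents):
                raise ValueError("mutations and parents lengths differ")
        n = len(parents)
        roots = [i for i, p in enumerate(parents) if p == i or p == -1]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for i, p in enumerate(parents):
            if p != -1 and not (0 <= p < n):
                raise ValueError(f"node {i} has out-of-range parent {p}")
        # connectivity/acyclicity: every node must reach the root within n steps
        root = roots[0]
        for i in range(n):
            node, steps = i, 0
            while node != root:
                node = parents[node]
                steps += 1
                if steps > n:
                    raise ValueError("cycle detected in parent vector")

    @property
    def n_nodes(self) -> int:
        return len(self.parents)


def classify_tree(tree: CloneTree) -> str:
    """"linear" iff every node has at most one child, else "branching"."""
    n_children = [0] * tree.n_nodes
    for i, p in enumerate(tree.parents):
        if p != i and p != -1:
            n_children[p] += 1
    return "linear" if max(n_children, default=0) <= 1 else "branching"


def compare_clonality(cohort_a: Sequence[bool], cohort_b: Sequence[bool]
                      ) -> Tuple[ContingencyTable2x2, float]:
    """Fisher comparison of a binary per-sample summary between two cohorts.

    The summary is e.g. "sample has exactly one clone" or "sample's tree is
    linear"; returns the 2x2 table (rows = cohorts, columns = flag yes/no)
    and the two-sided Fisher p-value.
    """
    a = [bool(v) for v in cohort_a]
    b = [bool(v) for v in cohort_b]
    if not a or not b:
        raise ValueError("both cohorts must be non-empty")
    table = ContingencyTable2x2(sum(a), len(a) - sum(a), sum(b), len(b) - sum(b))
    return table, fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_vaf_table(path: str | Path) -> List[SomaticVAFRecord]:
    """VAF TSV with columns chrom, pos, ref_count, alt_count[, lr, cnv_p]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    has_cnv = "lr" in df.columns and "cnv_p" in df.columns
    out = []
    for r in df.itertuples():
        lr = getattr(r, "lr", None) if has_cnv else None
        cp = getattr(r, "cnv_p", None) if has_cnv else None
        out.append(SomaticVAFRecord(
            r.chrom, int(r.pos), int(r.ref_count), int(r.alt_count),
            None if lr is None or (isinstance(lr, float) and math.isnan(lr)) else float(lr),
            None if cp is None or (isinstance(cp, float) and math.isnan(cp)) else float(cp),
        ))
    return out


def read_clone_tree_json(path: str | Path) -> CloneTree:
    """Tree JSON: {"parents": [...], "mutations": [...]} (mutations optional)."""
    payload = json.loads(Path(path).read_text())
    return CloneTree(tuple(payload["parents"]), tuple(payload.get("mutations", ())))
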