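"""Synthetic inputs with planted ground truth for every pipeline stage.

All generators are pure functions of their parameters and a seed.  A single
global seed can be fanned out to independent sub-streams with
:func:`derive_seed`, which hashes ``(seed, label)`` so that adding one
generator call never perturbs another's stream.

What is emulated (and what is not) is documented in ``docs/methods.md``:
briefly, paired tumor/normal read-depth tracks with planted copy-number
gains/losses and bin-total noise; paired genotype tables with a planted
loss-of-heterozygosity fraction; somatic variant-allele-fraction tables drawn
from a binomial model around planted clone fractions; per-sample binary
feature tables with configurable cohort effects; and taxonomy trees with
read-hit patterns whose true assignment is the lowest common ancestor.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeSpec, RDProfile

__all__ = [
    "PlantedCNV",
    "CloneConfig",
    "derive_seed",
    "gen_rd_profiles",
    "gen_genotype_table",
    "gen_vaf_table",
    "gen_taxonomy_and_hits",
    "gen_cohort_features",
    "gen_signature_reference",
    "gen_spectrum_mutations",
]


def derive_seed(seed: int, label: str) -> int:
    """Deterministic sub-seed (< 2**31) from a global seed and a label."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class PlantedCNV:
    """Ground-truth copy-number event: half-open interval with a true log2 ratio."""

    chrom: str
    start: int
    end: int
    true_lr: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty event {self.chrom}:{self.start}-{self.end}")

    @property
    def kind(self) -> str:
        return "gain" if self.true_lr > 0 else "loss" if self.true_lr < 0 else "neutral"


@dataclass(frozen=True)
class CloneConfig:
    """Planted clonal structure: cellular fractions, mutation counts, coverage."""

    clone_fractions: Tuple[float, ...]
    mutations_per_clone: Tuple[int, ...]
    mean_depth: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "clone_fractions", tuple(float(f) for f in self.clone_fractions))
        object.__setattr__(self, "mutations_per_clone", tuple(int(m) for m in self.mutations_per_clone))
        if len(self.clone_fractions) == 0:
            raise ValueError("at least one clone required")
        if len(self.clone_fractions) != len(self.mutations_per_clone):
            raise ValueError("clone_fractions and mutations_per_clone lengths differ")
        if any(not (0 < f <= 1) for f in self.clone_fractions):
            raise ValueError("clone fractions must lie in (0, 1]")
        if list(self.clone_fractions) != sorted(self.clone_fractions, reverse=True):
            raise ValueError("clone fractions must be sorted descending")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")


# ---------------------------------------------------------------------------
# Read-depth profiles with planted CNVs
# ---------------------------------------------------------------------------

def gen_rd_profiles(
    spec: GenomeSpec,
    events: Sequence[PlantedCNV],
    base_depth: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "gaussian",
    sample_id: str = "S1",
) -> Tuple[RDProfile, RDProfile, List[PlantedCNV]]:
    """Paired tumor/normal binned read-depth tracks with planted events.

    Normal bins fluctuate around ``base_depth`` (expected reads per bin);
    tumor bins around ``base_depth * 2**true_lr`` inside each planted event
    and ``base_depth`` elsewhere.  An event multiplies the expected depth of
    every bin whose midpoint it covers, so truth boundaries are exact at bin
    resolution.  Noise is Gaussian on bin totals with
    ``sd = noise_sd * sqrt(base_depth)`` (clipped at 0); ``noise_model=
    "poisson"`` instead draws each bin total from a Poisson with the bin's
    expected depth (equivalent to summing per-base Poisson counts).
    """
    if base_depth <= 0:
        raise ValueError("base_depth must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_model not in ("gaussian", "poisson"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    for ev in events:
        if ev.chrom not in spec.names:
            raise ValueError(f"event on unknown chromosome {ev.chrom}:{ev.start}-{ev.end}")
        if ev.start < 0 or ev.end > spec.length(ev.chrom):
            raise ValueError(
                f"event outside chromosome bounds: {ev.chrom}:{ev.start}-{ev.end} "
                f"(length {spec.length(ev.chrom)})"
            )

    rng = np.random.default_rng(seed)
    tumor_bins: Dict[str, np.ndarray] = {}
    normal_bins: Dict[str, np.ndarray] = {}
    for chrom in spec.names:
        n = spec.n_bins(chrom)
        mid = np.arange(n) * spec.bin_size + spec.bin_size / 2.0
        expect_t = np.full(n, base_depth, dtype=float)
        for ev in events:
            if ev.chrom == chrom:
                inside = (mid >= ev.start) & (mid < ev.end)
                expect_t[inside] = base_depth * 2.0 ** ev.true_lr
        expect_n = np.full(n, base_depth, dtype=float)
        if noise_model == "poisson":
            tumor_bins[chrom] = rng.poisson(expect_t).astype(float)
            normal_bins[chrom] = rng.poisson(expect_n).astype(float)
        else:
            sd = noise_sd * np.sqrt(base_depth)
            tumor_bins[chrom] = np.clip(expect_t + rng.normal(0.0, 1.0, n) * sd, 0.0, None)
            normal_bins[chrom] = np.clip(expect_n + rng.normal(0.0, 1.0, n) * sd, 0.0, None)

    lengths = {c: spec.length(c) for c in spec.names}
    tumor = RDProfile(sample_id, "tumor", tumor_bins, spec.bin_size, dict(lengths))
    normal = RDProfile(sample_id, "normal", normal_bins, spec.bin_size, dict(lengths))
    return tumor, normal, list(events)


# ---------------------------------------------------------------------------
# Paired genotype tables with planted LOH
# ---------------------------------------------------------------------------

def gen_genotype_table(
    n_sites: int,
    het_fraction: float,
    loh_fraction: float,
    tumor_depth: int = 40,
    seed: int = 0,
    noiseless: bool = False,
    residual_alt_rate: float = 0.01,
) -> pd.DataFrame:
    """Paired normal-genotype / tumor-allele-count table with planted LOH.

    Exactly ``round(n_sites*het_fraction)`` sites are heterozygous in the
    normal; of those, exactly ``round(.*loh_fraction)`` are planted LOH (the
    tumor is homozygous for one allele).  In noisy mode the per-site depth is
    Poisson(``tumor_depth``) truncated at 1, alt counts are binomial with
    p=0.5 at retained-het sites and p=``residual_alt_rate`` (or its
    complement) at LOH sites; noiseless mode emits exact expected counts.
    Returns columns chrom, pos, normal_gt, t_ref, t_alt, truth_loh.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if not (0 <= het_fraction <= 1 and 0 <= loh_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if tumor_depth < 1:
        raise ValueError("tumor_depth must be >= 1")

    rng = np.random.default_rng(seed)
    n_het = round(n_sites * het_fraction)
    n_loh = round(n_het * loh_fraction)

    normal_gt = np.array(["hom_ref"] * n_sites, dtype=object)
    het_idx = rng.choice(n_sites, size=n_het, replace=False)
    normal_gt[het_idx] = "het"
    # split the homozygous remainder between ref and alt states
    hom_idx = np.setdiff1d(np.arange(n_sites), het_idx)
    if len(hom_idx):
        alt_pick = rng.random(len(hom_idx)) < 0.5
        normal_gt[hom_idx[alt_pick]] = "hom_alt"

    truth = np.zeros(n_sites, dtype=bool)
    loh_idx = rng.choice(het_idx, size=n_loh, replace=False) if n_loh else np.array([], dtype=int)
    truth[loh_idx] = True

    if noiseless:
        depth = np.full(n_sites, tumor_depth)
    else:
        depth = np.maximum(rng.poisson(tumor_depth, n_sites), 1)

    p_alt = np.where(normal_gt == "het", 0.5, np.where(normal_gt == "hom_alt", 1.0, 0.0))
    # planted LOH: tumor retains one allele of the het site
    keep_alt = rng.random(n_sites) < 0.5
    if noiseless:
        p_loh = np.where(keep_alt, 1.0, 0.0)
        p_site = np.where(truth, p_loh, p_alt)
        alt = np.round(depth * p_site).astype(int)
    else:
        p_loh = np.where(keep_alt, 1.0 - residual_alt_rate, residual_alt_rate)
        p_site = np.where(truth, p_loh, np.clip(p_alt, residual_alt_rate, 1 - residual_alt_rate))
        p_site = np.where(normal_gt == "hom_ref", 0.0, p_site)  # hom_ref stays alt-free
        p_site = np.where((normal_gt == "hom_alt") & ~truth, 1.0, p_site)
        alt = rng.binomial(depth, p_site)

    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 100,  # 1-based, variant-table convention
            "normal_gt": normal_gt,
            "t_ref": depth - alt,
            "t_alt": alt,
            "truth_loh": truth,
        }
    )


# ---------------------------------------------------------------------------
# VAF tables around planted clone fractions
# ---------------------------------------------------------------------------

def gen_vaf_table(cfg: CloneConfig, seed: int = 0) -> pd.DataFrame:
    """Somatic ref/alt count table drawn around planted clone fractions.

    Each mutation of a clone with cellular fraction f is heterozygous in a
    diploid genome, so its expected VAF is f/2: per site, depth ~
    Poisson(mean_depth) truncated at 1 and alt ~ Binomial(depth, f/2).
    Returns columns chrom, pos, ref_count, alt_count, truth_clone.
    """
    rng = np.random.default_rng(seed)
    rows_f: List[float] = []
    rows_c: List[int] = []
    for k, (f, m) in enumerate(zip(cfg.clone_fractions, cfg.mutations_per_clone)):
        rows_f.extend([f] * m)
        rows_c.extend([k] * m)
    n = len(rows_f)
    if n == 0:
        return pd.DataFrame(columns=["chrom", "pos", "ref_count", "alt_count", "truth_clone"])
    f_arr = np.array(rows_f)
    depth = np.maximum(rng.poisson(cfg.mean_depth, n), 1)
    alt = rng.binomial(depth, f_arr / 2.0)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * 300,
            "ref_count": depth - alt,
            "alt_count": alt,
            "truth_clone": np.array(rows_c, dtype=int),
        }
    )


# ---------------------------------------------------------------------------
# Taxonomy trees and read-hit tables
# ---------------------------------------------------------------------------

def gen_taxonomy_and_hits(
    n_leaves: int,
    depth: int,
    reads: int | Sequence[Sequence[str]],
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Random rooted taxonomy plus read-hit patterns and their true LCA.

    The tree has ``depth`` internal levels below the root and ``n_leaves``
    leaves attached to random deepest-level nodes.  ``reads`` is either a
    list of explicit leaf-name hit patterns or an integer count of random
    patterns (1-4 leaves each).  Truth per read is the lowest common ancestor
    of its hit leaves, computed here by explicit root-path intersection.

    Returns (taxonomy table, hit table, truth node ids).  Taxonomy columns:
    node_id, parent_id, rank, name (root's parent is itself); hit-table
    columns: read_id, length, host_hits, host_min_mm, repeat_flag,
    exo_genomes (comma-separated leaf ids) — host fields are zeroed so every
    generated read survives host filtering.
    """
    if n_leaves < 1 or depth < 1:
        raise ValueError("n_leaves and depth must be >= 1")
    rng = np.random.default_rng(seed)

    ranks = ["root"] + [f"rank{i}" for i in range(1, depth + 1)] + ["species"]
    nodes: List[Tuple[str, str, str, str]] = [("n0", "n0", "root", "root")]
    parent: Dict[str, str] = {"n0": "n0"}
    levels: List[List[str]] = [["n0"]]
    counter = 1
    for lvl in range(1, depth + 1):
        n_at = max(2, min(2**lvl, n_leaves))
        level_nodes = []
        for _ in range(n_at):
            nid = f"n{counter}"
            counter += 1
            par = levels[lvl - 1][rng.integers(len(levels[lvl - 1]))]
            nodes.append((nid, par, ranks[lvl], nid))
            parent[nid] = par
            level_nodes.append(nid)
        levels.append(level_nodes)
    leaves: List[str] = []
    for i in range(n_leaves):
        nid = f"leaf{i}"
        par = levels[-1][rng.integers(len(levels[-1]))]
        nodes.append((nid, par, "species", nid))
        parent[nid] = par
        leaves.append(nid)

    taxonomy = pd.DataFrame(nodes, columns=["node_id", "parent_id", "rank", "name"])

    if isinstance(reads, int):
        patterns = [
            list(rng.choice(leaves, size=rng.integers(1, min(4, n_leaves) + 1), replace=False))
            for _ in range(reads)
        ]
    else:
        patterns = [list(p) for p in reads]
        known = set(leaves)
        for p in patterns:
            for leaf in p:
                if leaf not in known:
                    raise ValueError(f"hit references unknown leaf {leaf!r}")

    def root_path(node: str) -> List[str]:
        path = [node]
        while parent[node] != node:
            node = parent[node]
            path.append(node)
        return path

    truth: List[str] = []
    for p in patterns:
        paths = [root_path(leaf) for leaf in p]
        common = set(paths[0]).intersection(*map(set, paths[1:])) if len(paths) > 1 else set(paths[0])
        # deepest shared node = first along any root path that is common to all
        truth.append(next(n for n in paths[0] if n in common))

    hits = pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(patterns))],
            "length": 100,
            "host_hits": 0,
            "host_min_mm": 0,
            "repeat_flag": False,
            "exo_genomes": [",".join(p) for p in patterns],
        }
    )
    return taxonomy, hits, truth


# ---------------------------------------------------------------------------
# Cohort label and binary feature tables
# ---------------------------------------------------------------------------

def gen_cohort_features(
    n_a: int,
    n_b: int,
    effect: Mapping[str, Tuple[float, float]],
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Binary per-sample feature table with per-cohort event probabilities.

    Feature k is 1 with probability ``p_a`` for cohort-A samples and ``p_b``
    for cohort-B samples.  Returns (label table with columns sample, cohort;
    feature table indexed by sample).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("cohort sizes must be >= 1")
    for feat, (pa, pb) in effect.items():
        if not (0 <= pa <= 1 and 0 <= pb <= 1):
            raise ValueError(f"probabilities for {feat!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    cohorts = ["A"] * n_a + ["B"] * n_b
    labels = pd.DataFrame({"sample": samples, "cohort": cohorts})
    data = {}
    for feat, (pa, pb) in effect.items():
        p = np.array([pa] * n_a + [pb] * n_b)
        data[feat] = (rng.random(n_a + n_b) < p).astype(int)
    features = pd.DataFrame(data, index=samples)
    features.index.name = "sample"
    return labels, features


# ---------------------------------------------------------------------------
# Mutational-signature reference and mutation sampling
# ---------------------------------------------------------------------------

def gen_signature_reference(n_signatures: int = 4, seed: int = 0, alpha: float = 0.3) -> pd.DataFrame:
    """Synthetic 96 x S reference matrix: Dirichlet columns over the 96 classes.

    A stand-in reference for tests and simulations (signature matrices are
    user-supplied in real runs); sparse-ish columns (small Dirichlet alpha)
    keep signatures distinguishable.
    """
    from .spectra import trinucleotide_classes

    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = np.random.default_rng(seed)
    classes = trinucleotide_classes()
    cols = {f"SigS{j+1}": rng.dirichlet(np.full(96, alpha)) for j in range(n_signatures)}
    return pd.DataFrame(cols, index=classes)


def gen_spectrum_mutations(reference: pd.DataFrame, weights: Sequence[float],
                           n_mutations: int, seed: int = 0) -> np.ndarray:
    """Sample trinucleotide-class mutation counts from a signature mixture.

    ``weights`` must align with the reference columns and sum to 1; returns a
    96-vector of counts drawn from Multinomial(n_mutations, R @ w).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != reference.shape[1] or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per reference column")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("generation weights must sum to 1")
    p = reference.to_numpy() @ w
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_mutations, p)
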