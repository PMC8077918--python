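"""Exogenous-read host filtering and parsimonious taxonomy assignment.

Operates on per-read alignment *summaries* (the upstream host and
exogenous-genome alignments are external): reads that plausibly come from
the host genome are removed, and each surviving read with zero-mismatch
exogenous hits is assigned to the lowest common ancestor (the most
parsimonious node) of the genomes it hits in a rooted taxonomy tree.
Per-cohort enrichment is summarized with Fisher tests on taxon presence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .stats import ContingencyTable2x2, fisher_exact_2x2

__all__ = [
    "ReadAlignmentSummary",
    "TaxonomyTree",
    "filter_host",
    "assign_parsimonious",
    "summarize_taxa",
    "read_taxonomy_tsv",
    "read_hit_table",
    "summaries_from_sam",
]


@dataclass(frozen=True)
class ReadAlignmentSummary:
    """Per-read evidence: host alignment summary plus exogenous hit list.

    ``host_min_mismatches`` is the mismatch count of the best host hit;
    ``exo_hits`` lists genome ids hit with zero mismatches.
    """

    read_id: str
    length: int
    host_hits: int
    host_min_mismatches: int
    host_repeat_overlap: bool
    exo_hits: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")
        if self.host_hits < 0 or self.host_min_mismatches < 0:
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "exo_hits", tuple(self.exo_hits))


class TaxonomyTree:
    """Rooted taxonomy: nodes with parent pointers (root points to itself)."""

    def __init__(self, nodes: Iterable[Tuple[str, str, str, str]]):
        """``nodes`` yields (node_id, parent_id, rank, name) rows."""
        self.parent: Dict[str, str] = {}
        self.rank: Dict[str, str] = {}
        self.name: Dict[str, str] = {}
        for node_id, parent_id, rank, name in nodes:
            if node_id in self.parent:
                raise ValueError(f"duplicate node id {node_id!r}")
            self.parent[node_id] = parent_id
            self.rank[node_id] = rank
            self.name[node_id] = name
        roots = [n for n, p in self.parent.items() if p == n]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node, par in self.parent.items():
            if par not in self.parent:
                raise ValueError(f"node {node!r} has unknown parent {par!r}")
        # depth computation doubles as the acyclicity check
        self._depth: Dict[str, int] = {self.root: 0}
        n = len(self.parent)
        for node in self.parent:
            chain = []
            cur = node
            while cur not in self._depth:
                chain.append(cur)
                cur = self.parent[cur]
                if len(chain) > n:
                    raise ValueError("cycle detected in taxonomy")
            base = self._depth[cur]
            for i, c in enumerate(reversed(chain), start=1):
                self._depth[c] = base + i

    def depth(self, node: str) -> int:
        return self._depth[node]

    def ancestor_at_depth(self, node: str, depth: int) -> str:
        while self._depth[node] > depth:
            node = self.parent[node]
        return node

    def lca(self, nodes: Sequence[str]) -> str:
        """Lowest common ancestor of a non-empty node set."""
        if not nodes:
            raise ValueError("LCA of an empty node set is undefined")
        for n in nodes:
            if n not in self.parent:
                raise KeyError(f"unknown taxonomy node {n!r}")
        cur = nodes[0]
        for other in nodes[1:]:
            d = min(self._depth[cur], self._depth[other])
            a, b = self.ancestor_at_depth(cur, d), self.ancestor_at_depth(other, d)
            while a != b:
                a, b = self.parent[a], self.parent[b]
            cur = a
        return cur


def filter_host(reads: Sequence[ReadAlignmentSummary],
                max_mm_per_100bp: float = 5.0,
                multimap_cap: int = 200,
                multimap_min: int = 2,
                remove_beyond_cap: bool = True) -> List[ReadAlignmentSummary]:
    """Remove reads that plausibly come from the host genome.

    A read is removed when any of these hold:

    * it overlaps a repeat region of the host genome;
    * it has a host hit whose mismatch rate is within ``max_mm_per_100bp``
      per 100 bp (a credible host alignment);
    * it is host-multi-mapped: ``multimap_min <= host_hits <= multimap_cap``,
      or beyond the cap when ``remove_beyond_cap`` (the conservative
      default; set False to retain reads exceeding the search cap).

    A unique host hit with a high mismatch rate does not by itself remove a
    read.  The removal set grows monotonically with ``max_mm_per_100bp``.
    """
    out = []
    for r in reads:
        if r.host_repeat_overlap:
            continue
        if r.host_hits >= 1:
            rate = r.host_min_mismatches / r.length * 100.0
            if rate <= max_mm_per_100bp:
                continue
            if r.host_hits >= multimap_min and (r.host_hits <= multimap_cap or remove_beyond_cap):
                continue
        out.append(r)
    return out


def assign_parsimonious(read: ReadAlignmentSummary, taxonomy: TaxonomyTree,
                        genome_to_leaf: Mapping[str, str] | None = None) -> str:
    """Most parsimonious taxonomy node for a read: the LCA of its hit leaves.

    ``genome_to_leaf`` maps exogenous genome ids to taxonomy leaves; when
    omitted, genome ids are taken to be taxonomy node ids directly.
    """
    if not read.exo_hits:
        raise ValueError(f"read {read.read_id!r} has no exogenous hits")
    if genome_to_leaf is not None:
        try:
            leaves = [genome_to_leaf[g] for g in read.exo_hits]
        except KeyError as exc:
            raise KeyError(f"genome id {exc.args[0]!r} has no taxonomy mapping") from None
    else:
        leaves = list(read.exo_hits)
    return taxonomy.lca(leaves)


def summarize_taxa(assignments: Mapping[str, Sequence[str]],
                   taxonomy: TaxonomyTree,
                   labels: Mapping[str, str] | None = None,
                   top_n: int = 100) -> pd.DataFrame:
    """Ranked per-taxon read counts with optional cohort Fisher tests.

    ``assignments`` maps sample id to the node ids its reads were assigned
    to.  Counts roll up to ancestors (a node's count includes every read
    assigned at or below it), so the root's count equals the total number of
    assigned reads.  With cohort ``labels``, each taxon gets a two-sided
    Fisher test on per-sample presence/absence between the two cohorts.
    Returns the ``top_n`` taxa by total count.
    """
    if not assignments:
        raise ValueError("at least one sample required")
    samples = list(assignments)
    per_sample_counts: Dict[str, Dict[str, int]] = {}
    for sample in samples:
        counts: Dict[str, int] = {}
        for node in assignments[sample]:
            cur = node
            while True:
                counts[cur] = counts.get(cur, 0) + 1
                if taxonomy.parent[cur] == cur:
                    break
                cur = taxonomy.parent[cur]
        per_sample_counts[sample] = counts

    all_nodes = sorted({n for c in per_sample_counts.values() for n in c})
    rows = []
    for node in all_nodes:
        total = sum(per_sample_counts[s].get(node, 0) for s in samples)
        present = [per_sample_counts[s].get(node, 0) > 0 for s in samples]
        row = {
            "node_id": node,
            "rank": taxonomy.rank[node],
            "name": taxonomy.name[node],
            "total_reads": total,
            "n_samples_present": sum(present),
        }
        if labels is not None:
            groups = sorted(set(labels.values()))
            if len(groups) != 2:
                raise ValueError(f"need exactly two cohort labels, got {groups}")
            in_a = [labels[s] == groups[0] for s in samples]
            ka = sum(p for p, a in zip(present, in_a) if a)
            na = sum(in_a)
            kb = sum(p for p, a in zip(present, in_a) if not a)
            nb = len(samples) - na
            row["fisher_p"] = fisher_exact_2x2(
                ContingencyTable2x2(ka, na - ka, kb, nb - kb))
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["total_reads", "node_id"], ascending=[False, True], ignore_index=True)
    return out.head(top_n)


# ---------------------------------------------------------------------------
# File formats and optional alignment plumbing
# ---------------------------------------------------------------------------

def read_taxonomy_tsv(path: str | Path) -> TaxonomyTree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TaxonomyTree(df[["node_id", "parent_id", "rank", "name"]].itertuples(index=False))


def read_hit_table(path: str | Path) -> List[ReadAlignmentSummary]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "exo_genomes": str})
    out = []
    for r in df.itertuples():
        exo = () if pd.isna(r.exo_genomes) or r.exo_genomes == "" else tuple(
            str(r.exo_genomes).split(","))
        out.append(ReadAlignmentSummary(
            str(r.read_id), int(r.length), int(r.host_hits), int(r.host_min_mm),
            bool(r.repeat_flag) if not isinstance(r.repeat_flag, str)
            else r.repeat_flag.lower() in ("true", "1", "yes"),
            exo))
    return out


def summaries_from_sam(host_sam: str | Path, exo_sam: str | Path,
                       repeat_bed: str | Path | None = None) -> List[ReadAlignmentSummary]:
    """Build read summaries from host and exogenous SAM files (plumbing).

    Host hits are counted per read name with the minimum NM tag retained;
    exogenous hits keep only zero-NM alignments, recorded by reference name.
    ``repeat_bed`` marks reads whose host alignment overlaps a repeat region.
    """
    import pysam

    repeats: Dict[str, List[Tuple[int, int]]] = {}
    if repeat_bed is not None:
        bed = pd.read_csv(repeat_bed, sep="\t", header=None,
                          names=["chrom", "start", "end"], usecols=[0, 1, 2],
                          dtype={"chrom": str})
        for r in bed.itertuples():
            repeats.setdefault(r.chrom, []).append((int(r.start), int(r.end)))

    host: Dict[str, Dict] = {}
    with pysam.AlignmentFile(str(host_sam), "r", check_sq=False) as f:
        for aln in f:
            if aln.is_unmapped:
                host.setdefault(aln.query_name, {
                    "length": aln.query_length or 100, "hits": 0,
                    "min_mm": 0, "repeat": False})
                continue
            rec = host.setdefault(aln.query_name, {
                "length": aln.query_length or aln.infer_read_length() or 100,
                "hits": 0, "min_mm": None, "repeat": False})
            rec["hits"] += 1
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            rec["min_mm"] = nm if rec["min_mm"] is None else min(rec["min_mm"], nm)
            for start, end in repeats.get(aln.reference_name, ()):
                if aln.reference_start < end and start < (aln.reference_end or aln.reference_start + 1):
                    rec["repeat"] = True

    exo: Dict[str, List[str]] = {}
    with pysam.AlignmentFile(str(exo_sam), "r", check_sq=False) as f:
        for aln in f:
            if aln.is_unmapped:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            if nm == 0:  # the exogenous pass allows no mismatches
                exo.setdefault(aln.query_name, []).append(aln.reference_name)

    out = []
    for read_id in sorted(set(host) | set(exo)):
        h = host.get(read_id, {"length": 100, "hits": 0, "min_mm": 0, "repeat": False})
        out.append(ReadAlignmentSummary(
            read_id, int(h["length"]), int(h["hits"]),
            int(h["min_mm"] or 0), bool(h["repeat"]),
            tuple(sorted(set(exo.get(read_id, ()))))))
    return out
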