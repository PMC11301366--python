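"""Genomic enhancer clusters: single-linkage chaining of nearby enhancers.

Enhancers from the comprehensive set whose inner-edge distance is within
a gap (default 15 kb, the ``bedtools cluster -d`` semantics) chain
transitively into genomic enhancer clusters; genes are associated by
body overlap with the cluster interval extended by +/- 10 kb.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval
from .enhancers import EnhancerCandidate


@dataclass
class GenomicEnhancerCluster:
    id: str
    interval: GenomicInterval  # span from first to last member
    member_ids: List[str]
    gene_ids: List[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def chain_enhancers(
    enhancers: Sequence[EnhancerCandidate],
    gap: int = 15000,
    strict_gap: bool = False,
) -> List[GenomicEnhancerCluster]:
    """Transitive single-linkage chaining by inner-edge distance <= gap.

    ``strict_gap=True`` switches to < gap ("closer than").  Clusters
    never span chromosomes; singletons are clusters of size 1.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ordered = sorted(enhancers, key=lambda e: (e.region.chrom, e.region.start, e.id))
    clusters: List[GenomicEnhancerCluster] = []
    current: List[EnhancerCandidate] = []

    def flush() -> None:
        if not current:
            return
        start = min(e.region.start for e in current)
        end = max(e.region.end for e in current)
        clusters.append(
            GenomicEnhancerCluster(
                id=f"GEC{len(clusters) + 1:05d}",
                interval=GenomicInterval(current[0].region.chrom, start, end),
                member_ids=[e.id for e in current],
            )
        )
        current.clear()

    prev_end = None
    for e in ordered:
        if current and (
            e.region.chrom != current[-1].region.chrom
            or not _within(e.region.start - prev_end, gap, strict_gap)
        ):
            flush()
        current.append(e)
        prev_end = max(prev_end, e.region.end) if current[:-1] else e.region.end
    flush()
    return clusters


def _within(distance: int, gap: int, strict: bool) -> bool:
    # overlapping features (negative inner-edge distance) always chain
    return distance < gap if strict else distance <= gap


def cluster_size_profile(clusters: Sequence[GenomicEnhancerCluster]) -> dict:
    """Histogram of member counts, largest size and above-threshold query."""
    sizes = [c.size for c in clusters]
    hist = dict(sorted(Counter(sizes).items()))
    return {
        "histogram": hist,
        "largest": max(sizes) if sizes else 0,
        "n_clusters": len(sizes),
        "n_multi": sum(1 for s in sizes if s > 1),
        "above": lambda k: sum(1 for s in sizes if s > k),
    }


def associate_genes(
    clusters: Sequence[GenomicEnhancerCluster],
    genes: Sequence,
    margin: int = 10000,
) -> None:
    """Associate genes whose body overlaps the margin-extended cluster span."""
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.body.chrom, IntervalTree()).addi(g.body.start, g.body.end, g.gene_id)
    for c in clusters:
        tree = trees.get(c.interval.chrom)
        if tree is None:
            c.gene_ids = []
            continue
        ext = c.interval.expanded(margin)
        c.gene_ids = sorted({h.data for h in tree.overlap(ext.start, ext.end)})
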