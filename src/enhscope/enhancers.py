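"""Enhancer identification from balanced bidirectionally transcribed loci.

Active enhancers emit short, balanced, divergent eRNA; promoters are
strongly directional.  After masking annotated and top-expressed TCs,
divergent TC pairs within 450 bp are quantified in +/- 250 bp windows
around the pair midpoint, scored with the directionality score
D = (F - R) / (F + R), and loci with |D| below the exclusion bound are
kept as enhancer candidates.  Tag support across samples then assigns
nested confidence tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .core import CtssRecord, GenomicInterval
from .clustering import TagCluster

logger = logging.getLogger(__name__)


@dataclass
class EnhancerCandidate:
    """A divergent locus: midpoint, windowed expression and directionality."""

    id: str
    midpoint: int
    region: GenomicInterval  # unstranded [mid - flank, mid + flank)
    fwd_expr: float
    rev_expr: float
    per_sample_tags: np.ndarray  # fwd + rev window tags per sample
    D: float
    tier: str = "candidate"  # {candidate, comprehensive, robust, strict}
    novel: bool = False
    tpm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fwd_expr + self.rev_expr > 0 and not (-1.0 <= self.D <= 1.0):
            raise ValueError("D outside [-1, 1]")
        if not (self.region.start <= self.midpoint < self.region.end):
            raise ValueError("region must span the midpoint")

    @property
    def pooled(self) -> float:
        return self.fwd_expr + self.rev_expr


@dataclass
class MaskReport:
    n_annotation_masked: int
    n_top_expressed_masked: int
    retained_tc_ids: List[str]


@dataclass
class DivergentLocus:
    minus_tc: TagCluster
    plus_tc: TagCluster
    midpoint: int
    gap: int

    @property
    def chrom(self) -> str:
        return self.minus_tc.interval.chrom


def _exon_tss_trees(genes: Sequence, tss_margin: int) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.body.chrom, IntervalTree())
        for e in g.exons:
            tree.addi(e.start, e.end)
        if tss_margin > 0:
            for t in g.tss_list:
                tree.addi(max(0, t - tss_margin), t + tss_margin + 1)
    return trees


def mask_tcs(
    tcs: Sequence[TagCluster],
    genes: Sequence,
    top_n: int = 1000,
    tss_margin: int = 0,
) -> Tuple[List[TagCluster], MaskReport]:
    """Remove annotation-coinciding TCs, then the top-expressed remainder.

    Step 1 drops every TC overlapping (>= 1 bp) an annotated exon or
    lying within ``tss_margin`` bp of an annotated TSS; step 2 drops the
    ``top_n`` remaining TCs ranked by pooled TPM (ties broken by genomic
    order, lower coordinate ranked higher, i.e. masked first).
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    trees = _exon_tss_trees(genes, tss_margin)
    unmasked = []
    n_annot = 0
    for tc in tcs:
        tree = trees.get(tc.interval.chrom)
        if tree is not None and tree.overlap(tc.interval.start, tc.interval.end):
            n_annot += 1
        else:
            unmasked.append(tc)
    if top_n >= len(unmasked) and unmasked:
        logger.warning("top_n=%d masks all %d remaining TCs", top_n, len(unmasked))

    def expr_key(tc: TagCluster) -> float:
        return float(np.sum(tc.tpm)) if tc.tpm is not None else float(tc.pooled)

    ranked = sorted(
        unmasked,
        key=lambda t: (-expr_key(t), t.interval.chrom, t.interval.start),
    )
    top = set(id(t) for t in ranked[:top_n])
    retained = [t for t in unmasked if id(t) not in top]
    report = MaskReport(n_annot, min(top_n, len(unmasked)), [t.id for t in retained])
    return retained, report


def find_divergent_pairs(
    tcs: Sequence[TagCluster], max_separation: int = 450
) -> List[DivergentLocus]:
    """Pair divergent (-)/(+) TCs with inner-edge gap in [0, max_separation].

    A pair is a minus-strand TC followed left-to-right by a plus-strand
    TC (divergent orientation).  Pairing is one-to-one greedy by
    smallest gap, ties resolved to the leftmost pair.
    """
    by_chrom: Dict[str, Dict[str, list]] = {}
    for tc in tcs:
        by_chrom.setdefault(tc.interval.chrom, {"+": [], "-": []})[
            tc.interval.strand
        ].append(tc)
    candidates = []
    for chrom in sorted(by_chrom):
        plus = sorted(by_chrom[chrom]["+"], key=lambda t: t.interval.start)
        starts = np.array([t.interval.start for t in plus], dtype=np.int64)
        for m in by_chrom[chrom]["-"]:
            lo = np.searchsorted(starts, m.interval.end, side="left")
            hi = np.searchsorted(starts, m.interval.end + max_separation, side="right")
            for p in plus[lo:hi]:
                gap = p.interval.start - m.interval.end
                if 0 <= gap <= max_separation:
                    candidates.append((gap, chrom, m.interval.start, p.interval.start, m, p))
    candidates.sort(key=lambda c: c[:4])
    used = set()
    loci = []
    for gap, chrom, _, _, m, p in candidates:
        if id(m) in used or id(p) in used:
            continue
        used.add(id(m))
        used.add(id(p))
        loci.append(
            DivergentLocus(m, p, midpoint=(m.interval.end + p.interval.start) // 2, gap=gap)
        )
    loci.sort(key=lambda l: (l.chrom, l.midpoint))
    return loci


class CtssIndex:
    """Per (chrom, strand) sorted position arrays for fast window sums."""

    def __init__(self, records: Sequence[CtssRecord]):
        groups: Dict[Tuple[str, str], list] = {}
        for r in records:
            groups.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
        self._pos: Dict[Tuple[str, str], np.ndarray] = {}
        self._counts: Dict[Tuple[str, str], np.ndarray] = {}
        self.n_samples = len(records[0].counts) if records else 0
        for key, recs in groups.items():
            recs.sort(key=lambda r: r.pos)
            self._pos[key] = np.array([r.pos for r in recs], dtype=np.int64)
            self._counts[key] = np.stack([r.counts for r in recs])

    def window_counts(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Per-sample tag sums over positions in half-open [start, end)."""
        key = (chrom, strand)
        if key not in self._pos:
            return np.zeros(self.n_samples, dtype=np.int64)
        pos = self._pos[key]
        lo, hi = np.searchsorted(pos, [start, end])
        return self._counts[key][lo:hi].sum(axis=0)


def quantify_and_score(
    loci: Sequence[DivergentLocus],
    ctss: Sequence[CtssRecord] | CtssIndex,
    flank: int = 250,
) -> List[EnhancerCandidate]:
    """Quantify divergent loci in +/- flank windows and score directionality.

    Forward window [mid, mid + flank) counts plus-strand tags; reverse
    window [mid - flank, mid) counts minus-strand tags; both pooled over
    samples.  D = (F - R) / (F + R); loci with F + R = 0 are dropped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    index = ctss if isinstance(ctss, CtssIndex) else CtssIndex(ctss)
    out = []
    for locus in loci:
        mid = locus.midpoint
        fwd = index.window_counts(locus.chrom, "+", mid, mid + flank)
        rev = index.window_counts(locus.chrom, "-", max(0, mid - flank), mid)
        F, R = float(fwd.sum()), float(rev.sum())
        if F + R == 0:
            continue
        out.append(
            EnhancerCandidate(
                id="",
                midpoint=mid,
                region=GenomicInterval(locus.chrom, max(0, mid - flank), mid + flank),
                fwd_expr=F,
                rev_expr=R,
                per_sample_tags=(fwd + rev).astype(np.int64),
                D=(F - R) / (F + R),
            )
        )
    for k, e in enumerate(out, 1):
        e.id = f"ENH{k:05d}"
    return out


def filter_balanced(
    loci: Sequence[EnhancerCandidate], d_threshold: float = 0.9
) -> List[EnhancerCandidate]:
    """Keep balanced loci: |D| < d_threshold; directional loci are excluded."""
    if not (0 < d_threshold <= 1):
        raise ValueError("d_threshold must be in (0, 1]")
    return [e for e in loci if abs(e.D) < d_threshold]


def assign_enhancer_tiers(
    candidates: Sequence[EnhancerCandidate],
    n_samples_robust: int = 6,
    min_tags: int = 2,
) -> List[EnhancerCandidate]:
    """Assign nested support tiers from per-sample window tag totals.

    comprehensive: >= min_tags tags in >= 1 sample; robust: in >=
    n_samples_robust samples; strict: in every sample.
    """
    for e in candidates:
        supported = int((e.per_sample_tags >= min_tags).sum())
        n = len(e.per_sample_tags)
        if supported >= n and n > 0:
            e.tier = "strict"
        elif supported >= n_samples_robust:
            e.tier = "robust"
        elif supported >= 1:
            e.tier = "comprehensive"
        else:
            e.tier = "candidate"
    return list(candidates)


TIER_ORDER = {"candidate": 0, "comprehensive": 1, "robust": 2, "strict": 3}


def tier_at_least(e: EnhancerCandidate, tier: str) -> bool:
    return TIER_ORDER[e.tier] >= TIER_ORDER[tier]


def support_overlap(
    enhancers: Sequence[EnhancerCandidate],
    reference_sets: Dict[str, Sequence[GenomicInterval]],
    novel_reference: Optional[str] = None,
) -> Dict[str, dict]:
    """Count enhancers overlapping (>= 1 bp) each named reference set.

    Returns per-set {"count", "percent"}; when ``novel_reference`` names
    one of the sets, each enhancer's ``novel`` flag is set to True when
    it does not overlap that set.
    """
    result = {}
    n = len(enhancers)
    for name, intervals in reference_sets.items():
        if not intervals:
            logger.warning("reference set %r is empty", name)
        trees: Dict[str, IntervalTree] = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        hits = []
        for e in enhancers:
            tree = trees.get(e.region.chrom)
            hit = bool(tree is not None and tree.overlap(e.region.start, e.region.end))
            hits.append(hit)
            if name == novel_reference:
                e.novel = not hit
        count = int(sum(hits))
        result[name] = {"count": count, "percent": 100.0 * count / n if n else 0.0}
    return result
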