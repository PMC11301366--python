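"""Strand-specific tag clustering of CTSS positions, TPM scaling and tiers.

The clustering is the density-based recursive segmentation of Paraclu:
for the pooled (sample-summed) tag counts on one chromosome strand it
enumerates the laminar family of site intervals that are each maximal
for some density threshold.  A block of sites i..j breaks before site k
at the density of the weaker flanking block, where a block's density is
its pooled tags divided by the genomic distance to the break point
(tags(i..k-1) / (pos_k - pos_i) for the prefix side and symmetrically
for the suffix side); the smallest such break density over all k is the
maximal density the interval sustains, and the density inherited from
the enclosing interval at which it became separate is its minimal
sustaining density.  Clusters are then filtered on stability (max/min
density ratio), bp length and pooled tag count, and nested survivors
are resolved to the outermost one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CountMatrix, CtssRecord, GenomicInterval

logger = logging.getLogger(__name__)

INF = math.inf


@dataclass
class TagCluster:
    """A strand-specific tag cluster (TC): one promoter-scale unit."""

    id: str
    interval: GenomicInterval
    summit: int
    counts: np.ndarray  # per-sample raw tags
    tpm: Optional[np.ndarray] = None  # per-sample TPM, aggregated from CTSS TPM
    tier: str = "none"  # {"comprehensive", "robust", "none"}
    gene_id: Optional[str] = None
    min_density: float = 0.0
    max_density: float = INF

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside cluster interval")
        if self.min_density > self.max_density:
            raise ValueError("min_density exceeds max_density")

    @property
    def pooled(self) -> int:
        return int(self.counts.sum())


def _weakest_break(
    pos: np.ndarray, cum: np.ndarray, i: int, j: int
) -> Tuple[float, int]:
    """Weakest break point of sites i..j: returns (density, k).

    A break before site k (i < k <= j) severs the interval into blocks
    i..k-1 and k..j; its density is the weaker of the two flanking block
    densities, tags / distance-to-break.  The minimum over k is the
    density at which the interval splits; ties resolve to the leftmost
    break, so equal-density maximal intervals prefer the longer,
    leftmost survivor.
    """
    pre = (cum[i + 1 : j + 1] - cum[i]) / (pos[i + 1 : j + 1] - pos[i])
    suf = (cum[j + 1] - cum[i + 1 : j + 1]) / (pos[j] - pos[i:j])
    per_break = np.minimum(pre, suf)
    k_off = int(np.argmin(per_break))
    return float(per_break[k_off]), i + 1 + k_off


def paraclu_family(
    positions: Sequence[int], values: Sequence[float]
) -> List[Tuple[int, int, float, float, float]]:
    """Enumerate all density-maximal site intervals for one chrom/strand.

    Returns tuples ``(i, j, min_density, max_density, total)`` over
    inclusive site-index ranges.  ``min_density`` is the lowest density
    threshold at which the interval is the maximal interval sustaining
    that density, ``max_density`` the density at which it breaks apart
    (inf for single sites).
    """
    pos = np.asarray(positions, dtype=np.int64)
    val = np.asarray(values, dtype=float)
    n = len(pos)
    if n == 0:
        return []
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    cum = np.concatenate([[0.0], np.cumsum(val)])
    out: List[Tuple[int, int, float, float, float]] = []
    stack = [(0, n - 1, 0.0)]
    while stack:
        i, j, min_d = stack.pop()
        if i == j:
            out.append((i, j, min_d, INF, float(val[i])))
            continue
        break_d, k = _weakest_break(pos, cum, i, j)
        if break_d > min_d:
            out.append((i, j, min_d, break_d, float(cum[j + 1] - cum[i])))
        new_min = max(min_d, break_d)
        stack.append((i, k - 1, new_min))
        stack.append((k, j, new_min))
    return out


def filter_family(
    family: List[Tuple[int, int, float, float, float]],
    positions: Sequence[int],
    min_stability: float,
    max_length: int,
    min_tags: float,
) -> List[Tuple[int, int, float, float, float]]:
    """Apply stability/length/tag filters and keep outermost survivors.

    The family is laminar, so overlapping survivors are nested; a
    survivor strictly contained in another survivor is dropped.
    """
    pos = np.asarray(positions, dtype=np.int64)
    passing = []
    for i, j, min_d, max_d, total in family:
        length = pos[j] - pos[i] + 1
        stable = max_d >= min_stability * min_d  # min_d == 0 always passes
        if stable and length <= max_length and total >= min_tags:
            passing.append((i, j, min_d, max_d, total))
    # outermost: drop any cluster nested inside another passing cluster
    kept = []
    for c in passing:
        if not any(
            (o[0] <= c[0] and c[1] <= o[1] and (o[0], o[1]) != (c[0], c[1]))
            for o in passing
        ):
            kept.append(c)
    kept.sort(key=lambda c: c[0])
    return kept


def _group_ctss(records: Sequence[CtssRecord]) -> Dict[Tuple[str, str], list]:
    groups: Dict[Tuple[str, str], list] = {}
    for r in records:
        groups.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
    for key in groups:
        groups[key].sort(key=lambda r: r.pos)
    return groups


def paraclu_cluster(
    records: Sequence[CtssRecord],
    min_stability: float = 2.0,
    max_length: int = 200,
    min_tags: int = 3,
) -> List[TagCluster]:
    """Cluster CTSS records into tag clusters on pooled counts.

    Pooling over samples gives one consensus TC set for the cohort;
    the per-sample count vectors of a TC are the sums of its member
    CTSS counts.  Zero-count positions are ignored.
    """
    if min_stability <= 0:
        raise ValueError("min_stability must be positive")
    clusters: List[TagCluster] = []
    for (chrom, strand), recs in sorted(_group_ctss(records).items()):
        recs = [r for r in recs if r.counts.sum() > 0]
        if not recs:
            continue
        pos = np.array([r.pos for r in recs], dtype=np.int64)
        counts = np.stack([r.counts for r in recs])  # sites x samples
        pooled = counts.sum(axis=1).astype(float)
        family = paraclu_family(pos, pooled)
        kept = filter_family(family, pos, min_stability, max_length, min_tags)
        for i, j, min_d, max_d, total in kept:
            member_counts = counts[i : j + 1]
            summit_off = int(np.argmax(pooled[i : j + 1]))  # ties -> leftmost
            clusters.append(
                TagCluster(
                    id="",
                    interval=GenomicInterval(chrom, int(pos[i]), int(pos[j]) + 1, strand),
                    summit=int(pos[i + summit_off]),
                    counts=member_counts.sum(axis=0),
                    min_density=min_d,
                    max_density=max_d,
                )
            )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.strand))
    for k, tc in enumerate(clusters, 1):
        tc.id = f"TC{k:06d}"
    return clusters


def tpm_normalize(m: CountMatrix, totals: Optional[np.ndarray] = None) -> CountMatrix:
    """Scale raw tags to tags-per-million per sample.

    ``totals`` defaults to the column sums of ``m`` (all features of the
    sample); pass library sizes to normalise a feature subset against
    full sample totals.  All-zero columns stay zero.
    """
    if m.scale != "raw":
        raise ValueError("input matrix must be raw counts")
    if (m.values < 0).any():
        raise ValueError("negative counts")
    colsum = m.values.sum(axis=0) if totals is None else np.asarray(totals, dtype=float)
    if (colsum < 0).any():
        raise ValueError("negative totals")
    safe = np.where(colsum > 0, colsum, 1.0)
    vals = 1e6 * m.values / safe
    return CountMatrix(list(m.feature_ids), list(m.sample_ids), vals, scale="tpm")


def tier_tag_clusters(
    tcs: Sequence[TagCluster],
    tpm: Optional[CountMatrix] = None,
    comprehensive_tpm: float = 1.0,
    robust_tpm: float = 3.0,
    robust_rule: str = "all_samples",
) -> List[str]:
    """Label TCs comprehensive / robust / none from their TPM profiles.

    comprehensive: >= ``comprehensive_tpm`` in at least one sample.
    robust: >= ``robust_tpm`` in every sample (``robust_rule =
    "all_samples"``) or in the cross-sample mean (``"mean"``); robust
    TCs are comprehensive by construction of the thresholds.
    """
    if robust_rule not in ("all_samples", "mean"):
        raise ValueError(f"unknown robust_rule {robust_rule!r}")
    labels = []
    for tc in tcs:
        v = tc.tpm if tpm is None else tpm.row(tc.id)
        if v is None:
            raise ValueError(f"TC {tc.id} has no TPM vector")
        v = np.asarray(v, dtype=float)
        if robust_rule == "all_samples":
            robust = bool(v.min() >= robust_tpm)
        else:
            robust = bool(v.mean() >= robust_tpm)
        comp = bool(v.max() >= comprehensive_tpm)
        tier = "robust" if (robust and comp) else ("comprehensive" if comp else "none")
        tc.tier = tier
        labels.append(tier)
    return labels


def annotate_tcs(tcs: Sequence[TagCluster], genes: Sequence) -> None:
    """Assign each TC the gene whose body it overlaps (>= 1 bp, strand-agnostic).

    Multiple overlapping genes resolve to the one whose nearest
    transcript TSS is closest to the TC summit; no overlap leaves the TC
    unannotated.
    """
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.body.chrom, IntervalTree()).addi(g.body.start, g.body.end, g)
    for tc in tcs:
        tree = trees.get(tc.interval.chrom)
        if tree is None:
            tc.gene_id = None
            continue
        hits = tree.overlap(tc.interval.start, tc.interval.end)
        if not hits:
            tc.gene_id = None
            continue
        best = min(
            (h.data for h in hits),
            key=lambda g: (min(abs(t - tc.summit) for t in g.tss_list), g.gene_id),
        )
        tc.gene_id = best.gene_id
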