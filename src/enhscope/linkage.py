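"""TAD-constrained enhancer-promoter linkage by expression correlation.

Candidate pairs are a comprehensive promoter TC and a robust enhancer
within 2 Mb that are fully contained in a common TAD.  Each pair is
scored by the Pearson correlation of TPM profiles across samples;
retention is one-sided (r >= 0.5).  Bonferroni-adjusted p-values over
the number of scored pairs are reported but not used for retention.
PCHi-C interaction sets annotate pairs whose two anchors overlap the
enhancer and the promoter respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GenomicInterval, InteractionPair, Tad
from .clustering import TagCluster
from .enhancers import EnhancerCandidate

logger = logging.getLogger(__name__)


@dataclass
class LinkageCandidate:
    enhancer_id: str
    tc_id: str
    gene_id: Optional[str]
    distance: int  # enhancer midpoint <-> TC summit
    same_tad: bool = True
    r: float = float("nan")
    p: float = float("nan")
    p_adj: float = float("nan")
    retained: bool = False
    pchic_support: Dict[str, bool] = field(default_factory=dict)


def candidate_pairs(
    promoter_tcs: Sequence[TagCluster],
    enhancers: Sequence[EnhancerCandidate],
    tads: Sequence[Tad],
    max_dist: int = 2_000_000,
    tad_mode: str = "contained",
) -> List[LinkageCandidate]:
    """Enumerate (enhancer, promoter TC) pairs within ``max_dist`` sharing a TAD.

    ``tad_mode="contained"`` requires both features fully inside a common
    TAD; ``"midpoint"`` requires only both midpoints inside one.  A pair
    is kept if ANY provided TAD contains both.
    """
    if tad_mode not in ("contained", "midpoint"):
        raise ValueError(f"unknown tad_mode {tad_mode!r}")
    trees: Dict[str, IntervalTree] = {}
    for t in tads:
        trees.setdefault(t.interval.chrom, IntervalTree()).addi(
            t.interval.start, t.interval.end, t
        )

    def tads_of(iv: GenomicInterval) -> set:
        tree = trees.get(iv.chrom)
        if tree is None:
            return set()
        if tad_mode == "midpoint":
            mid = (iv.start + iv.end) // 2
            return {id(h.data) for h in tree.at(mid)}
        return {
            id(h.data)
            for h in tree.overlap(iv.start, iv.end)
            if h.data.interval.contains(iv)
        }

    pairs = []
    tc_by_chrom: Dict[str, list] = {}
    for tc in promoter_tcs:
        tc_by_chrom.setdefault(tc.interval.chrom, []).append(tc)
    for e in enhancers:
        e_tads = tads_of(e.region)
        if not e_tads:
            continue
        for tc in tc_by_chrom.get(e.region.chrom, []):
            dist = abs(e.midpoint - tc.summit)
            if dist > max_dist:
                continue
            if not (e_tads & tads_of(tc.interval)):
                continue
            pairs.append(
                LinkageCandidate(
                    enhancer_id=e.id,
                    tc_id=tc.id,
                    gene_id=tc.gene_id,
                    distance=int(dist),
                )
            )
    pairs.sort(key=lambda c: (c.enhancer_id, c.tc_id))
    return pairs


def pearson_linkage(
    pairs: Sequence[LinkageCandidate],
    enhancer_tpm: Dict[str, np.ndarray],
    tc_tpm: Dict[str, np.ndarray],
    r_threshold: float = 0.5,
) -> List[LinkageCandidate]:
    """Score candidate pairs by Pearson correlation of TPM profiles.

    p is the two-sided test with n - 2 degrees of freedom; p_adj is the
    Bonferroni adjustment over the number of scored pairs (m); retention
    is r >= r_threshold only (positive correlation, one-sided).
    Zero-variance profiles are excluded with a logged reason.
    """
    scored = []
    for c in pairs:
        x = np.asarray(enhancer_tpm[c.enhancer_id], dtype=float)
        y = np.asarray(tc_tpm[c.tc_id], dtype=float)
        if len(x) != len(y):
            raise ValueError("profiles must share the sample axis")
        if len(x) < 3:
            raise ValueError("need at least 3 samples for the correlation test")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.info(
                "excluding pair (%s, %s): zero-variance profile", c.enhancer_id, c.tc_id
            )
            continue
        res = stats.pearsonr(x, y)
        c.r, c.p = float(res.statistic), float(res.pvalue)
        scored.append(c)
    m = len(scored)
    logger.info("Bonferroni m = %d scored pairs", m)
    for c in scored:
        c.p_adj = min(1.0, m * c.p)
        c.retained = c.r >= r_threshold
    return scored


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r with n - 2 degrees of freedom."""
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def annotate_pchic(
    candidates: Sequence[LinkageCandidate],
    interaction_sets: Dict[str, Sequence[InteractionPair]],
    enhancers: Dict[str, EnhancerCandidate],
    tcs: Dict[str, TagCluster],
) -> None:
    """Flag pairs supported by chromatin interactions.

    A set supports a pair when one anchor overlaps the enhancer region
    and the other overlaps the promoter TC (>= 1 bp each, either anchor
    assignment); both anchors on the same feature do not count.
    """
    for name, pairs in interaction_sets.items():
        trees: Dict[str, IntervalTree] = {}
        for k, ip in enumerate(pairs):
            for which, anchor in (("a", ip.anchor_a), ("b", ip.anchor_b)):
                trees.setdefault(anchor.chrom, IntervalTree()).addi(
                    anchor.start, anchor.end, (k, which)
                )
        for c in candidates:
            e, tc = enhancers[c.enhancer_id], tcs[c.tc_id]
            tree_e = trees.get(e.region.chrom)
            tree_t = trees.get(tc.interval.chrom)
            hits_e = set()
            if tree_e is not None:
                hits_e = {h.data for h in tree_e.overlap(e.region.start, e.region.end)}
            hits_t = set()
            if tree_t is not None:
                hits_t = {h.data for h in tree_t.overlap(tc.interval.start, tc.interval.end)}
            supported = any(
                ((k, "a") in hits_e and (k, "b") in hits_t)
                or ((k, "b") in hits_e and (k, "a") in hits_t)
                for k, _ in hits_e | hits_t
            )
            c.pchic_support[name] = supported


def linkage_summary(
    candidates: Sequence[LinkageCandidate],
    clusters: Sequence = (),
    enhancers: Optional[Dict[str, EnhancerCandidate]] = None,
    snp_hits: Sequence = (),
    snps: Sequence = (),
) -> pd.DataFrame:
    """Cross-tabulate retained pairs: PCHi-C support, cluster membership,
    novel enhancers and SNP-hit enhancers per trait."""
    retained = [c for c in candidates if c.retained]
    rows = [{"category": "retained_pairs", "count": len(retained)}]
    set_names = sorted({k for c in candidates for k in c.pchic_support})
    for name in set_names:
        rows.append(
            {
                "category": f"pchic_{name}",
                "count": sum(1 for c in retained if c.pchic_support.get(name)),
            }
        )
    clustered_ids = set()
    for cl in clusters:
        if cl.size > 1:
            clustered_ids.update(cl.member_ids)
    rows.append(
        {
            "category": "enhancers_in_genomic_clusters",
            "count": len({c.enhancer_id for c in retained} & clustered_ids),
        }
    )
    if enhancers is not None:
        rows.append(
            {
                "category": "novel_enhancers",
                "count": len(
                    {c.enhancer_id for c in retained if enhancers[c.enhancer_id].novel}
                ),
            }
        )
    if snp_hits:
        trait_of: Dict[str, set] = {}
        for s in snps:
            trait_of.setdefault(s.rsid, set()).add(s.trait)
        enh_traits: Dict[str, set] = {}
        for h in snp_hits:
            enh_traits.setdefault(h.enhancer_id, set()).update(trait_of.get(h.rsid, set()))
        traits = sorted({t for ts in enh_traits.values() for t in ts})
        retained_enh = {c.enhancer_id for c in retained}
        for t in traits:
            rows.append(
                {
                    "category": f"snp_hit_enhancers_{t}",
                    "count": sum(
                        1 for e, ts in enh_traits.items() if t in ts and e in retained_enh
                    ),
                }
            )
    return pd.DataFrame(rows)
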