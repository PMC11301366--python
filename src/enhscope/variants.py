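"""GWAS SNP x enhancer intersection and per-trait summaries.

Two modes: exact (SNP position inside the enhancer region) and window
(enhancer within +/- 1 kb of the SNP).  Each (SNP, enhancer) pair is
reported once with the stronger mode; trait summaries count unique SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import SnpRecord
from .enhancers import EnhancerCandidate


@dataclass(frozen=True)
class SnpEnhancerHit:
    rsid: str
    enhancer_id: str
    mode: str  # {"exact", "window"}
    distance: int  # 0 for exact; else bp from SNP to nearest enhancer edge

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "window"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mode == "exact" and self.distance != 0:
            raise ValueError("exact hits have distance 0")
        if self.mode == "window" and self.distance <= 0:
            raise ValueError("window hits have positive distance")


def intersect_snps(
    snps: Sequence[SnpRecord],
    enhancers: Sequence[EnhancerCandidate],
    window: int = 1000,
) -> List[SnpEnhancerHit]:
    """Intersect SNPs with enhancer regions in exact and window modes.

    Exact: SNP position in [start, end).  Window: the enhancer overlaps
    the symmetric window [pos - window, pos + window + 1) but misses the
    SNP itself; distance is from the SNP to the nearest enhancer edge.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    trees: Dict[str, IntervalTree] = {}
    for e in enhancers:
        trees.setdefault(e.region.chrom, IntervalTree()).addi(
            e.region.start, e.region.end, e
        )
    # deduplicate identical (rsid, trait-independent) positions per rsid
    hits: List[SnpEnhancerHit] = []
    seen = set()
    for s in snps:
        tree = trees.get(s.position.chrom)
        if tree is None:
            continue
        pos = s.position.start
        for h in tree.overlap(max(0, pos - window), pos + window + 1):
            e = h.data
            key = (s.rsid, e.id)
            if key in seen:
                continue
            seen.add(key)
            if e.region.start <= pos < e.region.end:
                hits.append(SnpEnhancerHit(s.rsid, e.id, "exact", 0))
            else:
                dist = e.region.start - pos if pos < e.region.start else pos - (e.region.end - 1)
                hits.append(SnpEnhancerHit(s.rsid, e.id, "window", int(dist)))
    hits.sort(key=lambda h: (h.rsid, h.enhancer_id))
    return hits


def summarize_by_trait(
    hits: Sequence[SnpEnhancerHit], snps: Sequence[SnpRecord]
) -> pd.DataFrame:
    """Per-trait counts of unique SNPs hitting enhancers, plus a unique total.

    A SNP with both exact and window evidence counts once, as exact.
    A SNP listed under several traits appears in each trait row but only
    once in the unique-total row (deduplicated by rsid).
    """
    best: Dict[str, str] = {}
    for h in hits:
        if h.mode == "exact" or best.get(h.rsid) is None:
            best[h.rsid] = h.mode if best.get(h.rsid) != "exact" else "exact"
    rows = []
    traits = sorted({s.trait for s in snps})
    for trait in traits + ["__total__"]:
        sel = [s for s in snps if s.trait == trait] if trait != "__total__" else list(snps)
        lead = {s.rsid for s in sel if s.role == "lead"}
        ld = {s.rsid for s in sel if s.role == "ld"}
        row = {
            "trait": "unique_total" if trait == "__total__" else trait,
            "n_lead": len(lead),
            "n_ld": len(ld),
            "exact_lead": sum(1 for r in lead if best.get(r) == "exact"),
            "window_lead": sum(1 for r in lead if best.get(r) == "window"),
            "exact_ld": sum(1 for r in ld if best.get(r) == "exact"),
            "window_ld": sum(1 for r in ld if best.get(r) == "window"),
        }
        row["any_lead"] = row["exact_lead"] + row["window_lead"]
        row["any_ld"] = row["exact_ld"] + row["window_ld"]
        rows.append(row)
    return pd.DataFrame(rows)


def snps_in_clusters(
    hits: Sequence[SnpEnhancerHit], clusters: Sequence
) -> Optional[dict]:
    """Fraction of SNP-hit enhancers that are members of genomic clusters
    with more than one enhancer.  Returns None when no enhancer was hit.
    """
    hit_ids = {h.enhancer_id for h in hits}
    if not hit_ids:
        return None
    clustered = set()
    for c in clusters:
        if c.size > 1:
            clustered.update(c.member_ids)
    num = len(hit_ids & clustered)
    return {"numerator": num, "denominator": len(hit_ids), "fraction": num / len(hit_ids)}
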