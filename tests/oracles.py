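"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (exhaustive enumeration, O(n^2) or
worse) and shares no code with the package's algorithms.
"""

from __future__ import annotations

from math import inf
from typing import List, Sequence, Tuple

import numpy as np


def break_density(pos, val, i: int, j: int) -> float:
    """Density at which site interval i..j splits: the minimum over break
    points k of the weaker flanking block density (tags / distance to the
    break).  Singletons never split (inf)."""
    if i == j:
        return inf
    cum = np.concatenate([[0.0], np.cumsum(val)])
    best = inf
    for k in range(i + 1, j + 1):
        d_pre = (cum[k] - cum[i]) / (pos[k] - pos[i])
        d_suf = (cum[j + 1] - cum[k]) / (pos[j] - pos[k - 1])
        best = min(best, d_pre, d_suf)
    return best


def paraclu_family_oracle(pos, val) -> List[Tuple[int, int, float, float, float]]:
    """All density-maximal site intervals by exhaustive maximality testing.

    An interval is in the family when the density it sustains exceeds the
    densities sustained by every enclosing interval; its minimal
    sustaining density is the best an enclosing interval achieves.
    """
    pos = np.asarray(pos)
    val = np.asarray(val, dtype=float)
    n = len(pos)
    bd = {}
    for i in range(n):
        for j in range(i, n):
            bd[(i, j)] = break_density(pos, val, i, j)
    family = []
    for (i, j), b in bd.items():
        enclosing = [
            bd[(a, c)]
            for a in range(0, i + 1)
            for c in range(j, n)
            if (a, c) != (i, j)
        ]
        min_d = max(enclosing, default=0.0)
        if b > min_d:
            family.append((i, j, min_d, b, float(val[i : j + 1].sum())))
    return sorted(family)


def paraclu_clusters_oracle(pos, val, min_stability, max_length, min_tags):
    """Filtered, outermost clusters from the exhaustive family."""
    fam = paraclu_family_oracle(pos, val)
    passing = [
        (i, j, mn, mx, tot)
        for (i, j, mn, mx, tot) in fam
        if mx >= min_stability * mn and pos[j] - pos[i] + 1 <= max_length and tot >= min_tags
    ]
    outer = [
        c
        for c in passing
        if not any(
            o[0] <= c[0] and c[1] <= o[1] and (o[0], o[1]) != (c[0], c[1])
            for o in passing
        )
    ]
    return sorted(outer)


def overlap_count_oracle(queries, references) -> int:
    """All-pairs >=1 bp half-open overlap count of query intervals."""
    n = 0
    for q in queries:
        for r in references:
            if q.chrom == r.chrom and q.start < r.end and r.start < q.end:
                n += 1
                break
    return n


def chain_components_oracle(regions, gap: int) -> List[frozenset]:
    """Connected components of the <=gap inner-edge-distance graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(regions)))
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            ra, rb = regions[a], regions[b]
            if ra.chrom != rb.chrom:
                continue
            dist = max(rb.start - ra.end, ra.start - rb.end)
            if dist <= gap:
                g.add_edge(a, b)
    return sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )


def snp_hits_oracle(snps, enhancers, window: int):
    """All-pairs SNP/enhancer scan returning {(rsid, enh_id): mode}."""
    hits = {}
    for s in snps:
        p = s.position.start
        for e in enhancers:
            if e.region.chrom != s.position.chrom:
                continue
            if e.region.start <= p < e.region.end:
                hits[(s.rsid, e.id)] = "exact"
            elif e.region.start < p + window + 1 and p - window < e.region.end:
                hits.setdefault((s.rsid, e.id), "window")
    return hits


def pchic_support_oracle(enh_region, tc_interval, pairs) -> bool:
    """Does any interaction place one anchor on each feature?"""

    def hits(anchor, iv):
        return anchor.chrom == iv.chrom and anchor.start < iv.end and iv.start < anchor.end

    return any(
        (hits(p.anchor_a, enh_region) and hits(p.anchor_b, tc_interval))
        or (hits(p.anchor_b, enh_region) and hits(p.anchor_a, tc_interval))
        for p in pairs
    )


def pearson_oracle(x, y) -> float:
    """Pearson r from the covariance / sigma product definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
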