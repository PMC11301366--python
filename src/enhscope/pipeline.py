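"""End-to-end orchestration: one config, staged execution, manifest.

The pipeline is a pure function of (inputs, config): tag clustering ->
TPM -> tiers -> gene annotation -> masking -> divergent pairing ->
windowed quantification -> balance filter -> enhancer tiers -> genomic
enhancer clusters -> SNP intersection -> TAD-constrained correlation
linkage -> PCHi-C annotation -> summaries.  ``run_all`` reads inputs
from files, writes every stage artifact plus a provenance manifest, and
reproduces identical outputs on identical inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .core import CountMatrix, CtssRecord, SnpRecord, Tad
from .clustering import TagCluster, annotate_tcs, paraclu_cluster, tier_tag_clusters
from .enhancers import (
    CtssIndex,
    EnhancerCandidate,
    MaskReport,
    assign_enhancer_tiers,
    filter_balanced,
    find_divergent_pairs,
    mask_tcs,
    quantify_and_score,
    support_overlap,
    tier_at_least,
)
from .clusters import GenomicEnhancerCluster, associate_genes, chain_enhancers, cluster_size_profile
from .variants import SnpEnhancerHit, intersect_snps, snps_in_clusters, summarize_by_trait
from .linkage import LinkageCandidate, annotate_pchic, candidate_pairs, linkage_summary, pearson_linkage
from . import io

logger = logging.getLogger(__name__)

# top-expressed masking proportion of the reference study (1,000 of the
# 78,176-TC catalogue); used when top_mask="scaled"
SCALED_MASK_RATIO = 1000 / 78176


@dataclass
class PipelineConfig:
    # inputs
    ctss_dir: Optional[str] = None
    gtf: Optional[str] = None
    tads: Optional[str] = None
    snps: Optional[str] = None
    pchic: Dict[str, str] = field(default_factory=dict)
    reference_sets: Dict[str, str] = field(default_factory=dict)
    novel_reference: Optional[str] = None
    tcs_meta: Optional[str] = None  # precomputed TCs bypass tag clustering
    tcs_counts: Optional[str] = None
    out_dir: Optional[str] = None
    # tag clustering
    min_stability: float = 2.0
    max_length: int = 200
    min_tags: int = 3
    comprehensive_tpm: float = 1.0
    robust_tpm: float = 3.0
    robust_rule: str = "all_samples"
    # enhancer calling
    flank: int = 250
    max_sep: int = 450
    d_threshold: float = 0.9
    top_mask: Union[int, str] = 1000  # int or "scaled"
    tss_margin: int = 0
    robust_n: int = 6
    enhancer_min_tags: int = 2
    # clusters / SNPs / linkage
    chain_gap: int = 15000
    strict_gap: bool = False
    cluster_margin: int = 10000
    snp_window: int = 1000
    max_dist: int = 2_000_000
    r_min: float = 0.5
    tad_mode: str = "contained"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    sample_ids: List[str]
    library_sizes: np.ndarray
    tcs: List[TagCluster]
    mask_report: Optional[MaskReport]
    enhancers: List[EnhancerCandidate]  # tiered (>= comprehensive) calls
    clusters: List[GenomicEnhancerCluster]
    snp_hits: List[SnpEnhancerHit]
    snp_summary: Optional[pd.DataFrame]
    links: List[LinkageCandidate]
    link_summary: Optional[pd.DataFrame]
    support: Optional[dict] = None
    stage_counts: Dict[str, int] = field(default_factory=dict)


def resolve_top_mask(top_mask: Union[int, str], n_unmasked: int) -> int:
    if top_mask == "scaled":
        return int(round(SCALED_MASK_RATIO * n_unmasked))
    return int(top_mask)


def run_pipeline(
    ctss: Sequence[CtssRecord],
    sample_ids: Sequence[str],
    genes: Sequence,
    config: PipelineConfig,
    tads: Sequence[Tad] = (),
    snps: Sequence[SnpRecord] = (),
    pchic_sets: Optional[Dict[str, list]] = None,
    reference_sets: Optional[Dict[str, list]] = None,
    tcs: Optional[List[TagCluster]] = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``tcs`` bypasses tag clustering with a precomputed TC set (which must
    carry counts aligned to ``sample_ids``).
    """
    cfg = config
    counts_all = np.stack([r.counts for r in ctss]) if len(ctss) else np.zeros((0, len(sample_ids)))
    library_sizes = counts_all.sum(axis=0).astype(float)
    stage_counts: Dict[str, int] = {"ctss_positions": len(ctss)}

    # --- tag clustering, TPM, tiers, annotation
    if tcs is None:
        tcs = paraclu_cluster(
            ctss, min_stability=cfg.min_stability, max_length=cfg.max_length,
            min_tags=cfg.min_tags,
        )
    safe_lib = np.where(library_sizes > 0, library_sizes, 1.0)
    for tc in tcs:
        if tc.tpm is None:
            tc.tpm = 1e6 * tc.counts / safe_lib
    tier_tag_clusters(
        tcs, comprehensive_tpm=cfg.comprehensive_tpm, robust_tpm=cfg.robust_tpm,
        robust_rule=cfg.robust_rule,
    )
    annotate_tcs(tcs, genes)
    stage_counts["tag_clusters"] = len(tcs)
    stage_counts["tc_comprehensive"] = sum(1 for t in tcs if t.tier in ("comprehensive", "robust"))
    stage_counts["tc_robust"] = sum(1 for t in tcs if t.tier == "robust")

    # --- masking and enhancer calling
    retained, report = mask_tcs(
        tcs, genes,
        top_n=resolve_top_mask(cfg.top_mask, _n_unmasked(tcs, genes, cfg.tss_margin)),
        tss_margin=cfg.tss_margin,
    )
    loci = find_divergent_pairs(retained, max_separation=cfg.max_sep)
    index = CtssIndex(ctss)
    scored = quantify_and_score(loci, index, flank=cfg.flank)
    balanced = filter_balanced(scored, d_threshold=cfg.d_threshold)
    tiered = assign_enhancer_tiers(
        balanced, n_samples_robust=cfg.robust_n, min_tags=cfg.enhancer_min_tags
    )
    enhancers = [e for e in tiered if e.tier != "candidate"]
    for e in enhancers:
        e.tpm = 1e6 * e.per_sample_tags / safe_lib
    stage_counts.update(
        retained_tcs=len(retained),
        divergent_pairs=len(loci),
        balanced_loci=len(balanced),
        enhancers_comprehensive=len(enhancers),
        enhancers_robust=sum(1 for e in enhancers if tier_at_least(e, "robust")),
        enhancers_strict=sum(1 for e in enhancers if e.tier == "strict"),
    )

    support = None
    if reference_sets:
        support = support_overlap(enhancers, reference_sets, cfg.novel_reference)

    # --- genomic enhancer clusters
    clusters = chain_enhancers(enhancers, gap=cfg.chain_gap, strict_gap=cfg.strict_gap)
    associate_genes(clusters, genes, margin=cfg.cluster_margin)
    stage_counts["genomic_clusters"] = len(clusters)
    stage_counts["genomic_clusters_multi"] = sum(1 for c in clusters if c.size > 1)

    # --- SNP intersection
    snp_hits: List[SnpEnhancerHit] = []
    snp_summary = None
    if snps:
        snp_hits = intersect_snps(snps, enhancers, window=cfg.snp_window)
        snp_summary = summarize_by_trait(snp_hits, snps)
        stage_counts["snp_hits"] = len(snp_hits)

    # --- linkage
    promoter_tcs = [
        t for t in tcs if t.gene_id is not None and t.tier in ("comprehensive", "robust")
    ]
    robust_enh = [e for e in enhancers if tier_at_least(e, "robust")]
    pairs = candidate_pairs(
        promoter_tcs, robust_enh, tads, max_dist=cfg.max_dist, tad_mode=cfg.tad_mode
    )
    links = pearson_linkage(
        pairs,
        enhancer_tpm={e.id: e.tpm for e in robust_enh},
        tc_tpm={t.id: t.tpm for t in promoter_tcs},
        r_threshold=cfg.r_min,
    )
    if pchic_sets:
        annotate_pchic(
            links, pchic_sets,
            enhancers={e.id: e for e in robust_enh},
            tcs={t.id: t for t in promoter_tcs},
        )
    link_summary = linkage_summary(
        links, clusters, enhancers={e.id: e for e in enhancers},
        snp_hits=snp_hits, snps=snps,
    )
    stage_counts["linkage_candidates"] = len(pairs)
    stage_counts["linkage_retained"] = sum(1 for c in links if c.retained)

    return PipelineResult(
        sample_ids=list(sample_ids),
        library_sizes=library_sizes,
        tcs=list(tcs),
        mask_report=report,
        enhancers=enhancers,
        clusters=clusters,
        snp_hits=snp_hits,
        snp_summary=snp_summary,
        links=links,
        link_summary=link_summary,
        support=support,
        stage_counts=stage_counts,
    )


def _n_unmasked(tcs, genes, tss_margin) -> int:
    from .enhancers import _exon_tss_trees

    trees = _exon_tss_trees(genes, tss_margin)
    n = 0
    for tc in tcs:
        tree = trees.get(tc.interval.chrom)
        if tree is None or not tree.overlap(tc.interval.start, tc.interval.end):
            n += 1
    return n


def run_all(config: PipelineConfig) -> PipelineResult:
    """File-based run: read inputs, execute stages, write artifacts + manifest."""
    cfg = config
    if cfg.ctss_dir is None or cfg.gtf is None:
        raise ValueError("ctss_dir and gtf inputs are required")
    for path in [cfg.ctss_dir, cfg.gtf, cfg.tads, cfg.snps, *cfg.pchic.values(),
                 *cfg.reference_sets.values(), cfg.tcs_meta, cfg.tcs_counts]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"missing input: {path}")
    ctss, sample_ids = io.read_ctss_dir(cfg.ctss_dir)
    genes = io.read_gene_models(cfg.gtf)
    tads = io.read_tads(cfg.tads) if cfg.tads else []
    snps = io.read_snp_table(cfg.snps) if cfg.snps else []
    pchic_sets = {name: io.read_bedpe(p, name) for name, p in cfg.pchic.items()}
    reference_sets = {name: io.read_bed(p) for name, p in cfg.reference_sets.items()}
    tcs = None
    if cfg.tcs_meta:
        counts = io.read_matrix(cfg.tcs_counts) if cfg.tcs_counts else None
        tcs = io.read_tag_clusters(cfg.tcs_meta, counts=counts)

    result = run_pipeline(
        ctss, sample_ids, genes, cfg, tads=tads, snps=snps,
        pchic_sets=pchic_sets or None, reference_sets=reference_sets or None, tcs=tcs,
    )
    if cfg.out_dir:
        write_artifacts(result, cfg, Path(cfg.out_dir))
    return result


def write_artifacts(result: PipelineResult, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tcs, enh = result.tcs, result.enhancers
    io.write_tag_clusters(tcs, out / "tcs.tsv")
    io.write_bed(
        [t.interval for t in tcs], out / "tcs.bed",
        names=[f"{t.id}|{t.tier}" for t in tcs], scores=[t.pooled for t in tcs],
    )
    io.write_matrix(
        CountMatrix([t.id for t in tcs], result.sample_ids,
                    np.stack([t.counts for t in tcs]) if tcs else np.zeros((0, len(result.sample_ids)))),
        out / "tcs_counts.tsv",
    )
    io.write_matrix(
        CountMatrix([t.id for t in tcs], result.sample_ids,
                    np.stack([t.tpm for t in tcs]) if tcs else np.zeros((0, len(result.sample_ids))),
                    scale="raw"),
        out / "tcs_tpm.tsv",
    )
    if result.mask_report:
        pd.DataFrame(
            [{"n_annotation_masked": result.mask_report.n_annotation_masked,
              "n_top_expressed_masked": result.mask_report.n_top_expressed_masked,
              "n_retained": len(result.mask_report.retained_tc_ids)}]
        ).to_csv(out / "mask_report.tsv", sep="\t", index=False)
    io.write_enhancers(enh, out / "enhancers.tsv")
    io.write_enhancer_bed(enh, out / "enhancers.bed")
    if enh:
        io.write_matrix(
            CountMatrix([e.id for e in enh], result.sample_ids,
                        np.stack([e.per_sample_tags for e in enh])),
            out / "enhancer_counts.tsv",
        )
        io.write_matrix(
            CountMatrix([e.id for e in enh], result.sample_ids,
                        np.stack([e.tpm for e in enh]), scale="raw"),
            out / "enhancer_tpm.tsv",
        )
    pd.DataFrame(
        [{"id": c.id, "chrom": c.interval.chrom, "start": c.interval.start,
          "end": c.interval.end, "n_members": c.size,
          "members": ",".join(c.member_ids), "genes": ",".join(c.gene_ids) or "."}
         for c in result.clusters]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if result.support is not None:
        pd.DataFrame(
            [{"reference_set": name, **vals} for name, vals in result.support.items()]
        ).to_csv(out / "support_overlap.tsv", sep="\t", index=False)
    if result.snp_hits:
        pd.DataFrame([dataclasses.asdict(h) for h in result.snp_hits]).to_csv(
            out / "snp_hits.tsv", sep="\t", index=False
        )
    if result.snp_summary is not None:
        result.snp_summary.to_csv(out / "snp_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"enhancer_id": c.enhancer_id, "tc_id": c.tc_id, "gene_id": c.gene_id or ".",
          "distance": c.distance, "r": c.r, "p": c.p, "p_adj": c.p_adj,
          "retained": int(c.retained),
          **{f"pchic_{k}": int(v) for k, v in sorted(c.pchic_support.items())}}
         for c in result.links]
    ).to_csv(out / "links.tsv", sep="\t", index=False)
    if result.link_summary is not None:
        result.link_summary.to_csv(out / "linkage_summary.tsv", sep="\t", index=False)
    manifest = {
        "enhscope_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_samples": len(result.sample_ids),
        "stage_counts": result.stage_counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    pd.DataFrame(
        sorted(result.stage_counts.items()), columns=["stage", "count"]
    ).to_csv(out / "manifest.tsv", sep="\t", index=False)
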