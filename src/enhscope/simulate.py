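"""Ground-truthed synthetic CTSS cohort generator.

Emulates a leukocyte CAGE cohort: 37 samples of sparse 5'-end tag
counts on a small synthetic genome containing directional promoter
loci, balanced divergent enhancer loci, background noise positions,
gene annotation, TADs, GWAS-style SNPs and PCHi-C-style interactions.

Observation model: every planted feature has a base expression level
(log-normal across features) and a per-sample activity.  A linked
(enhancer, gene) pair shares a Gaussian latent whose weight is chosen
analytically so that the exp-scale activities correlate at
``latent_rho``.  Per-feature-per-sample gamma noise adds negative-
binomial-like overdispersion, and each sample's counts are drawn by a
single multinomial over all genomic positions, so the emitted total
equals the drawn library size exactly.

Identical seed => byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CtssRecord, GenomicInterval, InteractionPair, SnpRecord, Tad
from .io import GeneModel, write_bed, write_bedpe, write_ctss, write_snp_table

TRAITS = ("asthma", "childhood_onset_asthma", "copd", "fev1_fvc_ratio")


@dataclass
class SimulationConfig:
    seed: int = 1
    n_samples: int = 37
    n_genes: int = 500
    n_enhancers: int = 200
    n_noise_sites: int = 2000
    genome_length: int = 40_000_000  # per synthetic chromosome
    n_chromosomes: int = 4
    promoter_D_range: Tuple[float, float] = (0.95, 1.0)
    enhancer_D_range: Tuple[float, float] = (0.0, 0.5)
    linked_fraction: float = 0.5
    latent_rho: float = 0.8
    activity_sigma: float = 0.7  # sd of log per-sample activity
    nb_dispersion: float = 0.05  # gamma overdispersion of sample weights
    library_size_range: Tuple[int, int] = (2_500_000, 6_900_000)
    tad_mean_size: int = 1_000_000
    snp_in_enhancer_fraction: float = 0.3
    n_snps: int = 60
    pchic_fraction: float = 0.7
    n_pchic_decoys: int = 20
    reference_fraction: float = 0.6  # planted enhancers present in the atlas BED
    n_reference_decoys: int = 50
    spacing: int = 30_000  # minimum distance between planted blocks
    enhancer_group_count: int = 10  # dense groups for cluster-stage truth
    enhancer_group_size: int = 3
    # relative expression scales; promoters dominate the library as in
    # real CAGE, eRNA levels are orders of magnitude lower
    promoter_level: float = 100.0
    enhancer_level: float = 0.3
    noise_level: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_enhancers", "n_noise_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for lo, hi in (self.promoter_D_range, self.enhancer_D_range):
            if not (-1 <= lo <= hi <= 1):
                raise ValueError("D ranges must lie within [-1, 1]")
        for name in ("linked_fraction", "snp_in_enhancer_fraction", "pchic_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PlantedFeature:
    feature_id: str
    kind: str  # {"promoter", "enhancer", "noise"}
    chrom: str
    strand: str  # gene strand for promoters, "." otherwise
    anchor: int  # TSS for promoters, midpoint for enhancers, position for noise
    pair_midpoint: Optional[int]  # midpoint of the divergent TC pair
    D: float
    level: float
    linked_gene: Optional[str] = None
    group: Optional[str] = None
    tad_id: Optional[str] = None


@dataclass
class GroundTruth:
    sample_ids: List[str]
    library_sizes: np.ndarray
    features: List[PlantedFeature]
    links: List[dict]  # gene_id, enhancer_id, latent_rho
    activity: Dict[str, np.ndarray]  # exp-scale per-sample activity per feature
    enhancer_tags: Dict[str, np.ndarray]  # emitted per-sample tags per enhancer
    enhancer_tier: Dict[str, str]  # tier eligibility from emitted tags
    snp_placements: List[dict]
    pchic_supported_links: List[Tuple[str, str]]
    in_reference: Dict[str, bool] = field(default_factory=dict)  # enhancer -> in atlas

    @property
    def promoters(self) -> List[PlantedFeature]:
        return [f for f in self.features if f.kind == "promoter"]

    @property
    def enhancers(self) -> List[PlantedFeature]:
        return [f for f in self.features if f.kind == "enhancer"]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sample_ids: List[str]
    ctss: List[CtssRecord]  # merged multi-sample records
    genes: List[GeneModel]
    tads: List[Tad]
    snps: List[SnpRecord]
    pchic: List[InteractionPair]
    truth: GroundTruth
    reference_sets: Dict[str, List[GenomicInterval]] = field(default_factory=dict)
    out_dir: Optional[Path] = None


# positions of the 4 CTSS sites of one TC, relative to its 5' edge
_TC_OFFSETS = np.array([0, 6, 13, 21])
_TC_SPAN = 22  # covers offsets 0..21
_PROM_ANTISENSE_SHIFT = 280  # antisense TC placed this far upstream of the TSS
_ENH_HALF_GAP = 34  # inner edges of the two enhancer TCs sit at mid -/+ this


def _gene_geometry(strand: str, tss: int, length: int) -> dict:
    if strand == "+":
        body = (tss, tss + length)
        exons = [(tss, tss + 400), (tss + length - 500, tss + length)]
        sense = tss + _TC_OFFSETS  # + strand
        anti = tss - _PROM_ANTISENSE_SHIFT + _TC_OFFSETS  # - strand
        pair_mid = ((tss - _PROM_ANTISENSE_SHIFT + _TC_OFFSETS[-1] + 1) + tss) // 2
    else:
        body = (tss - length + 1, tss + 1)
        exons = [(tss - 399, tss + 1), (tss - length + 1, tss - length + 501)]
        sense = tss - _TC_OFFSETS  # - strand
        anti = tss + _PROM_ANTISENSE_SHIFT - _TC_OFFSETS  # + strand
        pair_mid = ((tss + 1) + (tss + _PROM_ANTISENSE_SHIFT - _TC_OFFSETS[-1])) // 2
    return {"body": body, "exons": exons, "sense": np.sort(sense),
            "anti": np.sort(anti), "pair_mid": int(pair_mid)}


def _rho_latent_weight(rho: float, sigma: float) -> float:
    """Gaussian-latent correlation giving exp-scale correlation ``rho``.

    For X = exp(sigma Z1), Y = exp(sigma Z2) with corr(Z1, Z2) = q,
    corr(X, Y) = (exp(q sigma^2) - 1) / (exp(sigma^2) - 1); invert for q.
    """
    if rho <= 0:
        return 0.0
    q = np.log1p(rho * np.expm1(sigma**2)) / sigma**2
    return float(min(q, 1.0))


def simulate(config: SimulationConfig, out_dir=None) -> SimulatedDataset:
    """Generate the synthetic cohort; optionally write all input files."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_geom, rng_level, rng_act, rng_noise, rng_count, rng_snp, rng_pchic, rng_ref = (
        np.random.default_rng(s) for s in streams
    )
    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]

    # ---------------- blocks: atomic placement units -------------------
    n_linked = int(round(cfg.linked_fraction * cfg.n_enhancers))
    n_grouped = min(
        cfg.enhancer_group_count * cfg.enhancer_group_size, cfg.n_enhancers - n_linked
    )
    n_groups = n_grouped // cfg.enhancer_group_size if cfg.enhancer_group_size else 0
    n_grouped = n_groups * cfg.enhancer_group_size
    n_single = cfg.n_enhancers - n_linked - n_grouped

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    enh_ids = [f"SIME{i + 1:04d}" for i in range(cfg.n_enhancers)]
    linked_genes = list(rng_geom.permutation(cfg.n_genes)[: min(n_linked, cfg.n_genes)])
    n_linked = len(linked_genes)

    blocks: List[List[dict]] = []
    e_idx = 0
    for gi, gid in enumerate(gene_ids):
        block = [{"kind": "promoter", "id": gid}]
        if gi in linked_genes:
            block.append({"kind": "enhancer", "id": enh_ids[e_idx], "linked": gid})
            e_idx += 1
        blocks.append(block)
    for g in range(n_groups):
        group_id = f"GRP{g + 1:03d}"
        block = []
        for _ in range(cfg.enhancer_group_size):
            block.append({"kind": "enhancer", "id": enh_ids[e_idx], "group": group_id})
            e_idx += 1
        blocks.append(block)
    for _ in range(n_single):
        blocks.append([{"kind": "enhancer", "id": enh_ids[e_idx]}])
        e_idx += 1
    for i in range(cfg.n_noise_sites):
        blocks.append([{"kind": "noise", "id": f"N{i + 1:05d}"}])

    order = rng_geom.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # ---------------- lay blocks out on chromosomes --------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    per_chrom: Dict[str, List[List[dict]]] = {c: [] for c in chroms}
    for i, b in enumerate(blocks):
        per_chrom[chroms[i % len(chroms)]].append(b)

    features: List[PlantedFeature] = []
    genes: List[GeneModel] = []
    geometry: Dict[str, dict] = {}
    block_spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for chrom in chroms:
        cursor = 60_000
        for block in per_chrom[chrom]:
            block_start = cursor + int(rng_geom.integers(0, 10_000))
            pos = block_start
            span_start = pos
            for el in block:
                if el["kind"] == "promoter":
                    strand = "+" if rng_geom.random() < 0.5 else "-"
                    length = int(rng_geom.integers(5_000, 30_000))
                    tss = pos if strand == "+" else pos + length - 1
                    geo = _gene_geometry(strand, tss, length)
                    d = rng_geom.uniform(*cfg.promoter_D_range)
                    D = d if strand == "+" else -d
                    features.append(
                        PlantedFeature(el["id"], "promoter", chrom, strand, tss,
                                       geo["pair_mid"], D, 0.0)
                    )
                    genes.append(
                        GeneModel(
                            el["id"],
                            GenomicInterval(chrom, geo["body"][0], geo["body"][1], strand),
                            strand,
                            tss_list=[tss],
                            exons=[GenomicInterval(chrom, a, b, strand) for a, b in geo["exons"]],
                        )
                    )
                    geometry[el["id"]] = geo
                    # a linked enhancer follows 5-31 kb downstream, so the
                    # +/- 10 kb cluster-gene association is exercised for
                    # part of the cohort
                    pos += length + int(rng_geom.integers(4_000, 30_000))
                elif el["kind"] == "enhancer":
                    mid = pos + 1_000
                    d = rng_geom.uniform(*cfg.enhancer_D_range)
                    D = d if rng_geom.random() < 0.5 else -d
                    features.append(
                        PlantedFeature(el["id"], "enhancer", chrom, ".", mid, mid, D,
                                       0.0, el.get("linked"), el.get("group"))
                    )
                    geometry[el["id"]] = {
                        "anti": np.sort(mid - _ENH_HALF_GAP - _TC_OFFSETS),  # - strand
                        "sense": np.sort(mid + _ENH_HALF_GAP + _TC_OFFSETS),  # + strand
                    }
                    if el.get("group"):
                        pos = mid + int(rng_geom.integers(2_000, 8_000))
                    else:
                        pos += 2_000 + int(rng_geom.integers(0, 2_000))
                else:  # noise
                    strand = "+" if rng_geom.random() < 0.5 else "-"
                    features.append(
                        PlantedFeature(el["id"], "noise", chrom, strand, pos, None, 0.0, 0.0)
                    )
                    geometry[el["id"]] = {"pos": pos, "strand": strand}
                    pos += 500
            block_spans[chrom].append((span_start, pos))
            cursor = pos + cfg.spacing
            if cursor > cfg.genome_length - 60_000:
                raise ValueError(
                    "infeasible geometry: planted features exceed genome_length "
                    f"on {chrom} (cursor {cursor})"
                )

    # ---------------- TADs: block-respecting tiling ---------------------
    tads: List[Tad] = []
    tad_of_block: Dict[Tuple[str, int], int] = {}
    for chrom in chroms:
        spans = block_spans[chrom]
        if not spans:
            continue
        boundary = 0
        i = 0
        while i < len(spans):
            target = int(cfg.tad_mean_size * rng_geom.uniform(0.6, 1.4))
            j = i
            while j + 1 < len(spans) and spans[j][1] - boundary < target:
                j += 1
            end = (
                (spans[j][1] + spans[j + 1][0]) // 2
                if j + 1 < len(spans)
                else cfg.genome_length
            )
            tad_idx = len(tads)
            tads.append(Tad(GenomicInterval(chrom, boundary, end)))
            for k in range(i, j + 1):
                tad_of_block[(chrom, k)] = tad_idx
            boundary = end
            i = j + 1
    # record TAD membership per feature
    tad_lookup = {}
    for t_idx, t in enumerate(tads):
        tad_lookup.setdefault(t.interval.chrom, []).append((t.interval.start, t.interval.end, t_idx))
    for f in features:
        for s, e, t_idx in tad_lookup.get(f.chrom, []):
            if s <= f.anchor < e:
                f.tad_id = f"TAD{t_idx + 1:04d}"
                break

    # ---------------- expression levels and activities ------------------
    scale = {"promoter": cfg.promoter_level, "enhancer": cfg.enhancer_level,
             "noise": cfg.noise_level}
    sigma_level = {"promoter": 0.8, "enhancer": 0.6, "noise": 0.3}
    for f in features:
        f.level = scale[f.kind] * float(
            np.exp(rng_level.normal(0.0, sigma_level[f.kind]))
        )

    q = _rho_latent_weight(cfg.latent_rho, cfg.activity_sigma)
    links = [
        {"gene_id": f.linked_gene, "enhancer_id": f.feature_id, "latent_rho": cfg.latent_rho}
        for f in features
        if f.kind == "enhancer" and f.linked_gene
    ]
    activity: Dict[str, np.ndarray] = {}
    linked_ids = set()
    s = cfg.activity_sigma
    for link in links:
        z = rng_act.normal(size=cfg.n_samples)
        for fid in (link["gene_id"], link["enhancer_id"]):
            eps = rng_act.normal(size=cfg.n_samples)
            activity[fid] = np.exp(s * (np.sqrt(q) * z + np.sqrt(1 - q) * eps))
            linked_ids.add(fid)
    for f in features:
        if f.feature_id not in linked_ids:
            activity[f.feature_id] = np.exp(s * rng_act.normal(size=cfg.n_samples))

    # ---------------- position table and weights ------------------------
    # rows: (chrom, pos, strand, feature_id); per-position base weight
    rows = []
    base_w = []
    for f in features:
        geo = geometry[f.feature_id]
        if f.kind == "noise":
            rows.append((f.chrom, geo["pos"], geo["strand"], f.feature_id))
            base_w.append(f.level)
            continue
        share_plus = (1.0 + f.D) / 2.0
        if f.kind == "promoter":
            plus_pos = geo["sense"] if f.strand == "+" else geo["anti"]
            minus_pos = geo["anti"] if f.strand == "+" else geo["sense"]
        else:
            plus_pos = geo["sense"]
            minus_pos = geo["anti"]
        for pos_arr, strand, share in ((plus_pos, "+", share_plus),
                                       (minus_pos, "-", 1.0 - share_plus)):
            profile = rng_level.dirichlet(np.full(len(pos_arr), 5.0))
            for p, w in zip(pos_arr, profile):
                rows.append((f.chrom, int(p), strand, f.feature_id))
                base_w.append(f.level * share * w)
    base_w = np.asarray(base_w)
    feat_index = {f.feature_id: i for i, f in enumerate(features)}
    row_feat = np.array([feat_index[r[3]] for r in rows])

    act_matrix = np.stack([activity[f.feature_id] for f in features])  # F x S
    disp = cfg.nb_dispersion
    if disp > 0:
        gamma = rng_noise.gamma(1.0 / disp, disp, size=(len(features), cfg.n_samples))
    else:
        gamma = np.ones((len(features), cfg.n_samples))
    weights = base_w[:, None] * (act_matrix * gamma)[row_feat]  # P x S

    library_sizes = rng_count.integers(
        cfg.library_size_range[0], cfg.library_size_range[1] + 1, size=cfg.n_samples
    )
    counts = np.zeros((len(rows), cfg.n_samples), dtype=np.int64)
    for sidx in range(cfg.n_samples):
        w = weights[:, sidx]
        total = w.sum()
        if total > 0:
            counts[:, sidx] = rng_count.multinomial(int(library_sizes[sidx]), w / total)

    # merged multi-sample CTSS records (aggregate duplicate keys, if any)
    key_to_idx: Dict[tuple, int] = {}
    agg_keys: List[tuple] = []
    agg_counts: List[np.ndarray] = []
    for ridx, (chrom, pos, strand, _fid) in enumerate(rows):
        key = (chrom, pos, strand)
        if key in key_to_idx:
            agg_counts[key_to_idx[key]] += counts[ridx]
        else:
            key_to_idx[key] = len(agg_keys)
            agg_keys.append(key)
            agg_counts.append(counts[ridx].copy())
    order2 = sorted(range(len(agg_keys)), key=lambda i: agg_keys[i])
    ctss = [
        CtssRecord(
            GenomicInterval(agg_keys[i][0], agg_keys[i][1], agg_keys[i][1] + 1, agg_keys[i][2]),
            agg_counts[i],
        )
        for i in order2
        if agg_counts[i].sum() > 0
    ]

    # per-enhancer emitted tags and tier eligibility
    enhancer_tags: Dict[str, np.ndarray] = {}
    enhancer_tier: Dict[str, str] = {}
    for f in features:
        if f.kind != "enhancer":
            continue
        mask = row_feat == feat_index[f.feature_id]
        tags = counts[mask].sum(axis=0)
        enhancer_tags[f.feature_id] = tags
        supported = int((tags >= 2).sum())
        if supported >= cfg.n_samples and cfg.n_samples > 0:
            enhancer_tier[f.feature_id] = "strict"
        elif supported >= 6:
            enhancer_tier[f.feature_id] = "robust"
        elif supported >= 1:
            enhancer_tier[f.feature_id] = "comprehensive"
        else:
            enhancer_tier[f.feature_id] = "candidate"

    # ---------------- SNPs ---------------------------------------------
    snps: List[SnpRecord] = []
    placements: List[dict] = []
    enh_feats = [f for f in features if f.kind == "enhancer"]
    enh_pos = {f.chrom: [] for f in features}
    for f in enh_feats:
        enh_pos[f.chrom].append(f.anchor)
    for i in range(cfg.n_snps):
        rsid = f"rs{900000 + i}"
        trait = TRAITS[i % len(TRAITS)]
        u = rng_snp.random()
        if u < cfg.snp_in_enhancer_fraction and enh_feats:
            f = enh_feats[int(rng_snp.integers(len(enh_feats)))]
            pos = f.anchor + int(rng_snp.integers(-30, 31))
            placement = {"rsid": rsid, "where": "in_enhancer", "enhancer_id": f.feature_id}
            chrom = f.chrom
        elif u < cfg.snp_in_enhancer_fraction + 0.2 and enh_feats:
            f = enh_feats[int(rng_snp.integers(len(enh_feats)))]
            side = 1 if rng_snp.random() < 0.5 else -1
            pos = f.anchor + side * int(rng_snp.integers(400, 1100))
            placement = {"rsid": rsid, "where": "near_enhancer", "enhancer_id": f.feature_id}
            chrom = f.chrom
        else:
            while True:
                chrom = chroms[int(rng_snp.integers(len(chroms)))]
                pos = int(rng_snp.integers(60_000, cfg.genome_length - 60_000))
                if all(abs(pos - a) > 2_000 for a in enh_pos.get(chrom, [])):
                    break
            placement = {"rsid": rsid, "where": "background", "enhancer_id": None}
        snps.append(SnpRecord(rsid, GenomicInterval(chrom, pos, pos + 1), trait, "lead"))
        placements.append(placement)
        if rng_snp.random() < 0.4:  # LD proxies near the lead
            for k in range(int(rng_snp.integers(1, 3))):
                ld_pos = max(1, pos + int(rng_snp.integers(-20_000, 20_001)))
                snps.append(
                    SnpRecord(f"{rsid}_ld{k + 1}", GenomicInterval(chrom, ld_pos, ld_pos + 1),
                              trait, "ld", rsid)
                )
                placements.append(
                    {"rsid": f"{rsid}_ld{k + 1}", "where": "ld", "enhancer_id": None}
                )

    # ---------------- PCHi-C interactions -------------------------------
    pchic: List[InteractionPair] = []
    supported_links: List[Tuple[str, str]] = []
    feat_by_id = {f.feature_id: f for f in features}
    for link in links:
        if rng_pchic.random() < cfg.pchic_fraction:
            e = feat_by_id[link["enhancer_id"]]
            g = feat_by_id[link["gene_id"]]
            pchic.append(
                InteractionPair(
                    GenomicInterval(e.chrom, max(0, e.anchor - 500), e.anchor + 500),
                    GenomicInterval(g.chrom, max(0, g.anchor - 500), g.anchor + 500),
                    "synthetic_pchic",
                )
            )
            supported_links.append((link["gene_id"], link["enhancer_id"]))
    for _ in range(cfg.n_pchic_decoys):
        chrom = chroms[int(rng_pchic.integers(len(chroms)))]
        a = int(rng_pchic.integers(60_000, cfg.genome_length - 600_000))
        b = a + int(rng_pchic.integers(100_000, 500_000))
        pchic.append(
            InteractionPair(
                GenomicInterval(chrom, a, a + 1_000),
                GenomicInterval(chrom, b, b + 1_000),
                "synthetic_pchic",
            )
        )

    # ---------------- reference enhancer atlas ---------------------------
    # emulates an external enhancer catalogue: most planted enhancers are
    # "known", the rest are novel; decoys sit away from planted loci
    atlas: List[GenomicInterval] = []
    in_reference: Dict[str, bool] = {}
    for f in enh_feats:
        known = bool(rng_ref.random() < cfg.reference_fraction)
        in_reference[f.feature_id] = known
        if known:
            jitter = int(rng_ref.integers(-100, 101))
            atlas.append(
                GenomicInterval(f.chrom, max(0, f.anchor - 300 + jitter),
                                f.anchor + 300 + jitter)
            )
    for _ in range(cfg.n_reference_decoys):
        while True:
            chrom = chroms[int(rng_ref.integers(len(chroms)))]
            a = int(rng_ref.integers(60_000, cfg.genome_length - 60_000))
            if all(abs(a - x) > 2_000 for x in enh_pos.get(chrom, [])):
                break
        atlas.append(GenomicInterval(chrom, a, a + int(rng_ref.integers(300, 800))))
    atlas.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    truth = GroundTruth(
        sample_ids=sample_ids,
        library_sizes=np.asarray(library_sizes, dtype=np.int64),
        features=features,
        links=links,
        activity=activity,
        enhancer_tags=enhancer_tags,
        enhancer_tier=enhancer_tier,
        snp_placements=placements,
        pchic_supported_links=supported_links,
        in_reference=in_reference,
    )
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    data = SimulatedDataset(
        config=cfg, sample_ids=sample_ids, ctss=ctss, genes=genes, tads=tads,
        snps=snps, pchic=pchic, truth=truth, reference_sets={"atlas": atlas},
    )
    if out_dir is not None:
        data.out_dir = Path(out_dir)
        _write_dataset(data)
    return data


def _write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            b = g.body
            fh.write(
                f"{b.chrom}\tsim\tgene\t{b.start + 1}\t{b.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{b.chrom}\tsim\ttranscript\t{b.start + 1}\t{b.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def _write_dataset(data: SimulatedDataset) -> None:
    out = data.out_dir
    (out / "ctss").mkdir(parents=True, exist_ok=True)
    for sidx, sid in enumerate(data.sample_ids):
        recs = [r for r in data.ctss if r.counts[sidx] > 0]
        single = [
            CtssRecord(r.interval, np.array([r.counts[sidx]])) for r in recs
        ]
        write_ctss(single, out / "ctss" / f"{sid}.ctss.tsv")
    _write_gtf(data.genes, out / "genes.gtf")
    write_bed([t.interval for t in data.tads], out / "tads.bed")
    write_snp_table(data.snps, out / "snps.tsv")
    write_bedpe(data.pchic, out / "pchic.bedpe")
    for name, intervals in data.reference_sets.items():
        write_bed(intervals, out / f"{name}.bed")
    truth = data.truth
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "sample_ids": truth.sample_ids,
                "library_sizes": truth.library_sizes.tolist(),
                "features": [asdict(f) for f in truth.features],
                "links": truth.links,
                "enhancer_tier": truth.enhancer_tier,
                "snp_placements": truth.snp_placements,
                "pchic_supported_links": truth.pchic_supported_links,
                "in_reference": truth.in_reference,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def _match_calls(calls, planted, tol: int):
    """Greedy 1:1 matching of calls to planted loci by midpoint distance."""
    matches = {}
    used = set()
    by_chrom: Dict[str, list] = {}
    for f in planted:
        by_chrom.setdefault(f.chrom, []).append(f)
    for e in calls:
        best, best_d = None, tol + 1
        for f in by_chrom.get(e.region.chrom, []):
            if f.feature_id in used:
                continue
            d = abs(e.midpoint - (f.pair_midpoint if f.pair_midpoint is not None else f.anchor))
            if d <= tol and d < best_d:
                best, best_d = f, d
        if best is not None:
            matches[e.id] = best.feature_id
            used.add(best.feature_id)
    return matches


def truth_eval(result, truth: GroundTruth, match_tol: int = 250) -> dict:
    """Per-stage confusion metrics of pipeline outputs against ground truth.

    ``result`` is a ``PipelineResult`` (or any object exposing
    ``enhancers``, ``clusters`` and ``links``).
    """
    calls = list(result.enhancers)
    enh_matches = _match_calls(calls, truth.enhancers, match_tol)
    prom_matches = _match_calls(
        [c for c in calls if c.id not in enh_matches], truth.promoters, match_tol
    )
    eligible = {
        f.feature_id
        for f in truth.enhancers
        if truth.enhancer_tier[f.feature_id] != "candidate"
    }
    matched_eligible = set(enh_matches.values()) & eligible
    n_calls = len(calls)
    false_calls = n_calls - len(enh_matches)
    out = {
        "enhancer_calling": {
            "n_calls": n_calls,
            "n_planted_eligible": len(eligible),
            "sensitivity": len(matched_eligible) / len(eligible) if eligible else float("nan"),
            "false_call_fraction": false_calls / n_calls if n_calls else 0.0,
            "promoters_called": len(prom_matches),
        }
    }
    # tier agreement on matched enhancers
    tier_ok = tier_total = 0
    for e in calls:
        fid = enh_matches.get(e.id)
        if fid is None:
            continue
        tier_total += 1
        if e.tier == truth.enhancer_tier[fid]:
            tier_ok += 1
    out["tiering"] = {
        "n_matched": tier_total,
        "agreement": tier_ok / tier_total if tier_total else float("nan"),
    }
    # clustering: truth groups recovered as single clusters
    if hasattr(result, "clusters") and result.clusters is not None:
        call_of = {v: k for k, v in enh_matches.items()}
        groups: Dict[str, set] = {}
        for f in truth.enhancers:
            if f.group:
                groups.setdefault(f.group, set()).add(f.feature_id)
        cluster_of = {}
        for c in result.clusters:
            for m in c.member_ids:
                cluster_of[m] = c.id
        ok = total = 0
        for gid, members in groups.items():
            call_ids = [call_of.get(m) for m in members]
            if any(ci is None for ci in call_ids):
                continue
            total += 1
            cids = {cluster_of.get(ci) for ci in call_ids}
            if len(cids) == 1 and None not in cids:
                ok += 1
        out["clustering"] = {
            "n_groups_evaluable": total,
            "group_recovery": ok / total if total else float("nan"),
        }
    # linkage
    if hasattr(result, "links") and result.links is not None:
        planted = {(l["enhancer_id"], l["gene_id"]) for l in truth.links}
        planted_retained: set = set()
        planted_scored: set = set()
        nonplanted_scored = retained_nonplanted = 0
        for c in result.links:
            fid = enh_matches.get(c.enhancer_id)
            key = (fid, c.gene_id)
            if fid is not None and key in planted:
                planted_scored.add(key)
                if c.retained:
                    planted_retained.add(key)
            else:
                nonplanted_scored += 1
                retained_nonplanted += int(c.retained)
        out["linkage"] = {
            "n_planted": len(planted),
            "planted_scored": len(planted_scored),
            "planted_retained_fraction": len(planted_retained) / len(planted) if planted else float("nan"),
            "nonplanted_scored": nonplanted_scored,
            "nonplanted_retained_fraction": (
                retained_nonplanted / nonplanted_scored if nonplanted_scored else 0.0
            ),
        }
    return out
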