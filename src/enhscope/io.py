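"""Readers and writers for every external representation the pipeline touches.

One coordinate convention everywhere: BED 0-based half-open.  GTF input
(1-based closed) is converted on read.  TSV files carry a header row and
"." for missing values.  Readers tolerate unsorted input and sort once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    CtssRecord,
    GenomicInterval,
    InteractionPair,
    SnpRecord,
    Tad,
)

logger = logging.getLogger(__name__)

MISSING = "."


# ---------------------------------------------------------------------------
# CTSS
# ---------------------------------------------------------------------------

def read_ctss(path, sample_id: str) -> List[CtssRecord]:
    """Read one sample's CTSS track: tab-separated chrom, pos, strand, count."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            chrom, pos_s, strand, count_s = parts
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            records.append(
                CtssRecord(GenomicInterval(chrom, pos, pos + 1, strand), np.array([count]))
            )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.strand))
    return records


def write_ctss(records: Sequence[CtssRecord], path, sample_index: int = 0) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.pos}\t{r.interval.strand}\t{int(r.counts[sample_index])}\n"
            )


def merge_ctss(per_sample: Dict[str, List[CtssRecord]]) -> List[CtssRecord]:
    """Merge single-sample CTSS lists into multi-sample records.

    Positions are keyed by (chrom, pos, strand); a sample missing a
    position contributes zero.  Sample order follows dict order.
    """
    sample_ids = list(per_sample)
    n = len(sample_ids)
    table: Dict[tuple, np.ndarray] = {}
    for s, recs in enumerate(per_sample.values()):
        for r in recs:
            key = (r.interval.chrom, r.pos, r.interval.strand)
            if key not in table:
                table[key] = np.zeros(n, dtype=np.int64)
            table[key][s] += int(r.counts[0])
    merged = [
        CtssRecord(GenomicInterval(chrom, pos, pos + 1, strand), counts)
        for (chrom, pos, strand), counts in sorted(table.items())
    ]
    return merged


def read_ctss_dir(dir_path) -> tuple:
    """Read every ``*.ctss.tsv`` file in a directory; returns (records, sample_ids)."""
    paths = sorted(Path(dir_path).glob("*.ctss.tsv"))
    if not paths:
        raise FileNotFoundError(f"no *.ctss.tsv files under {dir_path}")
    per_sample = {p.name.replace(".ctss.tsv", ""): read_ctss(p, p.stem) for p in paths}
    return merge_ctss(per_sample), list(per_sample)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/BED6 into half-open intervals (BED is already half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, names: Optional[Sequence[str]] = None,
              scores: Optional[Sequence] = None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            name = names[k] if names is not None else MISSING
            score = scores[k] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_tads(path) -> List[Tad]:
    return [Tad(iv) for iv in read_bed(path)]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene: body interval, strand-aware transcript TSSs and exons."""

    gene_id: str
    body: GenomicInterval
    strand: str
    tss_list: List[int] = field(default_factory=list)
    exons: List[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Representative TSS: the 5'-most transcript start."""
        return min(self.tss_list) if self.strand == "+" else max(self.tss_list)


def _tss_of(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end - 1


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from GTF (gene/transcript/exon) or BED12."""
    path = str(path)
    if path.endswith((".bed12", ".bed")):
        return _read_bed12(path)
    return _read_gtf(path)


def _read_gtf(path) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    known = {"gene", "transcript", "exon"}
    for ft in db.featuretypes():
        if ft not in known:
            logger.warning("ignoring unknown GTF feature type %r", ft)
    genes: Dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        genes[gid] = GeneModel(
            gene_id=gid,
            body=GenomicInterval(g.seqid, g.start - 1, g.end, g.strand),
            strand=g.strand,
        )
    for t in db.features_of_type("transcript"):
        gid = t.attributes["gene_id"][0]
        genes[gid].tss_list.append(_tss_of(t.start - 1, t.end, t.strand))
    for e in db.features_of_type("exon"):
        gid = e.attributes["gene_id"][0]
        genes[gid].exons.append(GenomicInterval(e.seqid, e.start - 1, e.end, e.strand))
    out = []
    for g in genes.values():
        if not g.tss_list:  # gene without transcript lines: use the body ends
            g.tss_list = [_tss_of(g.body.start, g.body.end, g.strand)]
        g.exons.sort(key=lambda iv: iv.start)
        out.append(g)
    out.sort(key=lambda g: (g.body.chrom, g.body.start))
    return out


def _read_bed12(path) -> List[GeneModel]:
    genes: Dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, end, name, strand = p[0], int(p[1]), int(p[2]), p[3], p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            ]
            g = genes.get(name)
            if g is None:
                g = genes[name] = GeneModel(
                    name, GenomicInterval(chrom, start, end, strand), strand
                )
            else:
                g.body = GenomicInterval(
                    chrom, min(g.body.start, start), max(g.body.end, end), strand
                )
            g.tss_list.append(_tss_of(start, end, strand))
            g.exons.extend(exons)
    out = list(genes.values())
    for g in out:
        g.exons.sort(key=lambda iv: iv.start)
    out.sort(key=lambda g: (g.body.chrom, g.body.start))
    return out


# ---------------------------------------------------------------------------
# BEDPE, SNP tables, matrices
# ---------------------------------------------------------------------------

def read_bedpe(path, source_label: str = "") -> List[InteractionPair]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >= 6 fields")
            a = GenomicInterval(p[0], int(p[1]), int(p[2]))
            b = GenomicInterval(p[3], int(p[4]), int(p[5]))
            label = source_label or (p[6] if len(p) > 6 else "")
            out.append(InteractionPair(a, b, label))
    return out


def write_bedpe(pairs: Sequence[InteractionPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.anchor_a, p.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{p.source_label or MISSING}\n"
            )


SNP_COLUMNS = ["rsid", "chrom", "pos", "trait", "role", "lead_rsid"]


def read_snp_table(path) -> List[SnpRecord]:
    """TSV with header rsid, chrom, pos, trait, role[, lead_rsid]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SNP_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SNP columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        lead = getattr(row, "lead_rsid", MISSING)
        lead = None if (pd.isna(lead) or lead == MISSING) else lead
        pos = int(row.pos)
        out.append(
            SnpRecord(row.rsid, GenomicInterval(row.chrom, pos, pos + 1), row.trait,
                      row.role, lead)
        )
    return out


def write_snp_table(snps: Sequence[SnpRecord], path) -> None:
    rows = [
        {
            "rsid": s.rsid,
            "chrom": s.position.chrom,
            "pos": s.position.start,
            "trait": s.trait,
            "role": s.role,
            "lead_rsid": s.lead_rsid or MISSING,
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=SNP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix(path, scale: str = "raw") -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated feature_ids")
    return CountMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)


def write_matrix(m: CountMatrix, path) -> None:
    df = pd.DataFrame(m.values, index=m.feature_ids, columns=m.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pipeline artifact round trips (tag clusters, enhancers)
# ---------------------------------------------------------------------------

def write_tag_clusters(tcs, meta_path) -> None:
    rows = [
        {
            "id": t.id,
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "strand": t.interval.strand,
            "summit": t.summit,
            "tier": t.tier,
            "gene_id": t.gene_id or MISSING,
            "min_density": t.min_density,
            "max_density": t.max_density,
        }
        for t in tcs
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_tag_clusters(meta_path, counts: Optional[CountMatrix] = None,
                      tpm: Optional[CountMatrix] = None):
    from .clustering import TagCluster

    df = pd.read_csv(meta_path, sep="\t", dtype={"gene_id": str})
    out = []
    for row in df.itertuples(index=False):
        c = counts.row(row.id) if counts is not None else np.zeros(1)
        t = tpm.row(row.id) if tpm is not None else None
        out.append(
            TagCluster(
                id=row.id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                summit=int(row.summit),
                counts=np.asarray(c, dtype=np.int64),
                tpm=t,
                tier=row.tier,
                gene_id=None if row.gene_id == MISSING else row.gene_id,
                min_density=float(row.min_density),
                max_density=float(row.max_density),
            )
        )
    return out


def write_enhancers(enhancers, meta_path) -> None:
    rows = [
        {
            "id": e.id,
            "chrom": e.region.chrom,
            "start": e.region.start,
            "end": e.region.end,
            "midpoint": e.midpoint,
            "fwd_expr": e.fwd_expr,
            "rev_expr": e.rev_expr,
            "D": e.D,
            "tier": e.tier,
            "novel": int(e.novel),
        }
        for e in enhancers
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_enhancers(meta_path, counts: Optional[CountMatrix] = None,
                   tpm: Optional[CountMatrix] = None):
    from .enhancers import EnhancerCandidate

    df = pd.read_csv(meta_path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        c = counts.row(row.id) if counts is not None else np.zeros(1, dtype=np.int64)
        e = EnhancerCandidate(
            id=row.id,
            midpoint=int(row.midpoint),
            region=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            fwd_expr=float(row.fwd_expr),
            rev_expr=float(row.rev_expr),
            per_sample_tags=np.asarray(c, dtype=np.int64),
            D=float(row.D),
            tier=row.tier,
            novel=bool(row.novel),
        )
        e.tpm = tpm.row(row.id) if tpm is not None else None
        out.append(e)
    return out


def write_enhancer_bed(enhancers, path) -> None:
    """BED6 export: tier in the name field, D scaled x1000 in the score."""
    write_bed(
        [e.region for e in enhancers],
        path,
        names=[f"{e.id}|{e.tier}" for e in enhancers],
        scores=[int(round(e.D * 1000)) for e in enhancers],
    )
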