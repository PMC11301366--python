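#!/usr/bin/env python
"""Intersect GWAS-style SNPs with the called enhancers.

Exact mode (SNP inside the enhancer region) and +/- 1 kb window mode,
summarised per trait with unique-SNP totals, plus the fraction of
SNP-hit enhancers sitting in multi-enhancer genomic clusters.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"


def main() -> None:
    summary = pd.read_csv(RUN / "snp_summary.tsv", sep="\t")
    hits = pd.read_csv(RUN / "snp_hits.tsv", sep="\t")
    clusters = pd.read_csv(RUN / "clusters.tsv", sep="\t")
    in_multi = set()
    for _, row in clusters[clusters.n_members > 1].iterrows():
        in_multi.update(row.members.split(","))
    hit_enh = set(hits.enhancer_id)
    frac = len(hit_enh & in_multi) / len(hit_enh) if hit_enh else float("nan")

    out = ROOT / "results" / "05_snp_summary.tsv"
    summary.to_csv(out, sep="\t", index=False)
    print(f"per-trait SNP/enhancer intersection -> {out.relative_to(ROOT)}")
    print(summary.to_string(index=False))
    print(f"  enhancers hit by a SNP: {len(hit_enh)}; fraction in multi-enhancer "
          f"clusters: {frac:.2f}")


if __name__ == "__main__":
    main()
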