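#!/usr/bin/env python
"""Profile genomic enhancer clusters (15 kb single-linkage chains).

Reports the size histogram, the largest cluster, how many clusters are
multi-enhancer, and the genes associated within the +/- 10 kb margins.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"


def main() -> None:
    clusters = pd.read_csv(RUN / "clusters.tsv", sep="\t")
    sizes = clusters["n_members"]
    hist = sizes.value_counts().sort_index()
    n_genes = clusters["genes"].apply(lambda g: 0 if g == "." else len(str(g).split(","))).sum()
    rows = [("clusters_total", len(clusters)),
            ("clusters_multi_enhancer", int((sizes > 1).sum())),
            ("largest_cluster_members", int(sizes.max())),
            ("genes_associated", int(n_genes))]
    rows += [(f"clusters_of_size_{s}", int(c)) for s, c in hist.items()]
    out = ROOT / "results" / "04_cluster_profile.tsv"
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(out, sep="\t", index=False)
    print(f"genomic enhancer cluster profile -> {out.relative_to(ROOT)}")
    for k, v in rows:
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
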