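#!/usr/bin/env python
"""Evaluate enhancer calling against the planted ground truth.

Compares the called balanced bidirectional loci (|D| < 0.9 after
annotation + top-expression masking) with the planted enhancers:
sensitivity among support-eligible loci, false-call fraction, promoter
leakage, tier sizes and the tier agreement with truth.
"""

import json
from pathlib import Path

import pandas as pd

from enhscope import SimulationConfig, simulate, truth_eval
from enhscope import io
from enhscope.pipeline import PipelineResult  # noqa: F401  (type of run artifacts)

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"


class RunView:
    """Minimal result view over the scratch/run artifacts."""

    def __init__(self):
        counts = io.read_matrix(RUN / "enhancer_counts.tsv")
        self.enhancers = io.read_enhancers(RUN / "enhancers.tsv", counts=counts)
        self.clusters = None
        self.links = None


def main() -> None:
    if not RUN.exists():
        raise SystemExit("run analysis/02_cluster_tags.py first")
    # the truth is regenerated (same seed) rather than stored wholesale
    data = simulate(SimulationConfig(seed=1))
    view = RunView()
    ev = truth_eval(view, data.truth)["enhancer_calling"]
    tiers = pd.Series([e.tier for e in view.enhancers]).value_counts()
    rows = [
        ("calls", ev["n_calls"]),
        ("planted_support_eligible", ev["n_planted_eligible"]),
        ("sensitivity", round(ev["sensitivity"], 4)),
        ("false_call_fraction", round(ev["false_call_fraction"], 4)),
        ("promoters_called", ev["promoters_called"]),
        ("tier_comprehensive_only", int(tiers.get("comprehensive", 0))),
        ("tier_robust", int(tiers.get("robust", 0))),
        ("tier_strict", int(tiers.get("strict", 0))),
        ("novel_vs_atlas", sum(1 for e in view.enhancers if e.novel)),
    ]
    out = ROOT / "results" / "03_enhancer_calling.tsv"
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(out, sep="\t", index=False)
    print(f"enhancer calling vs truth -> {out.relative_to(ROOT)}")
    for k, v in rows:
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
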