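# Methods

This note documents the models and procedures implemented in `enhscope`,
the parameters that matter, the assumptions behind the synthetic cohort
generator, and the numerical choices made where the design was open.

## Coordinates and overlap

All coordinates are BED-convention 0-based half-open `[start, end)`;
GTF input (1-based closed) is converted on read. The single overlap
predicate used by every stage is ≥ 1 bp intersection of half-open
intervals (the default `bedtools intersect` behaviour). Unsorted input
is tolerated and sorted once on load. A global validator
(`core.validate_intervals`) re-checks the half-open invariant on
anything that crossed a serialisation boundary.

## Tag clustering

CTSS positions are clustered per chromosome strand on pooled
(sample-summed) counts, giving one consensus TC catalogue for the
cohort — appropriate when downstream tiers and correlations are defined
over the same sample axis for every feature.

The segmentation enumerates the laminar family of *density-maximal*
site intervals. A break before site *k* severs sites *i..j* into blocks
*i..k−1* and *k..j*; the break's density is the weaker flanking block
density, where a block's density is its pooled tags divided by the
genomic distance to the break point (`tags(i..k−1) / (pos_k − pos_i)`,
symmetrically for the suffix side). The minimum over break points is
the largest density an interval sustains (`max_density`, ∞ for single
sites); the density at which it detached from its enclosing interval is
its `min_density`. The recursion that splits at the weakest break
enumerates exactly the intervals whose sustained density exceeds that
of every enclosing interval — the test suite verifies this against an
exhaustive O(n³) oracle on seeded random instances. Evaluating the
break *between* sites (prefix counts excluding the boundary site,
distance denominator rather than bp length) is what makes splits land
at gap boundaries instead of slicing one site off a dense island; this
matters on realistic data where a strong promoter dominates the
cumulative counts of a long interval.

Filters: `max_density ≥ min_stability × min_density` (default
min_stability = 2; top-level intervals have min_density 0 and always
pass), bp length ≤ `max_length` (200), pooled tags ≥ `min_tags` (3).
The original clustering method only being named by its users, these are
the conventional defaults, all configurable. Nested survivors resolve
to the outermost one; ties in the weakest break resolve to the leftmost
break, so equal-density maximal intervals prefer the longer, leftmost
survivor. The recursion is O(n) scans per level (worst case O(n²)
overall), ample for desk-scale catalogues; per-strand inputs beyond
~10⁵ sites would warrant the divide-and-conquer scan order of the
original tool.

TPM: `1e6 × count / column_total` per sample, where the totals are the
per-sample sums over all CTSS positions (library sizes); TC and
enhancer TPM vectors are therefore consistent aggregations of the same
normalisation, and all-zero libraries stay zero. TC tiers:
comprehensive ⇔ ≥ 1 TPM in ≥ 1 sample; robust ⇔ ≥ 3 TPM in all samples.
The robust rule has a documented variant (`robust_rule="mean"`, ≥ 3 TPM
on the cross-sample mean) because both definitions circulate; the
all-samples rule is the default. Annotation assigns a TC the gene whose
body it overlaps, resolving multiple overlaps to the gene whose nearest
transcript TSS is closest to the TC summit (ties to the
lexicographically smaller gene id).

## Enhancer calling

Masking removes, first, every TC overlapping an annotated exon (plus an
optional `tss_margin` around annotated TSSs, default 0 — exon overlap
already covers TSS-proximal signal in practice); second, the `top_mask`
most highly expressed remaining TCs (pooled TPM, ties masked in genomic
order). The absolute default of 1,000 reflects a ~78k-TC catalogue; on
synthetic catalogues of a few thousand TCs the same *proportion*
(`top_mask="scaled"`, 1000/78176 ≈ 1.28 %) is used, fixed as part of
the synthetic study design — an absolute 1,000 would remove a third of
the catalogue and change the experiment, not the method.

Divergent pairing: a (−) TC followed by a (+) TC with inner-edge gap
`plus.start − minus.end` in [0, 450] bp; pairing is one-to-one greedy
by smallest gap (ties to the leftmost pair), since a TC re-used across
pairs would double-count its signal. The locus midpoint is
`⌊(minus.end + plus.start)/2⌋`; windows are `[mid − 250, mid)` on (−)
and `[mid, mid + 250)` on (+); D = (F − R)/(F + R) on pooled window
tags; loci with F + R = 0 are dropped. The 0.9 threshold acts as an
*exclusion* bound — balanced loci have |D| near 0, so retention is
|D| < 0.9 — and both the formula and threshold are configurable.
Support tiers on per-sample window totals: ≥ 2 tags in ≥ 1 / ≥ 6 /
all samples (comprehensive / robust / strict). The strict denominator
is "every sample present in the matrix"; cohorts with a designated
sample subset should subset the matrix first.

## Genomic enhancer clusters, SNPs

Chaining is transitive single-linkage at inner-edge distance ≤ 15 kb
(`strict_gap=True` switches to < 15 kb); clusters never span
chromosomes, singletons are size-1 clusters and both counts are
reported. Gene association uses gene-body overlap with the cluster span
extended ± 10 kb (clamped at 0); a TSS-only mode is a one-line filter
on the gene table.

SNP intersection reports exact hits (width-1 SNP inside the region) and
symmetric ± 1 kb window hits, each (SNP, enhancer) pair once with the
stronger mode; trait summaries count unique rsids per trait and a
deduplicated total row. The "fraction of SNP-hit enhancers in genomic
clusters" uses multi-member clusters, since under singleton-inclusive
counting the fraction is identically 1.

## Linkage

Candidates are (comprehensive, gene-annotated promoter TC; robust
enhancer) pairs with midpoint–summit distance ≤ 2 Mb and both features
*fully contained* in at least one common TAD (conservative reading;
`tad_mode="midpoint"` relaxes to midpoint containment; with several TAD
sets, any set containing both suffices). Pearson r over TPM profiles is
computed per pair (`scipy.stats.pearsonr`; the test suite checks it
against an independently coded covariance/σ formula to 1e-12);
zero-variance profiles are excluded with a logged reason and do not
count toward m. The two-sided p uses n − 2 degrees of freedom;
Bonferroni p_adj = min(1, m·p) with m = number of scored pairs (logged,
since the tested universe defines the correction). Retention is by
r ≥ 0.5 alone — one-sided, positive — with p_adj reported for
inspection. At n = 37 samples, r = 0.5 corresponds to p ≈ 7e-4, so the
retention rule is individually significant well below 0.005 even
before adjustment. PCHi-C support requires one anchor overlapping the
enhancer and the other the promoter TC (either assignment); two anchors
on the same feature do not count.

## Synthetic cohort generator

The generator emulates a 37-sample leukocyte CAGE cohort on a synthetic
genome (4 × 40 Mb chromosomes by default): 500 genes with directional
promoters (true |D| ∈ [0.95, 1], divergent sense/antisense TC pair
257 bp apart), 200 balanced enhancers (true |D| ∈ [0, 0.5], divergent
TC pair 67 bp apart), 2,000 single-position noise sites, exon-bearing
gene models, TADs, SNPs (30 % inside enhancers, 20 % within 1 kb, the
rest background; some leads carry LD proxies), PCHi-C contacts for 70 %
of linked pairs plus decoys, and a reference enhancer atlas containing
60 % of planted enhancers plus decoys (the remainder is ground-truth
*novel*).

Placement is block-based: each linked (gene, enhancer) pair, enhancer
group (10 groups of 3 at 3–9 kb gaps, to exercise chaining), single
feature or noise site is one block; blocks are shuffled, dealt
round-robin across chromosomes and laid out ≥ 30 kb apart so stage
outputs are unambiguous. Linked enhancers sit 5–31 kb downstream of
their gene, so part of the cohort also exercises the ± 10 kb
cluster–gene association. TAD boundaries are tiled at ~1 Mb mean size
in the gaps *between* blocks, never through one — encoding the model's
own premise that interacting pairs share a TAD.

Expression: feature levels are log-normal with promoters ~300× the
eRNA scale (matching the empirical hierarchy in CAGE — this is also
what makes proportional top-expression masking safe); per-sample
activity is exp(σZ) with σ = 0.7. A linked pair shares a Gaussian
latent with weight chosen analytically so the *exp-scale* activity
correlation equals `latent_rho` (default 0.8):
q = ln(1 + ρ(e^{σ²} − 1))/σ². Observed counts add per-feature-sample
gamma noise (shape 1/α, α = `nb_dispersion` = 0.05 — negative-
binomial-like overdispersion) and are then drawn by one multinomial per
sample over all positions, so each sample's emitted total equals its
drawn library size exactly (library sizes uniform on [2.5M, 6.9M],
the depth range typical of HeliScope CAGE cohorts). Tag-level noise and
the gamma term attenuate the realised TPM correlation of linked pairs
to ~0.7, which still clears the r ≥ 0.5 retention for ~90–95 % of
planted pairs at n = 37.

One master seed expands into eight named substreams (geometry, levels,
activities, overdispersion, counts, SNPs, PCHi-C, atlas), so identical
seeds give byte-identical files and adding a feature class cannot
perturb unrelated draws.

What the generator does **not** emulate: real genome sequence and
mappability, promoter/enhancer shape heterogeneity, overlapping or
nested features (a separate "hard mode" would overlay features to
stress tie-breaking), batch effects, LD structure beyond a positional
proxy, or annotation incompleteness. Passing the recovery tests
therefore demonstrates correctness of the *machinery* under the stated
generative assumptions — not calling performance on real CAGE data,
where masking completeness and the D threshold dominate.

`truth_eval` matches calls to planted loci greedily at ≤ 250 bp
midpoint distance (1:1, so duplicate calls at one locus count as false
calls) and reports per-stage sensitivity/false fractions, tier
agreement, enhancer-group recovery and planted-link retention.

## Problem sizes and runtime

The test suite runs the full default cohort (37 × ~7.6k positions)
end-to-end in ~1 s; the oracle-equivalence checks use 50 seeded
instances of ≤ 20 sites (where exhaustive enumeration is exact and
fast); linkage recovery aggregates 20 seeded cohorts of 30 genes /
20 enhancers at 37 samples. `scripts/acceptance.py` (default cohort,
all checks, determinism rerun) completes in well under a minute on one
CPU.

## Known limitations

- One consensus TC/enhancer set per cohort; per-sample catalogues are
  out of scope.
- The filtered-cluster step keeps the outermost passing interval; no
  sub-cluster decomposition of broad promoters.
- `snps_in_clusters` and the linkage summary treat "in a cluster" as
  "in a multi-member cluster"; singleton-inclusive counts are available
  from the cluster table.
- Bonferroni m is the number of scored pairs of the current run; when
  comparing runs with different candidate universes, p_adj values are
  not directly comparable.
- The generator's spacing guarantees (≥ 30 kb) make matching
  unambiguous; it does not test resolution limits of the 450 bp pairing
  under feature collision.
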