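import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhscope.core import CountMatrix, CtssRecord, GenomicInterval
from enhscope.clustering import (
    annotate_tcs,
    paraclu_cluster,
    paraclu_family,
    tier_tag_clusters,
    tpm_normalize,
)
from enhscope.io import GeneModel

from conftest import make_tc
from oracles import paraclu_clusters_oracle, paraclu_family_oracle


def ctss(chrom, pos, strand, count):
    return CtssRecord(GenomicInterval(chrom, pos, pos + 1, strand), np.array([count]))


class TestParaclu:
    def test_singleton(self):
        (tc,) = paraclu_cluster([ctss("chr1", 100, "+", 5)], min_tags=1)
        assert tc.interval == GenomicInterval("chr1", 100, 101, "+")
        assert tc.pooled == 5
        assert tc.summit == 100

    def test_distant_positions_stay_separate(self):
        tcs = paraclu_cluster(
            [ctss("chr1", 100, "+", 5), ctss("chr1", 10_100, "+", 5)],
            max_length=200,
            min_tags=1,
        )
        assert len(tcs) == 2
        assert all(t.interval.length == 1 for t in tcs)

    def test_empty_input(self):
        assert paraclu_cluster([]) == []

    def test_nonpositive_stability_rejected(self):
        with pytest.raises(ValueError, match="min_stability"):
            paraclu_cluster([ctss("chr1", 1, "+", 1)], min_stability=0)

    @pytest.mark.parametrize("seed", range(1, 51))
    def test_matches_exhaustive_oracle(self, seed):
        """Recursive segmentation equals the brute-force density-maximality
        oracle, before and after filtering, on random instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        pos = np.sort(rng.choice(np.arange(0, 500), size=n, replace=False))
        val = rng.integers(1, 60, size=n).astype(float)
        fam = sorted(paraclu_family(pos, val))
        exp = paraclu_family_oracle(pos, val)
        assert [f[:2] for f in fam] == [e[:2] for e in exp]
        np.testing.assert_allclose(
            [f[2:] for f in fam], [e[2:] for e in exp], rtol=1e-12
        )
        records = [ctss("chr1", int(p), "+", int(v)) for p, v in zip(pos, val)]
        got = paraclu_cluster(records, min_stability=2, max_length=200, min_tags=3)
        exp_clusters = paraclu_clusters_oracle(pos, val, 2, 200, 3)
        assert [(t.interval.start, t.interval.end - 1) for t in got] == [
            (int(pos[i]), int(pos[j])) for (i, j, *_ ) in exp_clusters
        ]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_family_is_laminar(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        pos = np.sort(rng.choice(np.arange(0, 2000), size=n, replace=False))
        val = rng.integers(1, 50, size=n).astype(float)
        fam = paraclu_family(pos, val)
        for a in fam:
            for b in fam:
                disjoint = a[1] < b[0] or b[1] < a[0]
                nested = (a[0] <= b[0] and b[1] <= a[1]) or (b[0] <= a[0] and a[1] <= b[1])
                assert disjoint or nested

    def test_sample_permutation_invariance(self, rng):
        pos = np.sort(rng.choice(np.arange(0, 300), size=15, replace=False))
        counts = rng.integers(0, 10, size=(15, 5))
        recs = [
            CtssRecord(GenomicInterval("chr1", int(p), int(p) + 1, "+"), c)
            for p, c in zip(pos, counts)
        ]
        perm = rng.permutation(5)
        recs_perm = [
            CtssRecord(r.interval, r.counts[perm]) for r in recs
        ]
        a = paraclu_cluster(recs, min_tags=1)
        b = paraclu_cluster(recs_perm, min_tags=1)
        assert [(t.interval.start, t.interval.end) for t in a] == [
            (t.interval.start, t.interval.end) for t in b
        ]
        for ta, tb in zip(a, b):
            assert ta.counts[perm].tolist() == tb.counts.tolist()


class TestTpm:
    def test_examples(self):
        m = CountMatrix(["f1", "f2"], ["s1"], np.array([[5.0], [999_995.0]]))
        t = tpm_normalize(m)
        assert t.values[0, 0] == pytest.approx(5.0)
        m0 = CountMatrix(["f1"], ["s1"], np.array([[0.0]]))
        assert tpm_normalize(m0).values[0, 0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize(CountMatrix(["f"], ["s"], np.array([[1.0]])), totals=np.array([-1.0]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_conserve_one_million(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 50, size=(100, 37)).astype(float)
        vals[:, 0] = 0  # an all-zero library stays zero
        t = tpm_normalize(CountMatrix(
            [f"f{i}" for i in range(100)], [f"s{j}" for j in range(37)], vals
        ))
        sums = t.values.sum(axis=0)
        assert sums[0] == 0.0
        np.testing.assert_allclose(sums[1:], 1e6, rtol=1e-9)
        t.validate_tpm()


class TestTiers:
    def test_threshold_application(self):
        tcs = [
            make_tc("chr1", 0, 10, "+", [1], tpm=[0.5, 1.0, 0.2]),
            make_tc("chr1", 20, 30, "+", [1], tpm=[3.0, 4.0, 3.5]),
            make_tc("chr1", 40, 50, "+", [1], tpm=[0.1, 0.2, 0.3]),
        ]
        labels = tier_tag_clusters(tcs)
        assert labels == ["comprehensive", "robust", "none"]

    def test_mean_rule(self):
        tc = make_tc("chr1", 0, 10, "+", [1], tpm=[1.0, 8.0])  # mean 4.5, min 1
        assert tier_tag_clusters([tc], robust_rule="mean") == ["robust"]
        assert tier_tag_clusters([tc], robust_rule="all_samples") == ["comprehensive"]

    def test_partition_and_nesting(self, rng):
        tcs = [
            make_tc("chr1", i * 10, i * 10 + 5, "+", [1], tpm=rng.exponential(2.0, size=10))
            for i in range(200)
        ]
        labels = tier_tag_clusters(tcs)
        n = {k: labels.count(k) for k in ("robust", "comprehensive", "none")}
        assert sum(n.values()) == 200
        for tc in tcs:  # robust implies comprehensive thresholds
            if tc.tier == "robust":
                assert tc.tpm.max() >= 1.0 and tc.tpm.min() >= 3.0

    def test_tier_monotonicity(self, rng):
        order = {"none": 0, "comprehensive": 1, "robust": 2}
        for _ in range(50):
            tpm = rng.exponential(2.0, size=5)
            tc = make_tc("chr1", 0, 5, "+", [1], tpm=tpm)
            (before,) = tier_tag_clusters([tc])
            k = int(rng.integers(5))
            tc.tpm = tpm.copy()
            tc.tpm[k] += rng.exponential(2.0)
            (after,) = tier_tag_clusters([tc])
            assert order[after] >= order[before]


class TestAnnotate:
    def make_gene(self, gid, start, end, strand="+"):
        tss = start if strand == "+" else end - 1
        return GeneModel(gid, GenomicInterval("chr1", start, end, strand), strand, [tss])

    def test_tc_inside_single_gene(self):
        tc = make_tc("chr1", 500, 520, "+", [1])
        annotate_tcs([tc], [self.make_gene("gA", 100, 1000)])
        assert tc.gene_id == "gA"

    def test_intergenic_unannotated(self):
        tc = make_tc("chr1", 5000, 5020, "+", [1])
        annotate_tcs([tc], [self.make_gene("gA", 100, 1000)])
        assert tc.gene_id is None

    def test_nested_genes_resolve_to_nearer_tss(self):
        # five genes, two nested around the TC; hand enumeration says the
        # inner gene's TSS (at 900) is nearest to the summit at 950
        genes = [
            self.make_gene("outer", 100, 3000),
            self.make_gene("inner", 900, 1500),
            self.make_gene("left", 10, 50),
            self.make_gene("right", 4000, 5000),
            self.make_gene("minus", 600, 2500, strand="-"),  # TSS 2499
        ]
        tc = make_tc("chr1", 940, 960, "+", [1], summit=950)
        annotate_tcs([tc], genes)
        assert tc.gene_id == "inner"
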