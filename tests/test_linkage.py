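import numpy as np
import pytest
from scipy import stats

from enhscope.core import GenomicInterval, InteractionPair, Tad
from enhscope.enhancers import EnhancerCandidate
from enhscope.linkage import (
    LinkageCandidate,
    annotate_pchic,
    candidate_pairs,
    correlation_pvalue,
    linkage_summary,
    pearson_linkage,
)

from conftest import make_tc
from oracles import pchic_support_oracle, pearson_oracle


def enh(chrom, mid, eid):
    return EnhancerCandidate(eid, mid, GenomicInterval(chrom, mid - 250, mid + 250),
                             1.0, 1.0, np.array([2]), 0.0)


def tad(chrom, start, end):
    return Tad(GenomicInterval(chrom, start, end))


class TestCandidatePairs:
    def test_distance_boundary(self):
        tads = [tad("chr1", 0, 3_000_000)]
        tc = make_tc("chr1", 1000, 1100, "+", [5], tc_id="t", summit=1000)
        near = candidate_pairs([tc], [enh("chr1", 1000 + 1_999_999, "e")], tads)
        far = candidate_pairs([tc], [enh("chr1", 1000 + 2_000_001, "e")], tads)
        assert len(near) == 1 and near[0].distance == 1_999_999
        assert far == []

    def test_different_tads_excluded(self):
        tads = [tad("chr1", 0, 400_000), tad("chr1", 400_000, 1_000_000)]
        tc = make_tc("chr1", 1000, 1100, "+", [5], tc_id="t", summit=1000)
        assert candidate_pairs([tc], [enh("chr1", 501_000, "e")], tads) == []

    def test_containment_vs_midpoint_mode(self):
        # the enhancer straddles a TAD edge: contained mode excludes,
        # midpoint mode keeps the pair
        tads = [tad("chr1", 0, 500_100)]
        tc = make_tc("chr1", 1000, 1100, "+", [5], tc_id="t", summit=1000)
        e = enh("chr1", 500_000, "e")  # region [499750, 500250) exceeds the TAD
        assert candidate_pairs([tc], [e], tads) == []
        assert len(candidate_pairs([tc], [e], tads, tad_mode="midpoint")) == 1

    def test_any_tad_set_may_contain_both(self):
        tads = [tad("chr1", 0, 100_000), tad("chr1", 0, 2_000_000)]
        tc = make_tc("chr1", 1000, 1100, "+", [5], tc_id="t", summit=1000)
        assert len(candidate_pairs([tc], [enh("chr1", 900_000, "e")], tads)) == 1


class TestPearson:
    def pair(self):
        return LinkageCandidate("e", "t", "g", 1000)

    def test_identical_profiles_retained(self):
        x = np.arange(37, dtype=float)
        (c,) = pearson_linkage([self.pair()], {"e": x}, {"t": x + 3.0})
        assert c.r == pytest.approx(1.0)
        assert c.retained

    def test_negated_profile_not_retained(self):
        x = np.arange(37, dtype=float)
        (c,) = pearson_linkage([self.pair()], {"e": x}, {"t": -x})
        assert c.r == pytest.approx(-1.0)
        assert not c.retained

    def test_r_matches_independent_formula(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=37), rng.normal(size=37)
            (c,) = pearson_linkage([self.pair()], {"e": x}, {"t": y})
            assert c.r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
            assert c.p == pytest.approx(correlation_pvalue(c.r, 37), rel=1e-9)

    def test_bonferroni_is_exact(self, rng):
        pairs = [LinkageCandidate(f"e{k}", f"t{k}", None, 0) for k in range(7)]
        etpm = {f"e{k}": rng.normal(size=37) for k in range(7)}
        ttpm = {f"t{k}": rng.normal(size=37) for k in range(7)}
        scored = pearson_linkage(pairs, etpm, ttpm)
        for c in scored:
            assert c.p_adj == min(1.0, 7 * c.p)

    def test_zero_variance_profile_excluded(self, rng):
        pairs = [LinkageCandidate("e0", "t0", None, 0), LinkageCandidate("e1", "t1", None, 0)]
        scored = pearson_linkage(
            pairs,
            {"e0": np.full(37, 2.0), "e1": rng.normal(size=37)},
            {"t0": rng.normal(size=37), "t1": rng.normal(size=37)},
        )
        assert [c.enhancer_id for c in scored] == ["e1"]
        assert scored[0].p_adj == min(1.0, 1 * scored[0].p)  # m counts scored pairs only

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pearson_linkage([self.pair()], {"e": np.array([1.0, 2.0])}, {"t": np.array([1.0, 3.0])})

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=37), rng.normal(size=37)
        (a,) = pearson_linkage([self.pair()], {"e": x}, {"t": y})
        (b,) = pearson_linkage([self.pair()], {"e": 3.5 * x + 11.0}, {"t": 0.2 * y - 4.0})
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_retained_set_shrinks_with_threshold(self, rng):
        pairs = [LinkageCandidate(f"e{k}", f"t{k}", None, 0) for k in range(40)]
        z = rng.normal(size=37)
        etpm = {f"e{k}": z + rng.normal(size=37) for k in range(40)}
        ttpm = {f"t{k}": z + rng.normal(size=37) for k in range(40)}
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            scored = pearson_linkage(
                [LinkageCandidate(f"e{k}", f"t{k}", None, 0) for k in range(40)],
                etpm, ttpm, r_threshold=thr)
            cur = {c.enhancer_id for c in scored if c.retained}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_pvalue_at_half_correlation_37_samples(self):
        """r = 0.5 at n = 37 is individually significant well below 0.005,
        consistent with a sub-0.125 Bonferroni FDR at moderate m."""
        assert correlation_pvalue(0.5, 37) < 0.005


class TestPchic:
    def make_features(self):
        e = enh("chr1", 10_000, "e")
        t = make_tc("chr1", 500_000, 500_100, "+", [5], tc_id="t", summit=500_000)
        return e, t

    def test_anchors_on_both_features_supported(self):
        e, t = self.make_features()
        pairs = [InteractionPair(GenomicInterval("chr1", 9_500, 10_500),
                                 GenomicInterval("chr1", 499_900, 500_200), "mono")]
        c = LinkageCandidate("e", "t", None, 0)
        annotate_pchic([c], {"mono": pairs}, {"e": e}, {"t": t})
        assert c.pchic_support == {"mono": True}

    def test_both_anchors_on_enhancer_not_supported(self):
        e, t = self.make_features()
        pairs = [InteractionPair(GenomicInterval("chr1", 9_500, 10_500),
                                 GenomicInterval("chr1", 9_600, 10_400), "mono")]
        c = LinkageCandidate("e", "t", None, 0)
        annotate_pchic([c], {"mono": pairs}, {"e": e}, {"t": t})
        assert c.pchic_support == {"mono": False}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        enhancers, tcs, cands = {}, {}, []
        for k in range(20):
            em = int(rng.integers(0, 200_000))
            ts = int(rng.integers(0, 200_000))
            enhancers[f"e{k}"] = enh("chr1", max(em, 300), f"e{k}")
            tcs[f"t{k}"] = make_tc("chr1", ts, ts + 100, "+", [5], tc_id=f"t{k}", summit=ts)
            cands.append(LinkageCandidate(f"e{k}", f"t{k}", None, 0))
        pairs = []
        for _ in range(30):
            a = int(rng.integers(0, 200_000))
            b = int(rng.integers(0, 200_000))
            pairs.append(InteractionPair(GenomicInterval("chr1", a, a + int(rng.integers(200, 2000))),
                                         GenomicInterval("chr1", b, b + int(rng.integers(200, 2000))),
                                         "set"))
        annotate_pchic(cands, {"set": pairs}, enhancers, tcs)
        for c in cands:
            expected = pchic_support_oracle(
                enhancers[c.enhancer_id].region, tcs[c.tc_id].interval, pairs
            )
            assert c.pchic_support["set"] == expected


class TestSummary:
    def test_empty_candidates_all_zero(self):
        df = linkage_summary([])
        assert (df["count"] == 0).all()

    def test_single_retained_supported_candidate(self):
        from enhscope.clusters import chain_enhancers

        e1 = enh("chr1", 10_000, "e1")
        e2 = enh("chr1", 14_000, "e2")
        clusters = chain_enhancers([e1, e2])
        e1.novel = True
        c = LinkageCandidate("e1", "t1", "g1", 1000, r=0.9, retained=True,
                             pchic_support={"mono": True})
        df = linkage_summary([c], clusters, enhancers={"e1": e1, "e2": e2}).set_index("category")
        assert df.loc["retained_pairs", "count"] == 1
        assert df.loc["pchic_mono", "count"] == 1
        assert df.loc["enhancers_in_genomic_clusters", "count"] == 1
        assert df.loc["novel_enhancers", "count"] == 1
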