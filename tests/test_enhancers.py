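import numpy as np
import pytest

from enhscope.core import CtssRecord, GenomicInterval
from enhscope.enhancers import (
    CtssIndex,
    EnhancerCandidate,
    assign_enhancer_tiers,
    filter_balanced,
    find_divergent_pairs,
    mask_tcs,
    quantify_and_score,
    support_overlap,
)
from enhscope.io import GeneModel

from conftest import make_tc, random_intervals
from oracles import overlap_count_oracle


def ctss(chrom, pos, strand, count):
    return CtssRecord(GenomicInterval(chrom, pos, pos + 1, strand), np.array([count]))


def gene(gid, start, end, strand="+", exons=None):
    tss = start if strand == "+" else end - 1
    g = GeneModel(gid, GenomicInterval("chr1", start, end, strand), strand, [tss])
    g.exons = exons if exons is not None else [GenomicInterval("chr1", start, end, strand)]
    return g


class TestMasking:
    def setup_method(self):
        # 8 TCs: 3 overlap annotated exons, 5 are free
        self.genes = [gene("g1", 1000, 2000), gene("g2", 5000, 6000)]
        self.tcs = [
            make_tc("chr1", 1100, 1120, "+", [9], tc_id="a1", tpm=[9.0]),
            make_tc("chr1", 1900, 1910, "-", [9], tc_id="a2", tpm=[9.0]),
            make_tc("chr1", 5500, 5510, "+", [9], tc_id="a3", tpm=[9.0]),
            make_tc("chr1", 3000, 3010, "+", [1], tc_id="f1", tpm=[5.0]),
            make_tc("chr1", 3300, 3310, "-", [1], tc_id="f2", tpm=[4.0]),
            make_tc("chr1", 3600, 3610, "+", [1], tc_id="f3", tpm=[3.0]),
            make_tc("chr1", 3900, 3910, "-", [1], tc_id="f4", tpm=[2.0]),
            make_tc("chr1", 4200, 4210, "+", [1], tc_id="f5", tpm=[1.0]),
        ]

    def test_exon_overlap_masked_and_top_expressed_masked(self):
        retained, report = mask_tcs(self.tcs, self.genes, top_n=2)
        assert report.n_annotation_masked == 3
        assert report.n_top_expressed_masked == 2
        assert [t.id for t in retained] == ["f3", "f4", "f5"]

    def test_rank_boundary_retained(self):
        # with top_n = 4 of 5 free TCs, the 5th-ranked TC survives
        retained, _ = mask_tcs(self.tcs, self.genes, top_n=4)
        assert [t.id for t in retained] == ["f5"]

    def test_expression_tie_broken_by_genomic_order(self):
        tcs = [
            make_tc("chr1", 200, 210, "+", [1], tc_id="late", tpm=[5.0]),
            make_tc("chr1", 100, 110, "+", [1], tc_id="early", tpm=[5.0]),
        ]
        retained, _ = mask_tcs(tcs, [], top_n=1)
        assert [t.id for t in retained] == ["late"]  # lower coordinate masked first

    def test_negative_top_n_rejected(self):
        with pytest.raises(ValueError):
            mask_tcs(self.tcs, self.genes, top_n=-1)

    def test_top_n_exceeding_remainder_masks_all(self, caplog):
        retained, report = mask_tcs(self.tcs, self.genes, top_n=99)
        assert retained == []
        assert report.n_top_expressed_masked == 5


class TestPairing:
    def test_divergent_pair_and_midpoint(self):
        minus = make_tc("chr1", 100, 200, "-", [5])
        plus = make_tc("chr1", 400, 500, "+", [5])
        (locus,) = find_divergent_pairs([minus, plus])
        assert locus.gap == 200
        assert locus.midpoint == 300

    @pytest.mark.parametrize("gap,paired", [(450, True), (451, False)])
    def test_separation_boundary(self, gap, paired):
        minus = make_tc("chr1", 100, 200, "-", [5])
        plus = make_tc("chr1", 200 + gap, 300 + gap, "+", [5])
        assert bool(find_divergent_pairs([minus, plus])) is paired

    def test_convergent_orientation_not_paired(self):
        plus = make_tc("chr1", 100, 200, "+", [5])
        minus = make_tc("chr1", 300, 400, "-", [5])
        assert find_divergent_pairs([plus, minus]) == []

    def test_greedy_nearest_partner_one_to_one(self):
        minus_a = make_tc("chr1", 100, 200, "-", [5], tc_id="ma")
        minus_b = make_tc("chr1", 250, 300, "-", [5], tc_id="mb")
        plus = make_tc("chr1", 400, 500, "+", [5], tc_id="p")
        loci = find_divergent_pairs([minus_a, minus_b, plus])
        assert len(loci) == 1
        assert loci[0].minus_tc.id == "mb"  # smaller gap wins


class TestDirectionality:
    def build_index(self, fwd, rev, mid=1000):
        recs = []
        if fwd:
            recs.append(ctss("chr1", mid + 10, "+", fwd))
        if rev:
            recs.append(ctss("chr1", mid - 10, "-", rev))
        return CtssIndex(recs)

    def locus(self, mid=1000):
        minus = make_tc("chr1", mid - 60, mid - 30, "-", [1])
        plus = make_tc("chr1", mid + 30, mid + 60, "+", [1])
        (l,) = find_divergent_pairs([minus, plus])
        return l

    @pytest.mark.parametrize("F,R,D", [(10, 10, 0.0), (19, 1, 0.9), (0, 5, -1.0)])
    def test_directionality_examples(self, F, R, D):
        (e,) = quantify_and_score([self.locus()], self.build_index(F, R))
        assert e.D == pytest.approx(D)
        assert (e.fwd_expr, e.rev_expr) == (F, R)

    def test_empty_window_locus_dropped(self):
        assert quantify_and_score([self.locus()], CtssIndex([ctss("chr2", 1, "+", 5)])) == []

    def test_antisymmetry_under_strand_swap(self, rng):
        mid = 1000
        for _ in range(20):
            F, R = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            (e,) = quantify_and_score([self.locus()], self.build_index(F, R))
            (e_swap,) = quantify_and_score([self.locus()], self.build_index(R, F))
            assert e.D == pytest.approx(-e_swap.D)

    def test_translation_invariance(self):
        shift = 12_345
        recs = [ctss("chr1", 990, "-", 7), ctss("chr1", 1010, "+", 3)]
        shifted = [ctss("chr1", r.pos + shift, r.interval.strand, int(r.counts[0])) for r in recs]
        (a,) = quantify_and_score([self.locus(1000)], CtssIndex(recs))
        (b,) = quantify_and_score([self.locus(1000 + shift)], CtssIndex(shifted))
        assert a.D == b.D
        assert b.midpoint - a.midpoint == shift
        assert b.region.start - a.region.start == shift

    def test_flank_validation(self):
        with pytest.raises(ValueError):
            quantify_and_score([self.locus()], self.build_index(1, 1), flank=0)


class TestBalanceFilter:
    def make(self, D):
        return EnhancerCandidate(
            "e", 1000, GenomicInterval("chr1", 750, 1250), (1 + D) * 50,
            (1 - D) * 50, np.array([2]), D,
        )

    def test_balanced_retained_directional_discarded(self):
        assert filter_balanced([self.make(0.0)]) != []
        assert filter_balanced([self.make(0.95)]) == []
        assert filter_balanced([self.make(-0.95)]) == []

    @pytest.mark.parametrize("thr", [0.0, 1.5, -0.1])
    def test_threshold_validation(self, thr):
        with pytest.raises(ValueError):
            filter_balanced([], d_threshold=thr)

    def test_planted_loci_separate_cleanly(self, small_sim):
        """Unmasked divergent loci from the generator: every planted
        promoter (|D| >= 0.95) is discarded, >= 95 % of planted balanced
        loci (|D| <= 0.5) are retained."""
        from enhscope.clustering import paraclu_cluster

        tcs = paraclu_cluster(small_sim.ctss)
        loci = find_divergent_pairs(tcs)
        scored = quantify_and_score(loci, CtssIndex(small_sim.ctss))
        kept = {e.midpoint for e in filter_balanced(scored)}
        truth = small_sim.truth
        prom_mids = {f.pair_midpoint for f in truth.promoters}
        enh_mids = {f.pair_midpoint for f in truth.enhancers}
        assert all(
            min(abs(m - p) for p in prom_mids) > 250 for m in kept
        ), "a promoter-like locus survived the balance filter"
        recovered = sum(1 for m in enh_mids if any(abs(m - k) <= 250 for k in kept))
        assert recovered >= 0.95 * len(enh_mids)


class TestSupportTiers:
    def make(self, tags):
        tags = np.asarray(tags)
        return EnhancerCandidate(
            "e", 1000, GenomicInterval("chr1", 750, 1250), float(tags.sum()), 0.0,
            tags, 0.0,
        )

    def test_single_sample_support_is_comprehensive(self):
        (e,) = assign_enhancer_tiers([self.make([2] + [0] * 36)])
        assert e.tier == "comprehensive"

    def test_six_sample_support_is_robust(self):
        (e,) = assign_enhancer_tiers([self.make([2] * 6 + [0] * 31)])
        assert e.tier == "robust"

    def test_all_sample_support_is_strict(self):
        (e,) = assign_enhancer_tiers([self.make([2] * 37)])
        assert e.tier == "strict"

    def test_tiers_nest_over_random_support(self, rng):
        order = {"candidate": 0, "comprehensive": 1, "robust": 2, "strict": 3}
        for _ in range(1000):
            tags = rng.integers(0, 4, size=10)
            (e,) = assign_enhancer_tiers([self.make(tags)])
            n_sup = int((tags >= 2).sum())
            # nesting: the assigned tier's threshold chain is consistent
            if e.tier == "strict":
                assert n_sup >= 10
            if order[e.tier] >= order["robust"]:
                assert n_sup >= 6
            if order[e.tier] >= order["comprehensive"]:
                assert n_sup >= 1


class TestSupportOverlap:
    def make_enh(self, chrom, start, end, eid):
        mid = (start + end) // 2
        return EnhancerCandidate(eid, mid, GenomicInterval(chrom, start, end), 1.0, 1.0,
                                 np.array([2]), 0.0)

    def test_containment_counted_and_adjacency_not(self):
        e_in = self.make_enh("chr1", 100, 200, "in")
        e_out = self.make_enh("chr1", 300, 400, "out")
        res = support_overlap(
            [e_in, e_out], {"atac": [GenomicInterval("chr1", 50, 250)],
                            "h3k27ac": [GenomicInterval("chr1", 400, 500)]},
            novel_reference="atac",
        )
        assert res["atac"]["count"] == 1 and res["atac"]["percent"] == 50.0
        assert res["h3k27ac"]["count"] == 0  # 1 bp short: [300,400) vs [400,500)
        assert e_in.novel is False and e_out.novel is True

    def test_counts_match_brute_force(self, rng):
        enh = [
            self.make_enh(iv.chrom, iv.start, iv.end, f"e{k}")
            for k, iv in enumerate(random_intervals(rng, 200))
        ]
        refs = random_intervals(rng, 200)
        res = support_overlap(enh, {"ref": refs})
        assert res["ref"]["count"] == overlap_count_oracle([e.region for e in enh], refs)

    def test_empty_reference_set_warns(self, caplog):
        e = self.make_enh("chr1", 1, 10, "e")
        with caplog.at_level("WARNING"):
            res = support_overlap([e], {"empty": []})
        assert res["empty"]["count"] == 0
        assert any("empty" in r.message for r in caplog.records)
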