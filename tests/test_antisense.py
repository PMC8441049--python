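import numpy as np
import pytest

import crypterm as ct
from crypterm.antisense import (
    DiscoveryThresholds,
    Segment,
    assemble_segments,
    classify_origin,
    discover_novel,
    link_readthrough_antisense,
    merge_strata,
    quantify_and_select,
    reproducible_segments,
)

SIZES = {"chrI": 20_000}
TH = DiscoveryThresholds()


def seg(start, end, strand="+", chrom="chrI"):
    return Segment(chrom, start, end, strand)


class TestAssembly:
    def test_gap_of_five_merges_six_splits(self, make_cov):
        for gap, n in ((3, 1), (5, 1), (6, 2)):
            cov = make_cov(SIZES, [("chrI", "+", 100, 200, 2.0),
                                   ("chrI", "+", 200 + gap, 300, 2.0)])
            got = assemble_segments(cov, TH)
            assert len(got) == n
            if n == 1:
                assert (got[0].start, got[0].end) == (100, 300)

    def test_zero_coverage_gives_nothing(self, make_cov):
        cov = ct.StrandedCoverage(SIZES, {})
        assert assemble_segments(cov, TH) == []

    def test_sub_threshold_coverage_ignored(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "-", 100, 300, 0.5)])
        assert assemble_segments(cov, TH) == []

    def test_idempotent_on_repainted_output(self, make_cov):
        rng = np.random.default_rng(9)
        fills = []
        pos = 100
        for _ in range(30):
            length = int(rng.integers(20, 300))
            fills.append(("chrI", "+", pos, pos + length, 1.0))
            pos += length + int(rng.integers(6, 50))  # gaps > merge_gap
        cov = make_cov(SIZES, fills)
        first = assemble_segments(cov, TH)
        repainted = make_cov(
            SIZES, [(s.chrom, s.strand, s.start, s.end, 1.0) for s in first])
        assert assemble_segments(repainted, TH) == first


class TestReproducibility:
    def test_overlapping_portion_kept(self):
        assert reproducible_segments([seg(0, 100)], [seg(50, 150)]) == [seg(50, 100)]

    def test_disjoint_segments_drop_out(self):
        assert reproducible_segments([seg(0, 100)], [seg(200, 300)]) == []

    def test_strands_do_not_mix(self):
        assert reproducible_segments([seg(0, 100, "+")], [seg(0, 100, "-")]) == []

    def test_matches_quadratic_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)

        def random_segs(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 19_000))
                out.append(seg(s, s + int(rng.integers(1, 800)),
                               "+" if rng.random() < 0.5 else "-"))
            return out

        a, b = random_segs(500), random_segs(500)
        got = reproducible_segments(a, b)
        # oracle: per-base union masks of each replicate, intersected;
        # the union of pairwise intersections equals that mask exactly
        want = []
        for strand in "+-":
            masks = []
            for lst in (a, b):
                m = np.zeros(20_000, bool)
                for x in lst:
                    if x.strand == strand:
                        m[x.start:x.end] = True
                masks.append(m)
            both = np.concatenate(([False], masks[0] & masks[1], [False]))
            edges = np.flatnonzero(np.diff(both.astype(np.int8)))
            want += [seg(int(s), int(e), strand)
                     for s, e in zip(edges[0::2], edges[1::2])]
        assert got == sorted(want)


class TestMergeStrata:
    def test_idempotent_and_commutative(self):
        a = [seg(0, 100), seg(300, 400, "-")]
        b = [seg(90, 200), seg(600, 700)]
        assert merge_strata(a, a) == sorted(a)
        assert merge_strata(a, b) == merge_strata(b, a)

    def test_adjacent_same_strand_merge(self):
        assert merge_strata([seg(0, 100)], [seg(100, 200)]) == [seg(0, 200)]


class TestDiscovery:
    def annot(self):
        return ct.GenomeAnnotation(SIZES, [
            ct.TranscriptionUnit("big", "chrI", 5000, 15_000, "+"),
        ])

    def test_reciprocal_rule_keeps_small_overlap(self):
        # 500 bp of a 1 kb segment inside a 10 kb TU: < 10% of the TU
        kept = discover_novel([seg(4500, 5500)], self.annot(), TH)
        assert len(kept) == 1

    def test_reciprocal_rule_removes_contained_segment(self):
        assert discover_novel([seg(6000, 7000)], self.annot(), TH) == []

    def test_opposite_strand_overlap_is_ignored(self):
        kept = discover_novel([seg(6000, 7000, "-")], self.annot(), TH)
        assert len(kept) == 1

    @pytest.mark.parametrize("length,kept", [(49, 0), (50, 1), (5000, 1), (5001, 0)])
    def test_length_bounds_inclusive(self, length, kept):
        annot = ct.GenomeAnnotation(SIZES, [])
        got = discover_novel([seg(100, 100 + length, "-")], annot, TH)
        assert len(got) == kept

    def test_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(8)
        tus = []
        for i in range(200):
            s = int(rng.integers(0, 18_000))
            tus.append(ct.TranscriptionUnit(
                f"t{i}", "chrI", s, s + int(rng.integers(100, 2000)),
                "+" if rng.random() < 0.5 else "-"))
        annot = ct.GenomeAnnotation(SIZES, tus)
        segs = []
        for _ in range(1000):
            s = int(rng.integers(0, 19_000))
            segs.append(seg(s, s + int(rng.integers(20, 1000)),
                            "+" if rng.random() < 0.5 else "-"))
        got = {nt.segment for nt in discover_novel(segs, annot, TH)}
        want = set()
        for sg in segs:
            if not TH.min_len <= sg.length <= TH.max_len:
                continue
            bad = False
            for tu in tus:
                if tu.strand != sg.strand:
                    continue
                ov = min(tu.end, sg.end) - max(tu.start, sg.start)
                if ov >= TH.reciprocal_frac * sg.length and \
                        ov >= TH.reciprocal_frac * tu.length:
                    bad = True
                    break
            if not bad:
                want.add(sg)
        assert got == want


class TestQuantification:
    def novel(self, s=1000, e=2000, strand="+"):
        from crypterm.antisense import NovelTranscript
        return [NovelTranscript(segment=seg(s, e, strand))]

    def covs(self, make_cov, depth, n=2):
        # library 1e6, read length 50, 1 kb segment: FPKM = 20 * depth
        out = []
        for i in range(n):
            out.append(make_cov(
                SIZES, [("chrI", "+", 1000, 2000, depth)],
                species_counts=ct.SpeciesCounts(primary_reads=10**6),
                sample_id=f"s{depth}_{i}"))
        return out

    def test_fold_change_with_pseudocount(self, make_cov):
        wt = self.covs(make_cov, 0.05)   # FPKM 1
        mut = self.covs(make_cov, 0.25)  # FPKM 5
        got = quantify_and_select(self.novel(), wt, mut, None, TH)
        assert len(got) == 1
        assert got[0].fpkm_mut == pytest.approx(5.0)
        assert got[0].fold_change == pytest.approx(5.1 / 1.1, abs=1e-6)

    def test_abundance_gate_rejects_regardless_of_fc(self, make_cov):
        wt = self.covs(make_cov, 0.001)
        mut = self.covs(make_cov, 0.045)  # FPKM 0.9, huge fold change
        assert quantify_and_select(self.novel(), wt, mut, None, TH) == []

    def test_equal_expression_rejected(self, make_cov):
        wt = self.covs(make_cov, 0.25)
        assert quantify_and_select(self.novel(), wt, wt, None, TH) == []

    def test_raising_thresholds_never_grows_selection(self, make_cov):
        wt = self.covs(make_cov, 0.06)
        mut = self.covs(make_cov, 0.30)
        base = quantify_and_select(self.novel(), wt, mut, None, TH)
        for tighter in (DiscoveryThresholds(min_fpkm=10.0),
                        DiscoveryThresholds(min_fc=6.0)):
            sub = quantify_and_select(self.novel(), wt, mut, None, tighter)
            assert {n.segment for n in sub} <= {n.segment for n in base}


class TestOrigin:
    def annot(self):
        return ct.GenomeAnnotation(SIZES, [
            # + TU with PAS at 10_000; - TU with TSS at 6_000
            ct.TranscriptionUnit("a", "chrI", 4000, 10_000, "+"),
            ct.TranscriptionUnit("b", "chrI", 2000, 6000, "-"),
        ])

    def classify(self, s, e, strand):
        from crypterm.antisense import NovelTranscript
        return classify_origin(NovelTranscript(segment=seg(s, e, strand)),
                               self.annot(), TH)

    def test_pas_proximal_is_terminator(self):
        nt = self.classify(9000, 10_250, "-")  # TSS at 10_250, 250 nt from PAS
        assert nt.origin == "terminator_proximal"
        assert nt.opposite_overlap

    def test_tss_proximal_when_pas_is_far(self):
        # + segment TSS at 5900: 100 nt from b's TSS, >300 from any PAS
        nt = self.classify(5900, 9400, "+")
        assert nt.origin == "promoter_proximal"

    def test_far_from_both_is_other(self):
        nt = self.classify(7500, 7800, "-")
        assert nt.origin == "other"

    def test_convergence_flag_follows_overlapped_tu(self):
        nt = self.classify(9000, 10_250, "-")
        # 'a' and 'b' are tandem-ish here, not convergent
        assert not nt.convergent_locus


class TestScreenAndLinkage:
    def test_log2_fold_change_example(self, make_cov):
        annot = ct.GenomeAnnotation(
            SIZES, [ct.TranscriptionUnit("g", "chrI", 1000, 2000, "+")])
        # antisense read-equivalents: WT 10, mutant 40 (value*1000/50)
        wt = [make_cov(SIZES, [("chrI", "-", 1000, 2000, 0.5)], sample_id=f"w{i}")
              for i in range(2)]
        mut = [make_cov(SIZES, [("chrI", "-", 1000, 2000, 2.0)], sample_id=f"m{i}")
               for i in range(2)]
        table = ct.antisense_count_screen(annot, {"g"}, wt, mut)
        row = table.loc["g"]
        assert row.log2_fc == pytest.approx(np.log2(41 / 11), abs=1e-6)
        assert row.up and not row.down

    def test_symmetric_counts_give_zero(self, make_cov):
        annot = ct.GenomeAnnotation(
            SIZES, [ct.TranscriptionUnit("g", "chrI", 1000, 2000, "+")])
        reps = [make_cov(SIZES, [("chrI", "-", 1000, 2000, 1.0)], sample_id=f"r{i}")
                for i in range(2)]
        table = ct.antisense_count_screen(annot, {"g"}, reps, reps)
        assert table.loc["g"].log2_fc == 0.0
        assert "median_log2_normalized" in table.attrs

    def test_flags_monotone_in_min_fc(self, sim_default):
        _, annot, _, covs = sim_default
        ids = annot.select_tus("nonoverlapping")
        t1 = ct.antisense_count_screen(annot, ids, covs["WT"], covs["mutant"],
                                       min_fc=1.5)
        t2 = ct.antisense_count_screen(annot, ids, covs["WT"], covs["mutant"],
                                       min_fc=3.0)
        assert set(t2.index[t2.up]) <= set(t1.index[t1.up])

    def test_linkage_rules(self):
        from crypterm.antisense import NovelTranscript
        annot = ct.GenomeAnnotation(SIZES, [
            ct.TranscriptionUnit("g", "chrI", 8000, 10_000, "+"),  # PAS 10_000
        ])
        mk = lambda s, e, strand: NovelTranscript(segment=seg(s, e, strand))
        linked = link_readthrough_antisense(
            [mk(10_050, 10_500, "+")], {"g"}, annot)
        assert linked.attrs["n_linked"] == 1
        for nt, why in ((mk(9500, 10_050, "-"), "wrong strand"),
                        (mk(10_400, 10_800, "+"), "distance 400")):
            out = link_readthrough_antisense([nt], {"g"}, annot)
            assert out.attrs["n_linked"] == 0, why
        # an uncalled gene never links
        out = link_readthrough_antisense([mk(10_050, 10_500, "+")], set(), annot)
        assert out.attrs["n_linked"] == 0
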