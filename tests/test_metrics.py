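import numpy as np
import pytest
from scipy import stats

import crypterm as ct
from crypterm.metrics import group_window_compare, site_window_stat

SIZES = {"chrI": 20_000}


def one_tu(start=1000, end=3000, strand="+"):
    return ct.TranscriptionUnit("g", "chrI", start, end, strand)


class TestTravelingRatio:
    def test_uniform_coverage_gives_zero(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "+", 1000, 3000, 4.0)])
        entry = ct.traveling_ratio(cov, one_tu(), pseudocount=0.0)
        assert entry.tr == 0.0
        assert not entry.excluded_short

    def test_four_to_one_occupancy_gives_two(self, make_cov):
        # 400 vs 100 read-equivalents in the 200-bp windows (read length 50)
        cov = make_cov(SIZES, [("chrI", "+", 1000, 1200, 100.0),
                               ("chrI", "+", 2800, 3000, 25.0)])
        entry = ct.traveling_ratio(cov, one_tu(), pseudocount=0.0)
        assert (entry.occ5, entry.occ3) == (400.0, 100.0)
        assert entry.tr == pytest.approx(2.0)

    def test_minus_strand_five_prime_bias_is_positive(self, make_cov):
        # 5' end of a minus-strand TU is its right boundary
        cov = make_cov(SIZES, [("chrI", "-", 2800, 3000, 50.0),
                               ("chrI", "-", 1000, 2800, 5.0)])
        entry = ct.traveling_ratio(cov, one_tu(strand="-"), pseudocount=0.0)
        assert entry.tr > 0

    def test_invariant_under_global_scaling(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "+", 1000, 1200, 9.0),
                               ("chrI", "+", 1200, 3000, 2.0)])
        e1 = ct.traveling_ratio(cov, one_tu(), pseudocount=0.0)
        e2 = ct.traveling_ratio(cov.scaled(7.0), one_tu(), pseudocount=0.0)
        assert e1.tr == pytest.approx(e2.tr)

    def test_short_tu_flagged_not_raised(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "+", 0, 400, 1.0)])
        tu = ct.TranscriptionUnit("s", "chrI", 100, 450, "+")
        entry = ct.traveling_ratio(cov, tu, window=200)
        assert entry.excluded_short and np.isnan(entry.tr)

    def test_batch_table_sorts_by_construction(self, sim_default, make_cov):
        _, annot, _, covs = sim_default
        table = ct.traveling_ratio_table(covs["WT"][0], annot)
        assert len(table) == len(annot)
        scored = table[~table.excluded_short]
        # cumulative distribution of tr is non-decreasing by construction
        cdf = np.sort(scored.tr.to_numpy())
        assert (np.diff(cdf) >= 0).all()


class TestMetagene:
    def test_bin_counts_follow_trim_rule(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "+", 0, 20_000, 1.0)])
        annot = ct.GenomeAnnotation(SIZES, [
            ct.TranscriptionUnit("a", "chrI", 6000, 7000, "+"),    # 1 kb body
            ct.TranscriptionUnit("b", "chrI", 9000, 13_600, "+"),  # 4.6 kb body
        ])
        mat = ct.metagene_matrix(cov, annot, tu_ids=["a"], flank=500, bin=10,
                                 trim=4500)
        assert mat.values.shape[1] == 200  # (500 + 1000 + 500) / 10
        mat = ct.metagene_matrix(cov, annot, tu_ids=["b"], flank=500, bin=10,
                                 trim=4500)
        assert mat.values.shape[1] == 550  # trimmed to 500 + 4500 + 500

    def test_constant_signal_gives_constant_medians(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "+", 0, 20_000, 2.5),
                               ("chrI", "-", 0, 20_000, 2.5)])
        annot = ct.GenomeAnnotation(SIZES, [
            ct.TranscriptionUnit("a", "chrI", 6000, 8000, "+"),
            ct.TranscriptionUnit("b", "chrI", 10_000, 12_000, "-"),
        ])
        mat = ct.metagene_matrix(cov, annot)
        assert np.allclose(mat.column_median(), 2.5)

    def test_rows_sorted_by_length_and_empty_set_rejected(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "+", 0, 20_000, 1.0)])
        annot = ct.GenomeAnnotation(SIZES, [
            ct.TranscriptionUnit("short", "chrI", 6000, 7000, "+"),
            ct.TranscriptionUnit("long", "chrI", 9000, 12_000, "+"),
        ])
        mat = ct.metagene_matrix(cov, annot)
        assert mat.tu_ids == ["long", "short"]
        with pytest.raises(ValueError):
            ct.metagene_matrix(cov, annot, tu_ids=[])


class TestScaledMetagene:
    def test_ramp_scales_zero_to_one(self):
        cov = ct.StrandedCoverage(SIZES, {("chrI", "+"): np.arange(20_000.0)})
        annot = ct.GenomeAnnotation(
            SIZES, [ct.TranscriptionUnit("a", "chrI", 1000, 3000, "+")])
        out = ct.scaled_metagene(cov, annot, nbins=50)
        row = out.loc["a"].to_numpy()
        assert row[0] == pytest.approx(0.0) and row[-1] == pytest.approx(1.0)
        assert (np.diff(row) >= 0).all()

    def test_constant_row_maps_to_zeros(self, make_cov):
        cov = make_cov(SIZES, [("chrI", "+", 1000, 3000, 7.0)])
        annot = ct.GenomeAnnotation(
            SIZES, [ct.TranscriptionUnit("a", "chrI", 1000, 3000, "+")])
        assert not ct.scaled_metagene(cov, annot, nbins=20).loc["a"].any()

    def test_rows_stay_inside_unit_interval(self, sim_default):
        _, annot, _, covs = sim_default
        ids = [t.id for t in annot.tus[:20]]
        out = ct.scaled_metagene(covs["mutant"][0], annot, tu_ids=ids, nbins=40)
        assert (out.to_numpy() >= 0).all() and (out.to_numpy() <= 1).all()
        # with bins at per-base resolution the scaled extrema are exact
        tu = annot[ids[0]]
        fine = ct.scaled_metagene(covs["mutant"][0], annot, tu_ids=[ids[0]],
                                  nbins=tu.length)
        row = fine.loc[ids[0]].to_numpy()
        assert row.min() == pytest.approx(0.0) and row.max() == pytest.approx(1.0)


class TestGroupCompare:
    def test_identical_paired_groups_give_adjusted_one(self):
        stat = {f"t{i}": float(i) for i in range(10)}
        ids = {f"t{i}" for i in range(10)}
        res = group_window_compare(stat, ids, ids, paired=True, n_comparisons=4)
        assert res.p_adjusted == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(2)
        stat = {f"t{i}": float(v) for i, v in enumerate(rng.normal(size=40))}
        a = {f"t{i}" for i in range(20)}
        b = {f"t{i}" for i in range(20, 40)}
        r1 = group_window_compare(stat, a, b, n_comparisons=1)
        r4 = group_window_compare(stat, a, b, n_comparisons=4)
        assert r4.p_adjusted == pytest.approx(min(1.0, r1.p_raw * 4))

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        va = rng.normal(10, 1, 100)
        vb = rng.normal(0, 1, 100)
        stat = {f"a{i}": v for i, v in enumerate(va)}
        stat.update({f"b{i}": v for i, v in enumerate(vb)})
        res = group_window_compare(
            stat, {f"a{i}" for i in range(100)}, {f"b{i}" for i in range(100)},
            n_comparisons=4)
        assert res.p_adjusted < 0.01

    def test_rank_sum_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(7)
        va = rng.normal(0.4, 1, 30)
        vb = rng.normal(0.0, 1, 30)
        stat = {f"a{i}": v for i, v in enumerate(va)}
        stat.update({f"b{i}": v for i, v in enumerate(vb)})
        res = group_window_compare(
            stat, {f"a{i}" for i in range(30)}, {f"b{i}" for i in range(30)})
        # oracle: permutation distribution of the U statistic, 1e4 draws
        pooled = np.concatenate([np.sort(va), np.sort(vb)])
        n1 = 30
        obs = stats.mannwhitneyu(pooled[:n1], pooled[n1:],
                                 alternative="two-sided").statistic
        center = n1 * (pooled.size - n1) / 2
        nperm, hits = 10_000, 0
        for _ in range(nperm):
            perm = rng.permutation(pooled)
            u = stats.mannwhitneyu(perm[:n1], perm[n1:],
                                   alternative="two-sided").statistic
            if abs(u - center) >= abs(obs - center):
                hits += 1
        p_perm = hits / nperm
        mc_err = 3 * np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / nperm)
        assert res.p_raw == pytest.approx(p_perm, abs=mc_err + 0.02)

    def test_small_groups_and_overlap_rejected(self):
        stat = {f"t{i}": float(i) for i in range(10)}
        with pytest.raises(ValueError, match="size"):
            group_window_compare(stat, {"t0", "t1"}, {"t2", "t3", "t4"})
        with pytest.raises(ValueError, match="disjoint"):
            group_window_compare(stat, {"t0", "t1", "t2"}, {"t2", "t3", "t4"})

    def test_control_sampler_size_and_exclusion(self, sim_default):
        _, annot, _, _ = sim_default
        rng = np.random.default_rng(0)
        exclude = {t.id for t in annot.tus[:50]}
        grp = ct.sample_control_group(annot, 100, rng, exclude=exclude)
        assert len(grp) == 100 and not (grp & exclude)

    def test_site_window_is_centered_on_the_site(self, make_cov):
        tu = ct.TranscriptionUnit("g", "chrI", 1000, 3000, "+")
        cov = make_cov(SIZES, [("chrI", "+", 925, 1075, 10.0)])
        # [TSS-75, TSS+75) captures the painted block exactly
        assert site_window_stat(cov, tu, "TSS", 150) == pytest.approx(
            150 * 10.0 / 50)
        assert site_window_stat(cov, tu, "PAS", 150) == 0.0
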