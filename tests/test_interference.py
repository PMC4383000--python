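"""CoC profiles, adjacent distances, density, strand categories, summaries."""

import collections
import math

import numpy as np
import pytest
from scipy import stats

from tetrakit import (
    MarkerMap,
    MeiosisParams,
    adjacent_co_distances,
    chromatid_interference_analysis,
    classify_strand_involvement,
    co_density,
    coc_profile,
    default_genome,
    simulate_tetrads,
    summarize_co_counts,
    two_group_t_from_summary,
)
from tetrakit.sim_meiosis import SK, ZH
from tetrakit.interference import StrandInconsistencyError
from tetrakit.tetrad_caller import CrossoverEvent


def ev(tetrad, chrom, mid, cells=(1, 3), reciprocal=True):
    return CrossoverEvent(tetrad=tetrad, chrom=chrom, left=max(mid - 1, 1),
                          right=mid + 1, carrier_cells=cells,
                          reciprocal=reciprocal)


def truth_events(truths):
    return [
        CrossoverEvent(tetrad=t.tetrad_id, chrom=c.chrom, left=max(c.pos - 1, 1),
                       right=c.pos + 1, carrier_cells=c.carrier_cells,
                       reciprocal=True)
        for t in truths
        for c in t.co_events
    ]


def truth_origins(truths, genome):
    return {
        (t.tetrad_id, c.name): {1: SK, 2: SK, 3: ZH, 4: ZH}
        for t in truths
        for c in genome
    }


def single_marker_map(genome):
    return MarkerMap({c.name: np.array([1]) for c in genome})


class TestCocProfile:
    def test_hand_computed_pair(self):
        """12 of 24 tetrads hit window A, 8 hit B, 5 hit both -> CoC 1.25."""
        genome = default_genome(1, 2_000_000)
        events = []
        for t in range(1, 25):
            if t <= 12:
                events.append(ev(t, "chr1", 500_000))
            if t <= 5 or 12 < t <= 15:
                events.append(ev(t, "chr1", 1_500_000))
        prof = coc_profile(events, genome, window=1_000_000, level="tetrad",
                           tetrads=range(1, 25))
        assert len(prof.pairs) == 1
        row = prof.pairs.iloc[0]
        assert row["q1"] == pytest.approx(12 / 24)
        assert row["q2"] == pytest.approx(8 / 24)
        assert row["d"] == pytest.approx(5 / 24)
        assert row["coc"] == pytest.approx((5 / 24) / ((12 / 24) * (8 / 24)))

    def test_empty_window_pairs_excluded_not_infinite(self):
        genome = default_genome(1, 3_000_000)
        events = [ev(1, "chr1", 500_000), ev(2, "chr1", 500_000)]
        prof = coc_profile(events, genome, window=1_000_000)
        assert len(prof.pairs) == 0

    def test_requires_two_tetrads(self):
        genome = default_genome(1, 2_000_000)
        with pytest.raises(ValueError):
            coc_profile([ev(1, "chr1", 100)], genome)

    def test_invalid_window(self):
        genome = default_genome(1, 2_000_000)
        with pytest.raises(ValueError):
            coc_profile([ev(1, "chr1", 1), ev(2, "chr1", 2)], genome, window=0)

    def test_null_simulation_mean_coc_near_one_both_levels(self):
        """Poisson crossovers without chromatid interference: CoC = 1."""
        genome = default_genome(2, 10_000_000)
        mm = single_marker_map(genome)
        params = MeiosisParams(co_mean_per_tetrad=8.0, gc_prob_per_co=0.0)
        reps = {"tetrad": [], "cell": []}
        for rep in range(6):
            truths = simulate_tetrads(genome, mm, params, 250, seed=400 + rep)
            events = truth_events(truths)
            for level in reps:
                reps[level].append(coc_profile(events, genome, level=level).mean_coc)
        for level, values in reps.items():
            mean = np.mean(values)
            se = np.std(values, ddof=1) / math.sqrt(len(values))
            assert abs(mean - 1.0) < 3 * se + 0.02, level

    def test_cell_to_tetrad_ratio_tracks_strand_reuse(self):
        """Isolating two-crossover bivalents, CoC_cell/CoC_tetrad equals
        2*f2 + f3 from the chromatid-reuse closed form."""
        genome = default_genome(2, 20_000_000)
        mm = single_marker_map(genome)
        for r, predicted in ((0.1, 0.2), (0.5, 1.0), (0.9, 1.8)):
            ratios = []
            for rep in range(6):
                params = MeiosisParams(
                    co_mean_per_tetrad=4.0, gc_prob_per_co=0.0,
                    reuse_prob_sk=r, reuse_prob_zh=r,
                )
                truths = simulate_tetrads(genome, mm, params, 350,
                                          seed=600 + 10 * rep)
                events = truth_events(truths)
                by = collections.defaultdict(list)
                for e in events:
                    by[(e.tetrad, e.chrom)].append(e)
                kept = [
                    e
                    for es in by.values()
                    if len(es) == 2
                    and es[0].midpoint // 10**6 != es[1].midpoint // 10**6
                    for e in es
                ]
                ratio = (
                    coc_profile(kept, genome, level="cell").mean_coc
                    / coc_profile(kept, genome, level="tetrad").mean_coc
                )
                ratios.append(ratio)
            mean = np.mean(ratios)
            se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
            assert abs(mean - predicted) < 3 * se + 0.02, f"r={r}"

    def test_nonuniform_placement_inflates_long_range_coc(self):
        """Recombination-active regions without interference push the
        distance-aggregated CoC above 1 (negative-interference signature)."""
        length = 20_000_000
        genome = default_genome(1, length)
        mm = single_marker_map(genome)
        hot = {
            "chr1": (
                [0, 5e6, 10e6, 15e6, length],
                [4.0, 0.25, 4.0, 0.25],
            )
        }
        params = MeiosisParams(co_mean_per_tetrad=3.0, gc_prob_per_co=0.0,
                               rate_map=hot)
        truths = simulate_tetrads(genome, mm, params, 400, seed=31)
        prof = coc_profile(truth_events(truths), genome, level="tetrad")
        far = prof.by_distance[prof.by_distance["distance"] >= 8_000_000]
        assert far["mean_coc"].mean() > 1.05


class TestDistancesAndDensity:
    def test_adjacent_distances(self):
        events = [ev(1, "chr1", 10_000_000), ev(1, "chr1", 25_000_000),
                  ev(1, "chr1", 60_000_000), ev(1, "chr2", 1_000_000)]
        out = adjacent_co_distances(events)
        assert out["distance"].tolist() == [15_000_000, 35_000_000]

    def test_single_co_gives_no_distance(self):
        out = adjacent_co_distances([ev(1, "chr1", 5_000)])
        assert len(out) == 0

    def test_renewal_mode_near_mean_with_strong_interference(self):
        """Gamma shape 5 concentrates adjacent-CO distances near the mean."""
        genome = default_genome(1, 50_000_000)
        mm = single_marker_map(genome)
        params = MeiosisParams(co_mean_per_tetrad=5.0, interference_shape=5.0,
                               gc_prob_per_co=0.0)
        truths = simulate_tetrads(genome, mm, params, 400, seed=8)
        d = adjacent_co_distances(truth_events(truths))["distance"].to_numpy()
        mean_gap = 10_000_000  # 50 Mb / 5 expected crossovers
        hist, edges = np.histogram(d, bins=np.arange(0, 5e7, 2.5e6))
        mode_bin = edges[np.argmax(hist)]
        assert 0.5 * mean_gap <= mode_bin <= 1.5 * mean_gap
        # and the dispersion is far below the exponential (shape-1) case
        assert d.std() / d.mean() < 0.75

    def test_density_counts_and_conservation(self):
        genome = default_genome(1, 9_000_000)
        events = [ev(1, "chr1", 1_000), ev(1, "chr1", 2_000_000),
                  ev(2, "chr1", 2_500_000), ev(2, "chr1", 8_999_999)]
        table = co_density(events, genome, window=3_000_000)
        assert table["count"].sum() == len(events)
        assert table.iloc[0]["count"] == 3

    def test_uniform_placement_poisson_dispersion(self):
        genome = default_genome(1, 30_000_000)
        mm = single_marker_map(genome)
        params = MeiosisParams(co_mean_per_tetrad=6.0, gc_prob_per_co=0.0)
        truths = simulate_tetrads(genome, mm, params, 200, seed=15)
        counts = co_density(truth_events(truths), genome, window=3_000_000)["count"]
        # index of dispersion test: var/mean ~ chi2_{n-1}/(n-1) under Poisson
        n = len(counts)
        disp = (n - 1) * counts.var(ddof=1) / counts.mean()
        p = 1 - stats.chi2.cdf(disp, n - 1)
        assert p > 0.01


ORIGINS = {1: SK, 2: SK, 3: ZH, 4: ZH}


class TestClassifyStrandInvolvement:
    def test_same_carriers_two_chromatids(self):
        assert classify_strand_involvement(
            ev(1, "chr1", 100, (1, 3)), ev(1, "chr1", 200, (1, 3)), ORIGINS
        ) == "2chr"

    def test_disjoint_carriers_four_chromatids(self):
        assert classify_strand_involvement(
            ev(1, "chr1", 100, (1, 3)), ev(1, "chr1", 200, (2, 4)), ORIGINS
        ) == "4chr"

    def test_shared_sk_cell_three_chromatids_sk(self):
        assert classify_strand_involvement(
            ev(1, "chr1", 100, (1, 3)), ev(1, "chr1", 200, (1, 4)), ORIGINS
        ) == "3chr_SK"

    def test_shared_zh_cell_three_chromatids_zh(self):
        assert classify_strand_involvement(
            ev(1, "chr1", 100, (1, 3)), ev(1, "chr1", 200, (2, 3)), ORIGINS
        ) == "3chr_Zh"

    def test_mixed_tetrads_rejected(self):
        with pytest.raises(ValueError):
            classify_strand_involvement(
                ev(1, "chr1", 100), ev(2, "chr1", 200), ORIGINS
            )

    def test_inconsistent_three_cell_origins_rejected(self):
        bad = {1: SK, 2: SK, 3: SK, 4: ZH}
        with pytest.raises(StrandInconsistencyError):
            classify_strand_involvement(
                ev(1, "chr1", 100, (1, 2)), ev(1, "chr1", 200, (1, 3)), bad
            )


class TestChromatidInterference:
    def test_hand_computed_gof(self):
        """Counts (65, 81, 71, 64): chi-square 2.60, df 3, p 0.457."""
        chi2, p = stats.chisquare([65, 81, 71, 64])
        assert chi2 == pytest.approx(2.601, abs=0.01)
        assert p == pytest.approx(0.457, abs=0.005)

    def _analysis(self, r_sk=0.5, r_zh=0.5, n_tetrads=60, seed=3, **kw):
        genome = default_genome(6, 5_000_000)
        mm = single_marker_map(genome)
        params = MeiosisParams(co_mean_per_tetrad=24.0, gc_prob_per_co=0.0,
                               reuse_prob_sk=r_sk, reuse_prob_zh=r_zh)
        truths = simulate_tetrads(genome, mm, params, n_tetrads, seed=seed)
        events = truth_events(truths)
        origins = truth_origins(truths, genome)
        return chromatid_interference_analysis(events, genome, origins, **kw)

    def test_no_reuse_bias_passes_uniform_gof(self):
        res = self._analysis(level=2, seed=3)
        assert sum(res.counts.values()) > 500
        assert res.pvalue > 0.01

    def test_strong_reuse_bias_detected(self):
        res = self._analysis(r_sk=0.9, r_zh=0.9, level=2, seed=4)
        assert res.pvalue < 1e-6
        assert res.counts["2chr"] > res.counts["4chr"]

    def test_bootstrap_shape_and_determinism(self):
        res_a = self._analysis(level=2, seed=5, n_boot=25, boot_k=15)
        res_b = self._analysis(level=2, seed=5, n_boot=25, boot_k=15)
        assert len(res_a.bootstrap) == 25
        assert res_a.bootstrap.equals(res_b.bootstrap)
        summary = res_a.bootstrap_summary()
        assert set(summary["category"]) == {"2chr", "3chr_SK", "3chr_Zh", "4chr"}

    def test_bootstrap_of_identical_subsample_has_zero_sd(self):
        res = self._analysis(level=2, n_tetrads=15, boot_k=15, n_boot=10)
        assert (res.bootstrap_summary()["sd"] == 0).all()

    def test_degenerate_all_2chr(self):
        genome = default_genome(1, 2_000_000)
        events = []
        for t in range(1, 11):
            events += [ev(t, "chr1", 200_000, (1, 3)), ev(t, "chr1", 1_500_000, (1, 3))]
        origins = {(t, "chr1"): ORIGINS for t in range(1, 11)}
        res = chromatid_interference_analysis(events, genome, origins, level=1,
                                              n_boot=10, boot_k=5, seed=1)
        assert res.counts == {"2chr": 10, "3chr_SK": 0, "3chr_Zh": 0, "4chr": 0}
        assert res.pvalue < 1e-4

    def test_no_eligible_pairs_warns_empty(self):
        genome = default_genome(1, 2_000_000)
        events = [ev(1, "chr1", 100_000)]
        res = chromatid_interference_analysis(events, genome, {}, level=2)
        assert sum(res.counts.values()) == 0
        assert math.isnan(res.pvalue)


class TestSummarizeCoCounts:
    def test_pooled_t_from_printed_summaries(self):
        """n=7 31.6+-5.6 vs n=17 41.4+-5.0: t 4.22, two-sided p 3.4e-4."""
        t, p = two_group_t_from_summary(7, 31.6, 5.6, 17, 41.4, 5.0)
        assert t == pytest.approx(4.22, abs=0.01)
        assert p == pytest.approx(3.4e-4, rel=0.05)

    def test_identical_groups_give_f_near_zero(self):
        events = [ev(t, "chr1", 100_000 * k) for t in (1, 2, 3, 4) for k in (1, 2)]
        groups = {1: "a", 2: "a", 3: "b", 4: "b"}
        out = summarize_co_counts(events, groups)
        assert out.f_stat == pytest.approx(0.0)

    def test_per_cell_counts_sum_to_twice_tetrad_count(self, sim_truth):
        events = truth_events(sim_truth)
        out = summarize_co_counts(events)
        merged = out.per_cell.groupby("tetrad")["n_cos"].sum()
        for row in out.per_tetrad.itertuples():
            assert merged[row.tetrad] == 2 * row.n_cos

    def test_single_group_skips_test(self):
        events = [ev(1, "chr1", 100), ev(2, "chr1", 200)]
        out = summarize_co_counts(events)
        assert math.isnan(out.pvalue)
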