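"""QTL-seq statistics: filtering, null bands, P values, windows, regions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from plexqtl.genetics import CrossSpec, progeny_dosage_distribution
from plexqtl.core import (
    NullThresholds,
    PlexityFilterConfig,
    call_candidate_regions,
    compute_variant_stats,
    build_null_thresholds,
    filter_donor_variants,
    run_both_orientations,
    run_qtlseq,
    simulate_index_range_coverage,
    simulate_null_observations,
    sliding_window_stats,
)
from plexqtl.simulate import GenomeSpec, simulate_bsa_dataset


def make_observation(p1=(60, 0), p2=(45, 15), b1=(53, 7), b2=(52, 8), **kwargs):
    row = {
        "chrom": "chr01", "pos": 1000, "ref": "A", "alt": "T",
        "p1_ref": p1[0], "p1_alt": p1[1], "p2_ref": p2[0], "p2_alt": p2[1],
        "bulk1_ref": b1[0], "bulk1_alt": b1[1], "bulk2_ref": b2[0], "bulk2_alt": b2[1],
    }
    row.update(kwargs)
    return pd.DataFrame([row])


class TestFilter:
    def test_simplex_variant_kept(self):
        obs = make_observation(p2=(45, 15))  # donor index 0.25
        kept = filter_donor_variants(obs, PlexityFilterConfig(nplex=1), donor="P2")
        assert len(kept) == 1
        assert kept.loc[0, "plexity"] == 1

    def test_duplex_index_rejected_as_simplex_kept_as_duplex(self):
        obs = make_observation(p2=(30, 30))  # donor index 0.50
        assert filter_donor_variants(obs, PlexityFilterConfig(nplex=1), "P2").empty
        assert len(filter_donor_variants(obs, PlexityFilterConfig(nplex=2), "P2")) == 1

    def test_min_depth_applies_to_every_sample(self):
        # shrink one sample to total depth 39, preserving its SNP-index
        shallow = {"p1": (39, 0), "p2": (29, 10), "bulk1": (34, 5), "bulk2": (34, 5)}
        for sample, depths in shallow.items():
            obs = make_observation(p2=(90, 30))  # donor index 0.25 at depth 120
            obs[f"{sample}_ref"], obs[f"{sample}_alt"] = depths
            kept = filter_donor_variants(obs, PlexityFilterConfig(nplex=1), "P2")
            assert kept.empty, f"{sample} below minimum depth must reject the variant"

    def test_non_donor_parent_must_be_nulliplex(self):
        obs = make_observation(p1=(58, 2))  # two ALT reads in the other parent
        assert filter_donor_variants(obs, PlexityFilterConfig(nplex=1), "P2").empty

    def test_range_endpoints_inclusive(self):
        obs = make_observation(p2=(90, 10))  # index exactly 0.10
        assert len(filter_donor_variants(obs, PlexityFilterConfig(nplex=1), "P2")) == 1

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            filter_donor_variants(
                pd.DataFrame({"chrom": [], "pos": []}), PlexityFilterConfig(), "P2"
            )


class TestIndexRangeCoverage:
    def test_exact_binomial_coverage_at_depth_40(self):
        # sum of Binomial(40, 0.25) pmf over k = 4..14
        cov = simulate_index_range_coverage(CrossSpec(4, 1), 40, (0.10, 0.36))
        oracle = binom.pmf(np.arange(4, 15), 40, 0.25).sum()
        assert cov == pytest.approx(oracle, abs=1e-12)
        assert 0.94 <= cov <= 0.95

    def test_monte_carlo_agrees_with_exact(self):
        exact = simulate_index_range_coverage(CrossSpec(4, 2), 40, (0.37, 0.63))
        mc = simulate_index_range_coverage(
            CrossSpec(4, 2), 40, (0.37, 0.63), replicates=100_000, seed=1
        )
        assert abs(mc - exact) < 3 * np.sqrt(exact * (1 - exact) / 100_000)

    def test_concentration_at_large_depth(self):
        assert simulate_index_range_coverage(CrossSpec(4, 1), 10_000, (0.10, 0.36)) > 0.9999

    def test_full_range_is_certain(self):
        assert simulate_index_range_coverage(CrossSpec(4, 1), 40, (0.0, 1.0)) == pytest.approx(1.0)


class TestNullThresholds:
    def test_bands_symmetric_for_exchangeable_bulks(self):
        thr = NullThresholds(CrossSpec(4, 1), 18, 18, 50_000, seed=2)
        band = thr.for_depths(60, 60)
        assert band["lower95"] <= 0 <= band["upper95"]
        assert band["lower99"] <= band["lower95"] <= band["upper95"] <= band["upper99"]
        assert abs(band["upper95"] + band["lower95"]) < 0.02
        assert abs(band["upper99"] + band["lower99"]) < 0.03

    def test_bands_narrow_with_depth(self):
        thr = NullThresholds(CrossSpec(4, 1), 18, 18, 100_000, seed=3)
        shallow = thr.for_depths(40, 40)
        deep = thr.for_depths(400, 400)
        assert deep["upper99"] < shallow["upper99"]
        assert deep["lower99"] > shallow["lower99"]

    def test_duplex_bands_wider_than_simplex(self):
        simplex = NullThresholds(CrossSpec(4, 1), 18, 18, 50_000, seed=4).for_depths(60, 60)
        duplex = NullThresholds(CrossSpec(4, 2), 18, 18, 50_000, seed=4).for_depths(60, 60)
        assert duplex["upper99"] > simplex["upper99"]

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            NullThresholds(CrossSpec(4, 1), 18, 18, replicates=500)

    def test_builder_precomputes_requested_pairs(self):
        thr = build_null_thresholds(CrossSpec(4, 1), 18, 18, [(40, 40), (60, 80)], 2000, seed=5)
        assert (40, 40) in thr._bands and (60, 80) in thr._bands


def exact_null_delta_distribution(cross, n1, n2, d1, d2):
    """Full enumeration of the null ΔSNP-index for tiny bulks and depths."""
    dist = progeny_dosage_distribution(cross)
    deltas: dict[float, float] = {}

    def bulk_fraction_dist(n):
        out: dict[float, float] = {}
        for combo in itertools.product(sorted(dist), repeat=n):
            p = np.prod([dist[g] for g in combo])
            f = sum(combo) / (cross.ploidy * n)
            out[f] = out.get(f, 0.0) + p
        return out

    f1d, f2d = bulk_fraction_dist(n1), bulk_fraction_dist(n2)
    for f1, pf1 in f1d.items():
        for k1 in range(d1 + 1):
            pk1 = pf1 * binom.pmf(k1, d1, f1)
            for f2, pf2 in f2d.items():
                for k2 in range(d2 + 1):
                    delta = k1 / d1 - k2 / d2
                    deltas[round(delta, 12)] = deltas.get(round(delta, 12), 0.0) + (
                        pk1 * pf2 * binom.pmf(k2, d2, f2)
                    )
    return deltas


class TestPValues:
    def test_delta_and_direction(self):
        obs = make_observation(b1=(43, 15), b2=(60, 0))  # bulk1 index 0.259, bulk2 0
        thr = NullThresholds(CrossSpec(4, 1), 18, 18, 5000, seed=6)
        stats = compute_variant_stats(obs, thr)
        assert stats.loc[0, "delta_index"] == pytest.approx(15 / 58, abs=1e-12)
        assert stats.loc[0, "direction"] == "positive"

    def test_zero_delta_is_unclassified(self):
        obs = make_observation(b1=(53, 7), b2=(53, 7))
        thr = NullThresholds(CrossSpec(4, 1), 18, 18, 5000, seed=7)
        stats = compute_variant_stats(obs, thr)
        assert stats.loc[0, "delta_index"] == 0
        assert stats.loc[0, "significance"] == "none"
        assert stats.loc[0, "direction"] == "none"

    def test_significance_boundary_is_inclusive(self):
        # craft a null |Δ| sample so the observed variant lands exactly on
        # the P = 0.05 boundary: 49 null values at or above it, R = 1000,
        # P = (49 + 1)/(1000 + 1) <= 0.05 -> classed P95
        thr = NullThresholds(CrossSpec(4, 1), 2, 2, 1000, seed=8)
        thr._bands[(60, 60)] = {
            "lower99": -0.5, "lower95": -0.3, "upper95": 0.3, "upper99": 0.5,
            "sorted_abs": np.concatenate([np.linspace(0, 0.2, 951), np.full(49, 0.25)]),
        }
        obs = make_observation(b1=(45, 15), b2=(60, 0))  # delta exactly 0.25
        stats = compute_variant_stats(obs, thr)
        assert stats.loc[0, "p_value"] == pytest.approx(50 / 1001)
        assert stats.loc[0, "significance"] == "P95"
        # one more tying null value pushes P just past 0.05 -> not significant
        thr._bands[(60, 60)]["sorted_abs"] = np.concatenate(
            [np.linspace(0, 0.2, 950), np.full(50, 0.25)]
        )
        assert compute_variant_stats(obs, thr).loc[0, "significance"] == "none"

    def test_p_value_matches_exact_enumeration(self):
        cross = CrossSpec(4, 1)
        n1 = n2 = 2
        d1 = d2 = 10
        exact = exact_null_delta_distribution(cross, n1, n2, d1, d2)
        R = 200_000
        thr = NullThresholds(cross, n1, n2, R, seed=9)
        for b1_alt, b2_alt in [(5, 0), (3, 1), (0, 0)]:
            obs = make_observation(b1=(d1 - b1_alt, b1_alt), b2=(d2 - b2_alt, b2_alt))
            got = compute_variant_stats(obs, thr).loc[0, "p_value"]
            delta = abs(b1_alt / d1 - b2_alt / d2)
            p_exact = sum(p for d, p in exact.items() if abs(d) >= delta - 1e-9)
            se = np.sqrt(p_exact * (1 - p_exact) / R)
            assert abs(got - p_exact) < 4 * se + 2 / R

    def test_zero_bulk_depth_raises(self):
        obs = make_observation(b1=(0, 0))
        thr = NullThresholds(CrossSpec(4, 1), 18, 18, 5000, seed=10)
        with pytest.raises(ValueError):
            compute_variant_stats(obs, thr)


def make_stats_frame(positions, chrom="chr01", significance="none", direction="none"):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chrom, "pos": positions, "bulk1_index": 0.125, "bulk2_index": 0.125,
            "delta_index": 0.0 if direction == "none" else (0.2 if direction == "positive" else -0.2),
            "p_value": 0.5, "significance": significance, "direction": direction,
        }
    )


class TestSlidingWindows:
    def test_single_variant_covered_by_five_windows(self):
        stats = make_stats_frame([150_000])
        windows = sliding_window_stats(stats, {"chr01": 300_000})
        covering = windows[windows["n_variants"] > 0]
        assert len(covering) == 5
        assert covering["start"].tolist() == [60_001, 80_001, 100_001, 120_001, 140_001]

    def test_no_variants_all_windows_empty(self):
        windows = sliding_window_stats(make_stats_frame([]), {"chr01": 200_000})
        assert (windows["n_variants"] == 0).all()
        assert windows["mean_delta_index"].isna().all()

    def test_all_significant_positive_variants_counted(self):
        stats = make_stats_frame([10_000, 20_000, 30_000], significance="P99",
                                 direction="positive")
        windows = sliding_window_stats(stats, {"chr01": 120_000})
        covered = windows[windows["n_variants"] > 0]
        assert (covered["p99_pos"] == covered["n_variants"]).all()
        assert (covered["p95_pos"] == covered["n_variants"]).all()  # P99 implies beyond P95
        assert (covered["p99_neg"] == 0).all()

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_stats(make_stats_frame([100]), {"chr01": 1000},
                                 window_size=100, step=200)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        length=st.integers(50_000, 400_000),
        positions=st.lists(st.integers(1, 400_000), min_size=0, max_size=40),
        window=st.sampled_from([50_000, 100_000]),
        step=st.sampled_from([10_000, 20_000, 50_000]),
    )
    def test_counts_match_brute_force(self, length, positions, window, step):
        positions = sorted(p for p in positions if p <= length)
        stats = make_stats_frame(positions)
        windows = sliding_window_stats(stats, {"chr01": length}, window, step)
        for _, w in windows.iterrows():
            lo, hi = w["start"], w["end"]  # 1-based inclusive
            brute = sum(1 for p in positions if lo <= p <= hi)
            assert w["n_variants"] == brute
        # every variant covered by at least one window
        assert windows["end"].max() >= length if len(windows) else length == 0


class TestCandidateRegions:
    def window_row(self, start, p99_pos, p99_neg, chrom="chr01"):
        return {
            "chrom": chrom, "start": start, "end": start + 99_999, "n_variants": 300,
            "p95_pos": p99_pos, "p95_neg": p99_neg, "p99_pos": p99_pos, "p99_neg": p99_neg,
        }

    def test_one_directional_excess_qualifies(self):
        windows = pd.DataFrame([self.window_row(1, 120, 5)])
        regions = call_candidate_regions(windows)
        assert len(regions) == 1
        assert regions.loc[0, "direction"] == "positive"

    def test_both_directions_hot_rejected(self):
        windows = pd.DataFrame([self.window_row(1, 120, 110)])
        assert call_candidate_regions(windows).empty

    def test_threshold_is_strict(self):
        windows = pd.DataFrame([self.window_row(1, 100, 0)])
        assert call_candidate_regions(windows).empty

    def test_overlapping_windows_merge(self):
        windows = pd.DataFrame([
            self.window_row(1, 150, 0),
            self.window_row(20_001, 130, 0),
            self.window_row(500_001, 200, 1),
        ])
        regions = call_candidate_regions(windows)
        assert len(regions) == 2
        assert regions.loc[0, "start"] == 1 and regions.loc[0, "end"] == 120_000
        assert regions.loc[0, "peak_p99_count"] == 150

    def test_opposite_directions_do_not_merge(self):
        windows = pd.DataFrame([
            self.window_row(1, 150, 0),
            {**self.window_row(20_001, 0, 0), "p99_neg": 130},
        ])
        regions = call_candidate_regions(windows)
        assert len(regions) == 2


class TestOrientations:
    def test_label_swap_is_involution(self):
        genome = GenomeSpec((("chr01", 300_000),), 4.0, 2e-3)
        ds = simulate_bsa_dataset(genome, qtl_plexity=1, plexity_mix={1: 1.0}, seed=40)
        obs = ds.observations
        swapped = obs.rename(columns={
            "p1_ref": "p2_ref", "p1_alt": "p2_alt", "p2_ref": "p1_ref", "p2_alt": "p1_alt",
        })
        config = PlexityFilterConfig(nplex=1)
        kwargs = dict(chrom_lengths={"chr01": 300_000}, replicates=2000, seed=41)
        a = run_qtlseq(obs, config, donor="P2", **kwargs)
        b = run_qtlseq(swapped, config, donor="P1", **kwargs)
        cols = ["chrom", "pos", "delta_index", "p_value", "significance", "direction"]
        pd.testing.assert_frame_equal(
            a.variants[cols].reset_index(drop=True), b.variants[cols].reset_index(drop=True)
        )

    def test_both_orientations_runs_p1_and_p2(self):
        cross = CrossSpec(4, 1)
        obs = simulate_null_observations(cross, 200, 18, 18, 60, seed=42)
        results = run_both_orientations(
            obs, PlexityFilterConfig(nplex=1), replicates=2000, seed=43
        )
        assert set(results) == {"P1", "P2"}
        assert len(results["P2"].variants) > 0
        assert results["P1"].variants.empty  # P1 is nulliplex in these data


def test_null_observations_all_pass_filter():
    cross = CrossSpec(4, 2)
    obs = simulate_null_observations(cross, 500, 18, 18, 60, seed=44)
    kept = filter_donor_variants(obs, PlexityFilterConfig(nplex=2), "P2")
    # parents are read at the exact expected index, so nearly all variants pass
    assert len(kept) > 450
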