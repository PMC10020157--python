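"""Virtual-4C pipeline: counting, proportional binning, smoothing, scaling."""

import numpy as np
import pytest

from chicsv.hic_sim import ContactPairSet
from chicsv.locus_sv import GenomicInterval, digest
from chicsv.virtual4c import (
    PROFILE_SCALE_TOTAL,
    BinnedProfile,
    FragmentCountProfile,
    Viewpoint,
    bin_1kb,
    count_by_fragment,
    integrate,
    merge_replicates,
    scale_profile,
    smooth,
    viewpoint_profile,
)


REGION = GenomicInterval("chrT", 0, 20_000)


def make_pairs(rows):
    cols = list(zip(*rows)) if rows else [[]] * 6
    return ContactPairSet(*[np.asarray(c, dtype=np.int64) for c in cols])


@pytest.fixture
def rm20():
    """20 fragments of 1 kb (fragment-aligned to the grid)."""
    return digest(list(range(1000, 20_000, 1000)), "GATC", REGION)


@pytest.fixture
def vp(rm20):
    return Viewpoint(GenomicInterval("chrT", 5000, 6000), "vp")


class TestCountByFragment:
    def test_both_ends_in_viewpoint_excluded(self, rm20, vp):
        ps = make_pairs([(5100, 5900, 0, 0, 60, 60)])
        fc = count_by_fragment(ps, vp, rm20)
        assert fc.total_qualifying == 0
        assert fc.counts.sum() == 0

    def test_one_end_in_viewpoint_counts_distal_fragment(self, rm20, vp):
        ps = make_pairs([(5500, 7300, 0, 0, 60, 60)])
        fc = count_by_fragment(ps, vp, rm20)
        assert fc.counts[7] == 1 and fc.total_qualifying == 1

    def test_low_mapq_pair_skipped(self, rm20, vp):
        ps = make_pairs([(5500, 7300, 0, 0, 60, 29)])
        assert count_by_fragment(ps, vp, rm20).total_qualifying == 0

    def test_totals_match_independent_predicate_loop(self, rm20, vp):
        rng = np.random.default_rng(1)
        n = 10_000
        p1 = rng.integers(0, 20_000, n)
        p2 = rng.integers(0, 20_000, n)
        q1 = rng.choice([10, 60], n)
        q2 = rng.choice([10, 60], n)
        ps = ContactPairSet(p1, p2, np.zeros(n), np.zeros(n), q1, q2)
        fc = count_by_fragment(ps, vp, rm20)
        # oracle: per-pair predicate loop (viewpoint fragment == bases
        # 5000-5999 here, so no distal end can land in it)
        expected = sum(
            1 for a, b, qa, qb in zip(p1, p2, q1, q2)
            if min(qa, qb) >= 30 and ((5000 <= a < 6000) != (5000 <= b < 6000)))
        assert fc.total_qualifying == expected
        assert fc.counts.sum() == expected

    def test_viewpoint_fragments_carry_no_counts(self, rm20):
        # viewpoint straddles a fragment edge: both touched fragments stay 0
        vp2 = Viewpoint(GenomicInterval("chrT", 4500, 5500), "straddle")
        ps = make_pairs([(4700, 5800, 0, 0, 60, 60),   # distal in vp fragment
                         (4700, 9500, 0, 0, 60, 60)])  # distal far away
        fc = count_by_fragment(ps, vp2, rm20)
        assert fc.counts[4] == 0 and fc.counts[5] == 0
        assert fc.counts[9] == 1 and fc.total_qualifying == 1

    def test_viewpoint_outside_region_rejected(self, rm20):
        with pytest.raises(ValueError):
            count_by_fragment(make_pairs([]),
                              Viewpoint(GenomicInterval("chrT", 19_000, 21_000)),
                              rm20)


class TestBin1kb:
    def test_fragment_within_one_bin(self, rm20, vp):
        fc = FragmentCountProfile(np.zeros(20), vp, 5)
        fc.counts[7] = 5
        bp = bin_1kb(fc, rm20, 1000)
        assert bp.values[7] == 5.0 and bp.values.sum() == 5.0

    def test_proportional_split_across_bins(self):
        region = GenomicInterval("chrT", 0, 3000)
        rm = digest([500, 2000], "GATC", region)  # fragment [500,2000)
        fc = FragmentCountProfile(np.array([0.0, 3.0, 0.0]),
                                  Viewpoint(GenomicInterval("chrT", 0, 100)), 3)
        bp = bin_1kb(fc, rm, 1000)
        assert bp.values[0] == pytest.approx(1.0)
        assert bp.values[1] == pytest.approx(2.0)

    def test_matches_per_base_spreading_oracle(self):
        region = GenomicInterval("chrT", 0, 10_000)
        rng = np.random.default_rng(2)
        cuts = np.unique(rng.integers(1, 10_000, 15))
        rm = digest(cuts, "GATC", region)
        counts = rng.integers(0, 20, rm.n_fragments).astype(float)
        fc = FragmentCountProfile(counts, Viewpoint(GenomicInterval("chrT", 0, 1)),
                                  int(counts.sum()))
        bp = bin_1kb(fc, rm, 1000)
        # oracle: distribute each fragment's count uniformly base by base
        per_base = np.zeros(10_000)
        for f, c in zip(rm.fragments, counts):
            per_base[f.start:f.end] += c / len(f)
        oracle = per_base.reshape(10, 1000).sum(axis=1)
        assert np.allclose(bp.values, oracle, atol=1e-12)
        assert bp.values.sum() == pytest.approx(counts.sum(), abs=1e-12)


class TestSmooth:
    def test_constant_profile_unchanged(self):
        bp = BinnedProfile(REGION, 1000, np.full(20, 3.5), "binned")
        assert np.allclose(smooth(bp, 5000).values, 3.5)

    def test_unit_impulse_spreads_to_five_bins(self):
        vals = np.zeros(20)
        vals[10] = 1.0
        sm = smooth(BinnedProfile(REGION, 1000, vals, "binned"), 5000)
        assert np.allclose(sm.values[8:13], 0.2)
        assert sm.values[7] == 0 and sm.values[13] == 0

    def test_interior_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 10, 20)
        sm = smooth(BinnedProfile(REGION, 1000, vals, "binned"), 5000)
        for k in range(2, 18):
            assert sm.values[k] == pytest.approx(vals[k - 2:k + 3].mean())
        # edge windows shrink to the bins present
        assert sm.values[0] == pytest.approx(vals[:3].mean())

    def test_window_below_grid_rejected(self):
        bp = BinnedProfile(REGION, 1000, np.zeros(20), "binned")
        with pytest.raises(ValueError):
            smooth(bp, 500)


class TestScaleAndIntegrate:
    def test_eligible_sum_is_exactly_1000(self, rm20, vp):
        rng = np.random.default_rng(4)
        bp = BinnedProfile(REGION, 1000, rng.uniform(0, 5, 20), "smoothed")
        prof = scale_profile(bp, REGION, vp, margin=2000)
        eligible = np.ones(20, bool)
        eligible[3:8] = False  # vp 5000-6000 +/- 2 kb
        assert prof.values[eligible].sum() == pytest.approx(
            PROFILE_SCALE_TOTAL, rel=1e-9)

    def test_uniform_profile_closed_form_factor(self, vp):
        region = GenomicInterval("chrT", 0, 120_000)
        u = 2.5
        bp = BinnedProfile(region, 1000, np.full(120, u), "smoothed")
        vp_far = Viewpoint(GenomicInterval("chrT", 110_000, 111_000))
        enriched = GenomicInterval("chrT", 0, 100_000)
        prof = scale_profile(bp, enriched, vp_far, margin=5000)
        assert prof.scale_factor == pytest.approx(1000 / (100 * u))

    def test_profile_already_at_1000_unchanged(self, rm20, vp):
        vals = np.zeros(20)
        vals[15] = 1000.0
        bp = BinnedProfile(REGION, 1000, vals, "smoothed")
        prof = scale_profile(bp, REGION, vp, margin=2000)
        assert prof.scale_factor == 1.0
        assert np.array_equal(prof.values, vals)

    def test_zero_signal_rejected(self, rm20, vp):
        bp = BinnedProfile(REGION, 1000, np.zeros(20), "smoothed")
        with pytest.raises(ValueError, match="no signal"):
            scale_profile(bp, REGION, vp)

    def test_integrate_full_eligible_region_gives_1000(self, rm20, vp):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 5, 20)
        vals[3:8] = 0.0  # nothing near the viewpoint
        bp = BinnedProfile(REGION, 1000, vals, "smoothed")
        prof = scale_profile(bp, REGION, vp, margin=2000)
        assert integrate(prof, REGION) == pytest.approx(1000.0)

    def test_integrate_empty_window_is_zero(self, rm20, vp):
        vals = np.zeros(20)
        vals[15] = 4.0
        bp = BinnedProfile(REGION, 1000, vals, "smoothed")
        prof = scale_profile(bp, REGION, vp, margin=2000)
        assert integrate(prof, GenomicInterval("chrT", 0, 3000)) == 0.0

    def test_integrate_matches_per_base_accumulation(self, rm20, vp):
        rng = np.random.default_rng(6)
        bp = BinnedProfile(REGION, 1000, rng.uniform(0, 5, 20), "smoothed")
        prof = scale_profile(bp, REGION, vp, margin=2000)
        window = GenomicInterval("chrT", 2500, 11_700)
        per_base = np.repeat(prof.values / 1000.0, 1000)
        oracle = per_base[2500:11_700].sum()
        assert integrate(prof, window) == pytest.approx(oracle, rel=1e-9)


class TestMergeReplicates:
    def _profile(self, seed, rm20, vp):
        rng = np.random.default_rng(seed)
        bp = BinnedProfile(REGION, 1000, rng.uniform(0.1, 5, 20), "smoothed")
        return scale_profile(bp, REGION, vp, margin=2000)

    def test_merge_of_identical_profiles_is_identity(self, rm20, vp):
        p = self._profile(7, rm20, vp)
        merged = merge_replicates([p, p, p])
        assert np.allclose(merged.values, p.values)

    def test_merge_is_entrywise_mean(self, rm20, vp):
        p1, p2 = self._profile(8, rm20, vp), self._profile(9, rm20, vp)
        merged = merge_replicates([p1, p2])
        assert np.allclose(merged.values, 0.5 * (p1.values + p2.values))

    def test_merged_eligible_sum_still_1000(self, rm20, vp):
        ps = [self._profile(s, rm20, vp) for s in (10, 11, 12)]
        merged = merge_replicates(ps)
        eligible = np.ones(20, bool)
        eligible[3:8] = False
        assert merged.values[eligible].sum() == pytest.approx(1000.0, rel=1e-9)

    def test_mismatched_viewpoints_rejected(self, rm20, vp):
        p1 = self._profile(13, rm20, vp)
        other_vp = Viewpoint(GenomicInterval("chrT", 9000, 10_000), "other")
        p2 = scale_profile(
            BinnedProfile(REGION, 1000, np.full(20, 1.0), "smoothed"),
            REGION, other_vp, margin=2000)
        with pytest.raises(ValueError):
            merge_replicates([p1, p2])


class TestPipelineProperties:
    def test_conservation_counts_to_binned_values(self, cfg, locus, wt_sim):
        ann, rm = locus
        vp = cfg.viewpoint("Lbx1")
        fc = count_by_fragment(wt_sim["pairs"], vp, rm, cfg.mapq_min)
        bp = bin_1kb(fc, rm, cfg.grid_size)
        assert bp.values.sum() == pytest.approx(fc.total_qualifying, abs=1e-9)

    def test_monotone_response_to_added_pairs(self, rm20, vp):
        base = make_pairs([(5500, 9300, 0, 0, 60, 60)] * 5)
        more = make_pairs([(5500, 9300, 0, 0, 60, 60)] * 9)
        bp0 = bin_1kb(count_by_fragment(base, vp, rm20), rm20, 1000)
        bp1 = bin_1kb(count_by_fragment(more, vp, rm20), rm20, 1000)
        assert np.all(smooth(bp1, 5000).values >= smooth(bp0, 5000).values)

    def test_full_pipeline_scaled_sum(self, cfg, locus, wt_sim):
        ann, rm = locus
        prof = viewpoint_profile(wt_sim["pairs"], cfg.viewpoint("Fgf8"), rm,
                                 cfg.region, cfg.mapq_min, cfg.grid_size,
                                 cfg.smoothing_window, cfg.v4c_margin)
        from chicsv.virtual4c import _eligible_bins
        eligible = _eligible_bins(prof.profile, cfg.region,
                                  cfg.viewpoint("Fgf8"), cfg.v4c_margin)
        assert prof.values[eligible].sum() == pytest.approx(1000.0, rel=1e-9)
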