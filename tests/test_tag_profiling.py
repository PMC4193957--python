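from __future__ import annotations

import numpy as np
import pytest

import _oracles as oracle
from conftest import random_instance
from snpchrom.genomic_io import GenomicInterval, GenomicSite, TagSet, make_offsets
from snpchrom.tag_profiling import (
    StrandProfilePair,
    aggregate_profile,
    estimate_shift,
    extend_tags,
    profile_correlation,
    region_binding_profile,
    shift_and_sum,
    smooth_profile,
    strand_count_profiles,
)
from snpchrom.genomic_io import Profile, ProfileNormalization


def _pair(plus_values, minus_values, n_anchors=1):
    W = (len(plus_values) - 1) // 2
    offsets = make_offsets(W)
    norm = ProfileNormalization(1.0, False, 0)
    return StrandProfilePair(
        plus=Profile(offsets, np.asarray(plus_values, float), n_anchors, norm),
        minus=Profile(offsets, np.asarray(minus_values, float), n_anchors, norm),
    )


class TestStrandCountProfiles:
    def test_single_plus_tag(self):
        tags = TagSet([GenomicInterval("chr1", 95, 120, "+")])
        pair = strand_count_profiles(tags, [GenomicSite("chr1", 100)], 5)
        expected = np.zeros(11)
        expected[0] = 1  # offset -5
        assert np.array_equal(pair.plus.values, expected)
        assert not pair.minus.values.any()

    def test_minus_tag_five_prime_is_end_minus_one(self):
        # verified against a brute-force scan: 5' of [104,130) on '-' is 129
        tags = TagSet([GenomicInterval("chr1", 104, 130, "-")])
        anchors = [GenomicSite("chr1", 100)]
        pair = strand_count_profiles(tags, anchors, 40)
        brute_plus, brute_minus = oracle.brute_strand_counts(tags, anchors, 40)
        assert pair.minus.value_at(29) == 1.0
        assert np.array_equal(pair.minus.values, brute_minus)
        assert np.array_equal(pair.plus.values, brute_plus)

    def test_duplicate_anchors_double_counts(self):
        tags = TagSet([GenomicInterval("chr1", 95, 120, "+")])
        once = strand_count_profiles(tags, [GenomicSite("chr1", 100)], 5)
        twice = strand_count_profiles(tags, [GenomicSite("chr1", 100)] * 2, 5)
        assert np.array_equal(twice.plus.values, 2 * once.plus.values)

    def test_out_of_bounds_anchor_dropped(self, caplog):
        tags = TagSet([GenomicInterval("chr1", 0, 10, "+")])
        with caplog.at_level("WARNING"):
            pair = strand_count_profiles(
                tags, [GenomicSite("chr1", 2), GenomicSite("chr1", 50)], 5
            )
        assert pair.plus.n_anchors == 1
        assert "dropped" in caplog.text

    def test_no_usable_anchors_fatal(self):
        tags = TagSet([GenomicInterval("chr1", 0, 10, "+")])
        with pytest.raises(ValueError):
            strand_count_profiles(tags, [GenomicSite("chr1", 2)], 10)


class TestEstimateShift:
    def test_mirror_peaks_at_73(self):
        # exhaustive-search oracle agrees: peaks coincide at s = 73
        W = 100
        plus = np.zeros(2 * W + 1)
        minus = np.zeros(2 * W + 1)
        plus[W - 74 : W - 71] = [3.0, 5.0, 3.0]  # peak at offset -73
        minus[W + 72 : W + 75] = [3.0, 5.0, 3.0]  # peak at offset +73
        est = estimate_shift(_pair(plus, minus), 73)
        assert est.shift == 73
        assert est.shift == oracle.brute_best_shift(list(plus), list(minus), 73)

    def test_identical_profiles_shift_zero(self, rng):
        values = rng.random(201)
        est = estimate_shift(_pair(values, values.copy()), 50)
        assert est.shift == 0

    def test_cap_binds_for_wider_separation(self):
        W = 100
        plus = np.zeros(2 * W + 1)
        minus = np.zeros(2 * W + 1)
        # wide triangular peaks at -30 / +30: overlap (hence correlation)
        # still increases with s at the cap, so the cap binds
        ramp = np.concatenate([np.arange(1, 26), np.arange(24, 0, -1)]).astype(float)
        plus[W - 30 - 24 : W - 30 + 25] = ramp
        minus[W + 30 - 24 : W + 30 + 25] = ramp
        est = estimate_shift(_pair(plus, minus), 20)
        assert est.shift == 20

    def test_zero_variance_warns_shift_zero(self, caplog):
        with caplog.at_level("WARNING"):
            est = estimate_shift(_pair(np.zeros(11), np.zeros(11)), 5)
        assert est.shift == 0
        assert "zero-variance" in caplog.text

    def test_swap_symmetry(self, rng):
        # swapping plus and minus leaves the estimated shift unchanged
        for _ in range(10):
            plus = rng.poisson(3.0, size=301).astype(float)
            minus = np.roll(plus, int(rng.integers(0, 60)))
            a = estimate_shift(_pair(plus, minus), 40).shift
            b = estimate_shift(_pair(minus, plus), 40).shift
            assert a == b


class TestExtendTags:
    def test_plus_extension(self):
        tags = TagSet([GenomicInterval("chr1", 1000, 1025, "+")])
        (iv,) = extend_tags(tags).intervals
        assert (iv.start, iv.end) == (1000, 1146)

    def test_minus_extension_leftward(self):
        tags = TagSet([GenomicInterval("chr1", 1000, 1025, "-")])
        (iv,) = extend_tags(tags).intervals
        assert (iv.start, iv.end) == (879, 1025)

    def test_minus_clipped_at_zero(self):
        tags = TagSet([GenomicInterval("chr1", 10, 35, "-")])
        (iv,) = extend_tags(tags).intervals
        assert (iv.start, iv.end) == (0, 35)


class TestAggregateProfile:
    def test_uniform_tags_give_unity(self):
        # one point tag at every position: profile == 1 after normalization
        L = 400
        tags = TagSet([GenomicInterval("chr1", p, p + 1, "+") for p in range(L)])
        profile = aggregate_profile(
            tags, [GenomicSite("chr1", 200)], half_window=50, mode="point",
            genome_length=L, shift=0,
        )
        assert np.allclose(profile.values, 1.0)

    def test_scale_invariance(self):
        tags = TagSet(
            [GenomicInterval("chr1", p, p + 1, "+") for p in range(0, 400, 7)]
        )
        doubled = TagSet(tags.intervals * 2)
        anchors = [GenomicSite("chr1", 200)]
        p1 = aggregate_profile(tags, anchors, 50, "point", genome_length=400, shift=0)
        p2 = aggregate_profile(doubled, anchors, 50, "point", genome_length=400, shift=0)
        assert np.allclose(p1.values, p2.values)

    def test_translation_invariance(self, rng):
        tags, anchors, W = random_instance(rng, half_window=30)
        delta = 500
        shifted_tags = TagSet(
            [
                GenomicInterval(iv.chrom, iv.start + delta, iv.end + delta, iv.strand)
                for iv in tags.intervals
            ]
        )
        shifted_anchors = [GenomicSite(a.chrom, a.pos + delta) for a in anchors]
        p1 = aggregate_profile(tags, anchors, W, "point", genome_length=5000)
        p2 = aggregate_profile(
            shifted_tags, shifted_anchors, W, "point", genome_length=5000
        )
        assert np.allclose(p1.values, p2.values)

    @pytest.mark.parametrize("mode", ["point", "nucleosome"])
    def test_oracle_equivalence_small_instances(self, mode, rng):
        for _ in range(25):
            tags, anchors, W = random_instance(rng)
            got = aggregate_profile(tags, anchors, W, mode, genome_length=2000)
            want, shift = oracle.brute_aggregate_profile(
                tags, anchors, W, mode, genome_length=2000
            )
            assert got.normalization.shift_used == shift
            np.testing.assert_allclose(got.values, want, rtol=1e-9, atol=1e-12)

    def test_genome_length_required(self, rng):
        tags, anchors, W = random_instance(rng)
        with pytest.raises(ValueError):
            aggregate_profile(tags, anchors, W, "point", genome_length=0)

    def test_bad_mode(self, rng):
        tags, anchors, W = random_instance(rng)
        with pytest.raises(ValueError):
            aggregate_profile(tags, anchors, W, "peaks", genome_length=100)


class TestShiftAndSum:
    def test_zero_shift_is_plain_sum(self, rng):
        plus = rng.random(21)
        minus = rng.random(21)
        assert np.array_equal(shift_and_sum(_pair(plus, minus), 0), plus + minus)

    def test_shift_moves_strands_toward_each_other(self):
        plus = np.zeros(11)
        minus = np.zeros(11)
        plus[5 - 3] = 1.0  # peak at offset -3
        minus[5 + 3] = 1.0  # peak at offset +3
        summed = shift_and_sum(_pair(plus, minus), 3)
        assert summed[5] == 2.0


class TestRegionBindingProfile:
    def test_single_region(self):
        regions = [GenomicInterval("chr1", 90, 110)]
        profile = region_binding_profile(regions, [GenomicSite("chr1", 100)], 15)
        for d in range(-15, 16):
            expected = 1.0 if -10 <= d < 10 else 0.0
            assert profile.value_at(d) == expected

    def test_empty_interval_set(self):
        profile = region_binding_profile([], [GenomicSite("chr1", 100)], 10)
        assert not profile.values.any()

    def test_oracle_equivalence(self, rng):
        for _ in range(20):
            tags, anchors, W = random_instance(rng, n_tags=10)
            want = oracle.brute_region_profile(tags.intervals, anchors, W)
            got = region_binding_profile(tags.intervals, anchors, W)
            np.testing.assert_allclose(got.values, want, atol=1e-12)
            assert got.values.min() >= 0.0 and got.values.max() <= 1.0


class TestProfileCorrelation:
    def _profile(self, values):
        W = (len(values) - 1) // 2
        return Profile(make_offsets(W), np.asarray(values, float), 1)

    def test_affine_invariance(self, rng):
        v = rng.random(31)
        assert profile_correlation(
            self._profile(v), self._profile(2 * v + 3)
        ) == pytest.approx(1.0)

    def test_negation(self, rng):
        v = rng.random(31)
        assert profile_correlation(
            self._profile(v), self._profile(-v)
        ) == pytest.approx(-1.0)

    def test_against_closed_form(self, rng):
        v1, v2 = rng.random(41), rng.random(41)
        got = profile_correlation(self._profile(v1), self._profile(v2))
        assert got == pytest.approx(oracle.pearson(v1, v2), abs=1e-12)

    def test_mismatched_offsets_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation(self._profile(np.zeros(5)), self._profile(np.zeros(7)))


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        p = Profile(make_offsets(10), np.full(21, 4.0), 1)
        assert np.allclose(smooth_profile(p, 5).values, 4.0)

    def test_mean_preserved_roughly(self, rng):
        p = Profile(make_offsets(50), rng.random(101), 1)
        sm = smooth_profile(p, 7)
        assert sm.values.mean() == pytest.approx(p.values.mean(), rel=0.05)
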