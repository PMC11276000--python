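"""Spatial autocorrelation: oracle equivalence, size convention, intensity ops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import condkit as ck
from condkit.sac import UndefinedCorrelationError
from condkit.tracking import InvalidParameterError
from conftest import direct_sum_autocorrelation


class TestAutocorrelationMap:
    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.normal(50, 10, (48, 48)) + 30 * np.exp(
            -((np.arange(48)[:, None] - 20) ** 2 + (np.arange(48)[None, :] - 25) ** 2) / 40
        )
        yy, xx = np.mgrid[0:48, 0:48]
        mask = (xx - 24) ** 2 + (yy - 24) ** 2 <= 20**2
        res = ck.spatial_autocorrelation(img, 0.2, mask)
        oracle = direct_sum_autocorrelation(img, mask)
        both = np.isfinite(res.corr_map) & np.isfinite(oracle)
        assert np.nanmax(np.abs(res.corr_map[both] - oracle[both])) < 1e-6

    def test_zero_lag_normalized_to_one(self):
        img = np.random.default_rng(1).normal(10, 2, (32, 32))
        res = ck.spatial_autocorrelation(img, 0.1)
        h, w = img.shape
        assert res.corr_map[h - 1, w - 1] == pytest.approx(1.0)
        assert res.radial_corr[0] == pytest.approx(1.0)

    def test_constant_image_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            ck.spatial_autocorrelation(np.full((32, 32), 7.0), 0.1)

    def test_tiny_mask_rejected(self):
        img = np.random.default_rng(2).normal(0, 1, (32, 32))
        mask = np.zeros((32, 32), bool)
        mask[:5, :5] = True
        with pytest.raises(InvalidParameterError):
            ck.spatial_autocorrelation(img, 0.1, mask)

    def test_white_noise_decorrelates_within_one_pixel(self):
        img = np.random.default_rng(3).normal(0, 1, (64, 64))
        res = ck.spatial_autocorrelation(img, 0.2196)
        far = res.radial_lags >= 2 * 0.2196
        assert np.all(np.abs(res.radial_corr[far]) <= 0.1)

    def test_gaussian_blob_profile_matches_analytic_form(self, gaussian_blob):
        sigma = 0.6
        img = gaussian_blob(sigma, pixel_size=0.2196, n=128)
        res = ck.spatial_autocorrelation(img, 0.2196)
        sel = (res.radial_lags > 0) & (res.radial_lags <= 3 * sigma)
        expected = np.exp(-res.radial_lags[sel] ** 2 / (4 * sigma**2))
        # 3% allows the Jensen bias of averaging a convex decay over
        # one-pixel annuli; pointwise agreement is otherwise exact
        assert np.max(np.abs(res.radial_corr[sel] - expected)) < 0.03


class TestClusterSize:
    def test_gaussian_blob_size_is_twice_sigma(self, gaussian_blob):
        res = ck.cluster_size(ck.spatial_autocorrelation(gaussian_blob(0.45), 0.2196))
        assert res.cluster_size == pytest.approx(0.90, rel=0.05)
        assert not res.at_floor

    def test_size_doubles_with_sigma(self, gaussian_blob):
        s1 = ck.cluster_size(ck.spatial_autocorrelation(gaussian_blob(0.5), 0.2196))
        s2 = ck.cluster_size(ck.spatial_autocorrelation(gaussian_blob(1.0, n=128), 0.2196))
        assert s2.cluster_size / s1.cluster_size == pytest.approx(2.0, rel=0.05)

    def test_noise_only_image_reports_resolution_floor(self):
        img = np.random.default_rng(4).normal(100, 10, (96, 96))
        res = ck.cluster_size(ck.spatial_autocorrelation(img, 0.2196))
        assert res.at_floor
        assert res.cluster_size == pytest.approx(0.2196, rel=1e-6)

    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-5.0, 50.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_invariant_to_intensity_scaling_and_offset(self, scale, offset):
        rng = np.random.default_rng(9)
        y, x = np.mgrid[0:64, 0:64] * 0.2196
        img = 40 * np.exp(-((x - 7) ** 2 + (y - 7) ** 2) / (2 * 0.5**2)) + rng.normal(0, 1, (64, 64))
        a = ck.cluster_size(ck.spatial_autocorrelation(img, 0.2196))
        b = ck.cluster_size(ck.spatial_autocorrelation(scale * img + offset, 0.2196))
        assert b.cluster_size == pytest.approx(a.cluster_size, rel=1e-9)

    def test_recovery_across_sigma_grid_with_noise(self, gaussian_blob):
        # SNR 10 (amplitude 100, noise sd 10) at the coarse pixel size;
        # frame scales with the cluster so it does not vanish in empty
        # space, and the median over noise realizations is compared
        for sigma in (0.3, 0.5, 1.0, 2.0):
            n = max(48, int(14 * sigma / 0.2196))
            sizes = [
                ck.cluster_size(
                    ck.spatial_autocorrelation(
                        gaussian_blob(sigma, n=n, noise_sd=10.0, seed=s), 0.2196
                    )
                ).cluster_size
                for s in range(5)
            ]
            assert np.median(sizes) == pytest.approx(2 * sigma, rel=0.10)


class TestLineProfiles:
    def test_self_correlation_is_one(self, gaussian_blob):
        img = gaussian_blob(0.5)
        pair = ck.pairwise_line_profile(img, img, 0.2196, ((1.0, 10.0), (19.0, 10.0)))
        assert pair.pearson_r == pytest.approx(1.0)

    def test_inverted_channel_is_minus_one(self, gaussian_blob):
        img = gaussian_blob(0.5)
        pair = ck.pairwise_line_profile(img, 120.0 - img, 0.2196, ((1.0, 10.0), (19.0, 10.0)))
        assert pair.pearson_r == pytest.approx(-1.0)

    def test_profiles_normalized_to_unit_range(self, gaussian_blob):
        img = gaussian_blob(0.5)
        pair = ck.pairwise_line_profile(img, img + 5, 0.2196, ((1.0, 10.0), (19.0, 10.0)))
        for prof in (pair.channel_a, pair.channel_b):
            assert prof.min() == pytest.approx(0.0)
            assert prof.max() == pytest.approx(1.0)

    def test_degenerate_line_rejected(self, gaussian_blob):
        img = gaussian_blob(0.5)
        with pytest.raises(InvalidParameterError):
            ck.pairwise_line_profile(img, img, 0.2196, ((5.0, 5.0), (5.0, 5.0)))

    def test_core_shell_pair_anticorrelates_more_with_age(self):
        spec = ck.SceneSpec(seed=6)
        aging = ck.AgingLaw(initial_sigma=0.3, final_sigma=0.6, timescale_h=2.0,
                            final_amplitude=150.0, amp_timescale_h=1.0)
        stack = ck.gen_condensate_stack(spec, aging, [0.5, 8.0])
        # draw the line through a known cluster, as one would by eye
        ccx, ccy = stack.ground_truth[1]["cluster_centers_um"][0]
        line = ((ccx - 5.0, ccy), (ccx + 5.0, ccy))
        rs = [
            ck.pairwise_line_profile(
                stack.data[i, 0], stack.data[i, 1], spec.pixel_size, line, width=3
            ).pearson_r
            for i in range(2)
        ]
        assert rs[1] < rs[0]
        assert rs[1] < -0.5


class TestClusterFraction:
    def test_homogeneous_condensate_is_zero(self):
        mask = np.ones((96, 96), bool)
        assert ck.cluster_fraction(np.full((96, 96), 100.0), mask) == 0.0
        rng = np.random.default_rng(10)
        noisy = 100 + rng.normal(0, 2, (96, 96))
        assert ck.cluster_fraction(noisy, mask) < 0.005

    def test_known_ten_percent_cluster_share(self):
        # clusters carry 10% of the background-subtracted condensate signal
        rng = np.random.default_rng(12)
        n, px = 192, 0.2196
        y, x = np.mgrid[0:n, 0:n] * px
        c = (n - 1) / 2 * px
        disk = (x - c) ** 2 + (y - c) ** 2 <= 15.0**2
        baseline = 100.0
        total_baseline = baseline * disk.sum()
        target = 0.10 / 0.90 * total_baseline  # cluster integral
        sigma = 0.6
        amp = target / (3 * 2 * np.pi * (sigma / px) ** 2)
        img = np.where(disk, baseline, 0.0)
        for dx, dy in ((-5, 0), (5, 3), (0, -6)):
            img += amp * np.exp(-((x - c - dx) ** 2 + (y - c - dy) ** 2) / (2 * sigma**2))
        img += rng.normal(0, 1.0, img.shape)
        frac = ck.cluster_fraction(img, disk)
        assert frac == pytest.approx(0.10, abs=0.02)

    def test_all_signal_in_clusters(self):
        # shell at background level: the channel lives almost entirely in clusters
        rng = np.random.default_rng(13)
        n, px = 128, 0.2196
        y, x = np.mgrid[0:n, 0:n] * px
        c = (n - 1) / 2 * px
        disk = (x - c) ** 2 + (y - c) ** 2 <= 10.0**2
        img = np.zeros((n, n))
        for dx, dy in ((-3, 0), (3, 2)):
            img += 200 * np.exp(-((x - c - dx) ** 2 + (y - c - dy) ** 2) / (2 * 0.8**2))
        img += rng.normal(0, 1.0, img.shape)
        assert ck.cluster_fraction(img, disk) > 0.9

    @given(scale=st.floats(0.5, 20.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_invariant_to_uniform_scaling(self, scale):
        rng = np.random.default_rng(14)
        n = 96
        y, x = np.mgrid[0:n, 0:n] * 0.2
        img = 50.0 + 100 * np.exp(-((x - 9) ** 2 + (y - 9) ** 2) / (2 * 0.5**2))
        img += rng.normal(0, 1, (n, n))
        mask = np.ones((n, n), bool)
        a = ck.cluster_fraction(img, mask)
        b = ck.cluster_fraction(scale * img, mask)
        assert b == pytest.approx(a, rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidParameterError):
            ck.cluster_fraction(np.zeros((16, 16)), np.zeros((16, 16), bool))


class TestTimecourse:
    def test_growing_clusters_give_positive_trend(self):
        spec = ck.SceneSpec(seed=20)
        aging = ck.AgingLaw(initial_sigma=0.05, final_sigma=0.6, timescale_h=2.0,
                            final_amplitude=150.0)
        stack = ck.gen_condensate_stack(spec, aging, [0.25, 1.0, 2.0, 4.0, 8.0])
        table, tau = ck.cluster_size_timecourse(stack)
        sizes = table["cluster_size_um"].to_numpy()
        assert np.all(np.diff(sizes) >= 0)
        assert tau > 0
        assert bool(table["at_floor"].iloc[0]) and not bool(table["at_floor"].iloc[-1])

    def test_flat_aging_all_at_floor(self):
        spec = ck.SceneSpec(seed=21)
        stack = ck.gen_condensate_stack(
            spec, ck.AgingLaw(final_sigma=0.0, final_amplitude=0.0), [0.5, 4.0]
        )
        table, tau = ck.cluster_size_timecourse(stack)
        assert table["at_floor"].all()

    def test_single_age_rejected(self):
        spec = ck.SceneSpec(seed=22)
        stack = ck.gen_condensate_stack(spec, ck.AgingLaw(), [1.0])
        with pytest.raises(InvalidParameterError):
            ck.cluster_size_timecourse(stack)
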