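"""Exocytosis quantification, outlier filtering, shell and droplet analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.morphology import disk, erosion

from synbind.cells import (
    DropletParams,
    ExoResult,
    ExoTrace,
    compare_conditions,
    compare_partition,
    compute_exo,
    droplet_partition,
    iqr_filter,
    peripheral_fraction,
)
from synbind.simulate import DropletGenConfig, gen_droplet_image


def plateau_trace(f_basal, f_stim, f_total, n=60, stim=10, peak=25, nh4cl=50):
    f = np.empty(n)
    f[:stim] = f_basal
    f[stim:peak] = np.linspace(f_basal, f_stim, peak - stim)
    f[peak:nh4cl] = f_stim
    f[nh4cl:] = f_total
    return ExoTrace(time=np.arange(n, dtype=float), fluorescence=f,
                    stim_frame=stim, peak_frame=peak, nh4cl_frame=nh4cl,
                    cell_id="c0")


class TestComputeExo:
    def test_constructed_windows_give_half(self):
        assert compute_exo(plateau_trace(100.0, 250.0, 400.0)).exo == pytest.approx(0.5)

    def test_endpoints(self):
        assert compute_exo(plateau_trace(100.0, 400.0, 400.0)).exo == pytest.approx(1.0)
        assert compute_exo(plateau_trace(100.0, 100.0, 400.0)).exo == pytest.approx(0.0)

    @given(st.floats(0.1, 10.0), st.floats(-50.0, 50.0))
    def test_invariant_to_affine_rescaling(self, gain, offset):
        tr = plateau_trace(100.0, 250.0, 400.0)
        scaled = ExoTrace(time=tr.time, fluorescence=gain * tr.fluorescence + offset,
                          stim_frame=tr.stim_frame, peak_frame=tr.peak_frame,
                          nh4cl_frame=tr.nh4cl_frame)
        assert compute_exo(scaled).exo == pytest.approx(0.5, rel=1e-9)

    def test_flat_total_response_undefined(self):
        with pytest.raises(ValueError, match="tolerance"):
            compute_exo(plateau_trace(100.0, 100.0, 100.0))

    def test_auto_peak_detection_matches_plateau(self):
        tr = plateau_trace(100.0, 250.0, 400.0)
        auto = ExoTrace(time=tr.time, fluorescence=tr.fluorescence,
                        stim_frame=tr.stim_frame, peak_frame=None,
                        nh4cl_frame=tr.nh4cl_frame)
        assert compute_exo(auto).exo == pytest.approx(0.5, rel=0.01)

    def test_out_of_order_frames_rejected(self):
        with pytest.raises(ValueError, match="stim < peak < nh4cl"):
            ExoTrace(time=np.arange(60.0), fluorescence=np.ones(60),
                     stim_frame=30, peak_frame=20, nh4cl_frame=50)


class TestIqrFilter:
    def test_constant_values_all_kept(self):
        kept, removed = iqr_filter([5.0] * 8)
        assert len(kept) == 8 and len(removed) == 0

    def test_single_outlier_removed_matching_quantile_convention(self):
        values = list(range(1, 10)) + [100]
        q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expect_removed = [v for v in values if not lo <= v <= hi]
        kept, removed = iqr_filter(values)
        assert sorted(removed) == expect_removed == [100]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60))
    def test_kept_and_removed_partition_the_input(self, values):
        kept, removed = iqr_filter(values)
        assert sorted(np.concatenate([kept, removed])) == pytest.approx(sorted(values))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([1.0, 2.0, 3.0])


class TestCompareConditions:
    def test_identical_groups_not_significant(self):
        g = [ExoResult(str(i), v) for i, v in enumerate([0.1, 0.2, 0.3, 0.4, 0.5])]
        rep = compare_conditions(g, g)
        assert rep.difference == pytest.approx(0.0)
        assert rep.significance == "NS"

    def test_powered_shift_reaches_strongest_category(self, rng):
        low = rng.normal(0.2, 0.1, 50)
        high = rng.normal(0.4, 0.1, 50)
        rep = compare_conditions(low, high)
        assert rep.significance == "***"
        assert rep.significance_raw == "***"
        assert rep.difference == pytest.approx(0.2, abs=0.06)

    def test_invariant_to_cell_order(self, rng):
        low = list(rng.normal(0.2, 0.1, 30))
        high = list(rng.normal(0.3, 0.1, 30))
        a = compare_conditions(low, high)
        b = compare_conditions(low[::-1], high[::-1])
        assert a.p_value == pytest.approx(b.p_value)
        assert a.difference == pytest.approx(b.difference)

    def test_tiny_group_descriptive_only(self):
        rep = compare_conditions([0.2], [0.4])
        assert np.isnan(rep.p_value)
        assert rep.difference == pytest.approx(0.2)


class TestPeripheralFraction:
    yy, xx = np.mgrid[0:200, 0:200]
    mask = (yy - 100) ** 2 + (xx - 100) ** 2 <= 80**2

    def test_all_intensity_in_shell_gives_100_percent(self):
        shell = self.mask & ~erosion(self.mask, disk(8))
        img = np.where(shell, 5.0, 0.0)
        pct = peripheral_fraction(img, self.mask, pixel_size_um=0.1)
        assert pct == pytest.approx(100.0)

    def test_uniform_intensity_gives_shell_area_ratio(self):
        pct = peripheral_fraction(np.ones_like(self.mask, float), self.mask,
                                  pixel_size_um=0.1)
        shell = self.mask & ~erosion(self.mask, disk(8))
        assert pct == pytest.approx(100.0 * shell.sum() / self.mask.sum())

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            peripheral_fraction(np.zeros_like(self.mask, float), self.mask, 0.1)

    def test_subpixel_shell_demands_finer_sampling(self):
        with pytest.raises(ValueError, match="pixel"):
            peripheral_fraction(np.ones_like(self.mask, float), self.mask,
                                pixel_size_um=1.0)


class TestDropletPartition:
    def test_uniform_tracer_gives_unit_pc(self):
        gfp, rho, _ = gen_droplet_image(DropletGenConfig(seed=3, n_droplets=6))
        flat = np.full_like(rho, 500, dtype=float)
        for d in droplet_partition(gfp, flat, 0.132):
            assert d.partition_coefficient == pytest.approx(1.0)

    def test_ten_to_one_recovered_within_two_percent(self):
        gfp, rho, truth = gen_droplet_image(DropletGenConfig(seed=0))
        stats = droplet_partition(gfp, rho, 0.132)
        assert len(stats) == len(truth)
        for d in stats:
            assert d.partition_coefficient == pytest.approx(10.0, rel=0.02)

    def test_gain_invariance_of_pc(self):
        gfp, rho, _ = gen_droplet_image(DropletGenConfig(seed=1))
        a = sorted(d.partition_coefficient
                   for d in droplet_partition(gfp, rho, 0.132))
        b = sorted(d.partition_coefficient
                   for d in droplet_partition(gfp, rho.astype(float) * 3.7, 0.132))
        assert a == pytest.approx(b)

    def test_small_droplet_excluded_by_area_filter(self):
        # sharp-edged construction (no blur) so particle areas are exact
        g = np.full((128, 128), 10.0)
        r = np.full((128, 128), 100.0)
        yy, xx = np.mgrid[0:128, 0:128]
        big = (yy - 40) ** 2 + (xx - 40) ** 2 <= 12**2
        small = (yy - 90) ** 2 + (xx - 90) ** 2 <= 1.5**2  # ~0.12 um^2
        g[big | small] = 200.0
        r[big | small] = 1000.0
        params = DropletParams(blur_sigma_px=0.0, interior_margin_px=2)
        stats = droplet_partition(g, r, 0.132, params)
        assert len(stats) == 1
        assert stats[0].area > 0.2

    def test_saturated_droplets_dropped(self):
        cfg = DropletGenConfig(seed=2, n_droplets=8, n_saturated=2)
        gfp, rho, truth = gen_droplet_image(cfg)
        stats = droplet_partition(gfp, rho, 0.132)
        assert len(stats) == int((~truth.saturated).sum())

    def test_empty_field_returns_empty_list(self):
        flat = np.full((64, 64), 7.0)
        assert droplet_partition(flat, flat.copy(), 0.132) == []

    def test_condition_comparison_significant_for_distinct_pc(self):
        g1, r1, _ = gen_droplet_image(DropletGenConfig(seed=5, noise_sd=0.02,
                                                       n_droplets=10))
        g2, r2, _ = gen_droplet_image(DropletGenConfig(
            seed=6, noise_sd=0.02, n_droplets=10, partition_coefficient=4.0))
        a = droplet_partition(g1, r1, 0.132)
        b = droplet_partition(g2, r2, 0.132)
        rep = compare_partition(a, b)
        assert rep.mean_log_pc_a == pytest.approx(np.log(10.0), rel=0.05)
        assert rep.mean_log_pc_b == pytest.approx(np.log(4.0), rel=0.05)
        assert rep.significance == "***"
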