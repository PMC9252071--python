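"""Tests of the composed pathology readouts against brute-force oracles."""

import math

import numpy as np
import pytest

from gliaquant.imaging import CalibratedStack, ChannelRole
from gliaquant.pathology import (
    MetricReport,
    MetricValue,
    PlaqueParams,
    background_subtracted_intensity,
    cd68_in_microglia,
    mex04_ratio,
    microglia_coverage,
    neuritic_damage_ratio,
    plaque_associated_microglia,
    plaque_burden,
    tau_epitope_ratio,
)
from conftest import rect_roi, stack_from_2d
from oracles import brute_dilate, size_filtered, threshold_from_pixels


def two_level(mask, hi=200.0, lo=10.0):
    out = np.full(mask.shape, lo)
    out[mask] = hi
    return out


class TestPlaqueBurden:
    def test_blank_image_flags_degenerate(self):
        stack = stack_from_2d(np.full((100, 100), 7.0))
        vals = {v.name: v for v in plaque_burden(stack, rect_roi(100, 100))}
        assert all(v.value == 0.0 and v.flag == "degenerate_threshold" for v in vals.values())

    def test_forced_geometry_400px_in_10000(self):
        mask = np.zeros((100, 100), bool)
        mask[40:60, 40:60] = True  # 400 px object
        stack = stack_from_2d(two_level(mask))
        vals = {v.name: v for v in plaque_burden(stack, rect_roi(100, 100))}
        assert vals["plaque_area_fraction"].value == pytest.approx(0.04)
        assert vals["plaque_count"].value == 1
        assert vals["plaque_mean_size_um2"].value == pytest.approx(400.0)

    def test_area_fraction_counts_subcutoff_pixels(self):
        mask = np.zeros((100, 100), bool)
        mask[40:60, 40:60] = True  # retained plaque
        mask[5:8, 5:10] = True  # 15 px speck: in fraction, not in count
        stack = stack_from_2d(two_level(mask))
        vals = {v.name: v for v in plaque_burden(stack, rect_roi(100, 100))}
        assert vals["plaque_area_fraction"].value == pytest.approx(415 / 10_000)
        assert vals["plaque_count"].value == 1
        assert vals["plaque_mean_size_um2"].value == pytest.approx(400.0)

    def test_noisy_scene_matches_pixel_oracle(self):
        rng = np.random.default_rng(11)
        mask = np.zeros((64, 64), bool)
        mask[10:26, 10:26] = True
        mask[40:55, 38:54] = True
        image = two_level(mask, 120.0, 20.0) + rng.normal(0, 5, (64, 64))
        image = np.clip(image, 0, None)
        stack = stack_from_2d(image)
        roi = rect_roi(64, 64)
        vals = {v.name: v for v in plaque_burden(stack, roi)}
        t = threshold_from_pixels(image.ravel(), "otsu")
        fg = image > t
        assert vals["plaque_area_fraction"].value == fg.sum() / 64**2
        kept = size_filtered(fg, 50.0, 1.0)
        assert vals["plaque_count"].value == 2
        assert vals["plaque_mean_size_um2"].value == pytest.approx(kept.sum() / 2)


class TestMex04Ratio:
    def test_identical_masks_ratio_one(self):
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        mex = stack_from_2d(two_level(mask), ChannelRole.PLAQUE_MEX04)
        e10 = stack_from_2d(two_level(mask), ChannelRole.PLAQUE_6E10)
        vals = {v.name: v for v in mex04_ratio(mex, e10, rect_roi(64, 64))}
        assert vals["mex04_over_6e10"].value == pytest.approx(1.0)

    def test_empty_mex04_is_zero(self):
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        mex = stack_from_2d(np.full((64, 64), 5.0), ChannelRole.PLAQUE_MEX04)
        e10 = stack_from_2d(two_level(mask), ChannelRole.PLAQUE_6E10)
        vals = {v.name: v for v in mex04_ratio(mex, e10, rect_roi(64, 64))}
        assert vals["mex04_area_fraction"].value == 0.0
        assert vals["mex04_over_6e10"].value == 0.0

    def test_zero_6e10_is_missing(self):
        mask = np.zeros((64, 64), bool)
        mask[20:30, 20:30] = True
        mex = stack_from_2d(two_level(mask), ChannelRole.PLAQUE_MEX04)
        e10 = stack_from_2d(np.full((64, 64), 5.0), ChannelRole.PLAQUE_6E10)
        vals = {v.name: v for v in mex04_ratio(mex, e10, rect_roi(64, 64))}
        assert math.isnan(vals["mex04_over_6e10"].value)
        assert vals["mex04_over_6e10"].flag != ""

    def test_nested_cores_area_quotient(self):
        yy, xx = np.mgrid[0:64, 0:64]
        d2 = (yy - 32) ** 2 + (xx - 32) ** 2
        inner, outer = d2 <= 64, d2 <= 225
        mex = stack_from_2d(two_level(inner), ChannelRole.PLAQUE_MEX04)
        e10 = stack_from_2d(two_level(outer), ChannelRole.PLAQUE_6E10)
        vals = {v.name: v for v in mex04_ratio(mex, e10, rect_roi(64, 64))}
        assert vals["mex04_over_6e10"].value == pytest.approx(inner.sum() / outer.sum())


class TestNeuriticDamage:
    def test_empty_lamp1_is_zero(self, damage_fixture):
        blank = stack_from_2d(np.full((64, 64), 10.0), ChannelRole.LAMP1)
        res = neuritic_damage_ratio(
            damage_fixture["plaque"], blank, damage_fixture["microglia"], rect_roi(64, 64)
        )
        assert res.value == 0.0

    def test_lamp1_inside_microglia_is_zero(self):
        yy, xx = np.mgrid[0:64, 0:64]
        plaque = (yy - 32) ** 2 + (xx - 32) ** 2 <= 25
        lamp1 = (xx >= 42) & (xx <= 45)
        microglia = (xx >= 40) & (xx <= 47)  # superset of lamp1
        res = neuritic_damage_ratio(
            stack_from_2d(two_level(plaque)),
            stack_from_2d(two_level(lamp1), ChannelRole.LAMP1),
            stack_from_2d(two_level(microglia), ChannelRole.MICROGLIA),
            rect_roi(64, 64),
        )
        assert res.value == 0.0

    def test_matches_pixel_loop_oracle(self, damage_fixture):
        params = PlaqueParams(min_plaque_area_um2=50.0, neurite_halo_um=25.0)
        res = neuritic_damage_ratio(
            damage_fixture["plaque"],
            damage_fixture["lamp1"],
            damage_fixture["microglia"],
            rect_roi(64, 64),
            params,
        )
        # independent re-implementation of the sequence
        pl = damage_fixture["plaque"].voxels[0]
        la = damage_fixture["lamp1"].voxels[0]
        mg = damage_fixture["microglia"].voxels[0]
        p_fg = pl > threshold_from_pixels(pl.ravel(), "otsu")
        l_fg = la > threshold_from_pixels(la.ravel(), "otsu")
        m_fg = mg > threshold_from_pixels(mg.ravel(), "otsu")
        plaques = size_filtered(p_fg, 50.0, 1.0)
        halo = brute_dilate(plaques, 25.0, 1.0)
        non_mg = l_fg & ~m_fg
        expected = (non_mg & halo).sum() / plaques.sum()
        assert res.value == expected

    def test_monotone_in_halo_radius(self, damage_fixture):
        values = [
            neuritic_damage_ratio(
                damage_fixture["plaque"],
                damage_fixture["lamp1"],
                damage_fixture["microglia"],
                rect_roi(64, 64),
                PlaqueParams(neurite_halo_um=r),
            ).value
            for r in (2.0, 6.0, 12.0, 25.0)
        ]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_zero_plaque_is_missing(self, damage_fixture):
        blank = stack_from_2d(np.full((64, 64), 10.0))
        res = neuritic_damage_ratio(
            blank, damage_fixture["lamp1"], damage_fixture["microglia"], rect_roi(64, 64)
        )
        assert math.isnan(res.value) and res.flag != ""


class TestMicrogliaMetrics:
    def test_coverage_blank_and_full(self):
        blank = stack_from_2d(np.full((32, 32), 3.0), ChannelRole.MICROGLIA, nz=2)
        assert microglia_coverage(blank, rect_roi(32, 32)).value == 0.0
        # threshold splits lo/hi; hi covers all but one pixel per plane
        img = np.full((32, 32), 200.0)
        img[0, 0] = 10.0
        stack = stack_from_2d(img, ChannelRole.MICROGLIA, nz=3)
        cov = microglia_coverage(stack, rect_roi(32, 32)).value
        assert cov == pytest.approx((32 * 32 - 1) / (32 * 32))

    def test_coverage_loop_oracle(self):
        rng = np.random.default_rng(12)
        mask = rng.random((3, 32, 32)) < 0.2
        vox = np.where(mask, 180.0, 15.0) + rng.normal(0, 4, (3, 32, 32))
        stack = CalibratedStack(np.clip(vox, 0, None), 1.0, ChannelRole.MICROGLIA)
        cov = microglia_coverage(stack, rect_roi(32, 32)).value
        t = threshold_from_pixels(stack.voxels.ravel(), "otsu")
        assert cov == (stack.voxels > t).sum() / (32 * 32 * 3)

    def test_plaque_associated_no_plaque_is_zero(self, damage_fixture):
        blank = stack_from_2d(np.full((64, 64), 10.0))
        res = plaque_associated_microglia(blank, damage_fixture["microglia"], rect_roi(64, 64))
        assert res.value == 0.0

    def test_plaque_associated_full_overlap_is_one(self):
        yy, xx = np.mgrid[0:64, 0:64]
        plaque = (yy - 32) ** 2 + (xx - 32) ** 2 <= 100
        microglia = (yy - 32) ** 2 + (xx - 32) ** 2 <= 144  # within 5 um of plaque
        res = plaque_associated_microglia(
            stack_from_2d(two_level(plaque)),
            stack_from_2d(two_level(microglia), ChannelRole.MICROGLIA),
            rect_roi(64, 64),
        )
        assert res.value == pytest.approx(1.0)

    def test_plaque_associated_zero_halo_is_pure_overlap(self, damage_fixture):
        masks = damage_fixture["masks"]
        res = plaque_associated_microglia(
            damage_fixture["plaque"],
            damage_fixture["microglia"],
            rect_roi(64, 64),
            PlaqueParams(microglia_assoc_halo_um=1e-9),
        )
        expected = (masks["plaque"] & masks["microglia"]).sum() / masks["microglia"].sum()
        assert res.value == pytest.approx(expected)

    def test_plaque_associated_oracle(self, damage_fixture):
        res = plaque_associated_microglia(
            damage_fixture["plaque"], damage_fixture["microglia"], rect_roi(64, 64)
        )
        pl = damage_fixture["plaque"].voxels[0]
        mg = damage_fixture["microglia"].voxels[0]
        p_fg = pl > threshold_from_pixels(pl.ravel(), "otsu")
        m_fg = mg > threshold_from_pixels(mg.ravel(), "otsu")
        halo = brute_dilate(p_fg, 5.0, 1.0)
        assert res.value == (m_fg & halo).sum() / m_fg.sum()

    def test_cd68_empty_and_superset(self, damage_fixture):
        blank = stack_from_2d(np.full((64, 64), 10.0), ChannelRole.CD68)
        assert cd68_in_microglia(blank, damage_fixture["microglia"], rect_roi(64, 64)).value == 0.0
        yy, xx = np.mgrid[0:64, 0:64]
        mg = (xx >= 20) & (xx <= 30)
        cd = (xx >= 18) & (xx <= 32)  # superset
        res = cd68_in_microglia(
            stack_from_2d(two_level(cd), ChannelRole.CD68),
            stack_from_2d(two_level(mg), ChannelRole.MICROGLIA),
            rect_roi(64, 64),
        )
        assert res.value == pytest.approx(1.0)

    def test_cd68_oracle(self, damage_fixture):
        masks = damage_fixture["masks"]
        cd = masks["plaque"] | masks["lamp1"]  # arbitrary puncta pattern
        res = cd68_in_microglia(
            stack_from_2d(two_level(cd), ChannelRole.CD68),
            damage_fixture["microglia"],
            rect_roi(64, 64),
        )
        expected = (cd & masks["microglia"]).sum() / masks["microglia"].sum()
        assert res.value == pytest.approx(expected)


class TestMarkerIntensity:
    def test_uniform_signal_minus_background(self):
        img = np.full((64, 64), 30.0)
        img[20:40, 20:40] = 90.0
        stack = stack_from_2d(img, ChannelRole.MICROGLIA)
        res = background_subtracted_intensity(stack, rect_roi(64, 64))
        assert res.value == pytest.approx(60.0)

    def test_constant_image_flags(self):
        stack = stack_from_2d(np.full((32, 32), 12.0), ChannelRole.MICROGLIA)
        res = background_subtracted_intensity(stack, rect_roi(32, 32))
        assert res.value == 0.0 and res.flag == "degenerate_threshold"

    def test_noisy_regions_near_analytic_expectation(self):
        rng = np.random.default_rng(13)
        sig = np.zeros((64, 64), bool)
        sig[10:50, 10:50] = True
        vox = np.where(sig, 120.0, 30.0)[None] + rng.normal(0, 3, (4, 64, 64))
        stack = CalibratedStack(np.clip(vox, 0, None), 1.0, ChannelRole.MICROGLIA)
        res = background_subtracted_intensity(stack, rect_roi(64, 64))
        # z-sum projection: signal 480, background 120 -> expect ~360
        assert res.value == pytest.approx(360.0, abs=5.0)


class TestTauRatio:
    def test_equal_masks_ratio_one(self):
        mask = np.zeros((64, 64), bool)
        mask[10:40, 10:40] = True
        ph = stack_from_2d(two_level(mask), ChannelRole.TAU_PHOSPHO)
        tt = stack_from_2d(two_level(mask), ChannelRole.TAU_TOTAL)
        vals = {v.name: v for v in tau_epitope_ratio(ph, tt, rect_roi(64, 64))}
        assert vals["phospho_over_total_tau"].value == pytest.approx(1.0)

    def test_empty_phospho(self):
        mask = np.zeros((64, 64), bool)
        mask[10:40, 10:40] = True
        ph = stack_from_2d(np.full((64, 64), 5.0), ChannelRole.TAU_PHOSPHO)
        tt = stack_from_2d(two_level(mask), ChannelRole.TAU_TOTAL)
        vals = {v.name: v for v in tau_epitope_ratio(ph, tt, rect_roi(64, 64))}
        assert vals["phospho_tau_area_fraction"].value == 0.0
        assert vals["phospho_over_total_tau"].value == 0.0

    def test_zero_total_is_missing(self):
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        ph = stack_from_2d(two_level(mask), ChannelRole.TAU_PHOSPHO)
        tt = stack_from_2d(np.full((64, 64), 5.0), ChannelRole.TAU_TOTAL)
        vals = {v.name: v for v in tau_epitope_ratio(ph, tt, rect_roi(64, 64))}
        assert math.isnan(vals["phospho_over_total_tau"].value)

    def test_nested_fixture_area_quotient(self):
        yy, xx = np.mgrid[0:64, 0:64]
        d2 = (yy - 30) ** 2 + (xx - 30) ** 2
        ph_mask, tt_mask = d2 <= 49, d2 <= 196
        ph = stack_from_2d(two_level(ph_mask), ChannelRole.TAU_PHOSPHO)
        tt = stack_from_2d(two_level(tt_mask), ChannelRole.TAU_TOTAL)
        vals = {v.name: v for v in tau_epitope_ratio(ph, tt, rect_roi(64, 64))}
        assert vals["phospho_over_total_tau"].value == pytest.approx(
            ph_mask.sum() / tt_mask.sum()
        )


class TestInvariants:
    def test_fractions_in_unit_interval_on_random_scenes(self):
        from gliaquant.synthetic import random_scene_spec, render_scene

        roi = rect_roi(256, 256)
        for seed in (0, 1):
            ch, _ = render_scene(random_scene_spec(seed))
            frac_metrics = []
            frac_metrics += [v for v in plaque_burden(ch[ChannelRole.PLAQUE_6E10], roi)
                             if v.name == "plaque_area_fraction"]
            frac_metrics.append(microglia_coverage(ch[ChannelRole.MICROGLIA], roi))
            frac_metrics.append(
                plaque_associated_microglia(ch[ChannelRole.PLAQUE_6E10], ch[ChannelRole.MICROGLIA], roi)
            )
            frac_metrics.append(
                cd68_in_microglia(ch[ChannelRole.CD68], ch[ChannelRole.MICROGLIA], roi)
            )
            for v in frac_metrics:
                assert 0.0 <= v.value <= 1.0

    def test_affine_intensity_invariance(self, damage_fixture):
        """Metrics are unchanged by a global a*I + b rescale (a > 0)."""
        roi = rect_roi(64, 64)
        base = neuritic_damage_ratio(
            damage_fixture["plaque"], damage_fixture["lamp1"], damage_fixture["microglia"], roi
        ).value

        def rescale(stack, a=3.0, b=17.0):
            return CalibratedStack(a * stack.voxels + b, stack.pixel_size_um, stack.channel_role)

        scaled = neuritic_damage_ratio(
            rescale(damage_fixture["plaque"]),
            rescale(damage_fixture["lamp1"]),
            rescale(damage_fixture["microglia"]),
            roi,
        ).value
        assert scaled == pytest.approx(base)


def test_metric_report_long_format():
    rep = MetricReport()
    rep.add("img1", "subiculum", [MetricValue("a", 1.0), MetricValue("b", float("nan"), "zero_denominator")])
    df = rep.to_frame()
    assert list(df.columns) == ["image", "region", "metric", "value", "flag"]
    assert len(df) == 2
    assert df.loc[1, "flag"] == "zero_denominator"
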