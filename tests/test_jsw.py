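"""Sampling-grid conventions, width recovery on phantoms, minimum-JSW search."""
import math

import numpy as np
import pytest

from kneejsw.contour import build_frame, extract_margins
from kneejsw.errors import MissingSiteError, ProfileInvalidError
from kneejsw.imaging import LabelMask
from kneejsw.jsw import (
    SamplingGrid,
    calibrate,
    min_jsw,
    multi_jsw,
    sample_sites,
    width_at,
)

MM = 0.2


def naive_min_distance(femur, tibia, frame, lo=0.7, hi=0.9):
    """Independent double-loop oracle for the all-pairs minimum distance."""
    best = math.inf
    for cf, rf in zip(femur.columns, femur.rows):
        if not lo <= frame.to_x(int(cf)) <= hi:
            continue
        for ct, rt in zip(tibia.columns, tibia.rows):
            if not lo <= frame.to_x(int(ct)) <= hi:
                continue
            d = math.hypot((rt - rf) * frame.row_mm, (ct - cf) * frame.col_mm)
            best = min(best, d)
    return best


class TestSamplingGrid:
    @pytest.mark.parametrize("n,interval", [(8, 0.05), (16, 0.025),
                                            (32, 0.0125), (64, 0.00625)])
    def test_point_counts_match_intervals(self, n, interval):
        grid = SamplingGrid(n_points=n)
        assert grid.spacing == pytest.approx(interval)
        sites = sample_sites(grid)
        assert sites.size == n

    def test_16_point_medial_sites(self):
        sites = sample_sites(SamplingGrid(n_points=16))
        assert np.allclose(sites[8:], 0.700 + 0.025 * np.arange(8))

    def test_two_point_grid_hits_range_starts(self):
        sites = sample_sites(SamplingGrid(n_points=2))
        assert np.allclose(sites, [0.10, 0.70])

    @pytest.mark.parametrize("n", [8, 16, 32])
    def test_dyadic_nesting(self, n):
        coarse = sample_sites(SamplingGrid(n_points=n))
        fine = sample_sites(SamplingGrid(n_points=2 * n))
        for x in coarse:
            assert np.min(np.abs(fine - x)) < 1e-12

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            SamplingGrid(n_points=7)
        with pytest.raises(ValueError):
            SamplingGrid(n_points=8, lateral_range=(0.1, 0.4))  # unequal widths
        with pytest.raises(ValueError):
            SamplingGrid(n_points=8, lateral_range=(0.6, 0.8),
                         medial_range=(0.3, 0.5))  # out of order


class TestWidthAt:
    def test_constant_gap_recovered_at_every_site(self, flat_phantom):
        _, mask, _, _ = flat_phantom
        femur, tibia = extract_margins(mask)
        frame = build_frame(tibia, "right", MM, MM)
        for x in sample_sites(SamplingGrid(n_points=64)):
            assert width_at(float(x), femur, tibia, frame) == pytest.approx(4.0, abs=MM)

    def test_parabolic_profile_recovered(self, parabolic_margins):
        femur, tibia, frame, truth = parabolic_margins
        profile = multi_jsw(femur, tibia, frame, SamplingGrid(n_points=64))
        expected = 2.0 + 8.0 * (profile.x - 0.8) ** 2
        assert np.max(np.abs(profile.widths - expected)) <= 1.5 * MM
        assert profile.n_imputed == 0

    def test_site_outside_overlap_raises(self, parabolic_margins):
        femur, tibia, frame, _ = parabolic_margins
        with pytest.raises(MissingSiteError):
            width_at(1.2, femur, tibia, frame)

    def test_crossing_margins_clamp_to_zero(self):
        # bone-on-bone contact: femoral margin dips below the tibial margin
        from kneejsw.contour import ArticularMargin

        cols = np.arange(60)
        femur_rows = np.full(60, 20.5)
        femur_rows[40] = 41.5  # below the tibial margin
        femur = ArticularMargin("femur", cols, femur_rows)
        tibia = ArticularMargin("tibia", cols, np.full(60, 39.5))
        frame = build_frame(tibia, "right", MM, MM)
        x_spur = frame.to_x(40)
        with pytest.warns(UserWarning, match="clamp"):
            assert width_at(float(x_spur), femur, tibia, frame) == 0.0


class TestMultiJSW:
    def test_dyadic_grids_agree_at_shared_sites(self, parabolic_margins):
        femur, tibia, frame, _ = parabolic_margins
        p8 = multi_jsw(femur, tibia, frame, SamplingGrid(n_points=8))
        p64 = multi_jsw(femur, tibia, frame, SamplingGrid(n_points=64))
        lookup = dict(zip(np.round(p64.x, 9), p64.widths))
        for x, w in zip(np.round(p8.x, 9), p8.widths):
            assert w == lookup[x]

    @staticmethod
    def _frame_and_eroded_margins(femur_end):
        """Frame from the full mask; margins from a mask with an eroded femur.

        Emulates measuring with a frame fixed at baseline while the current
        segmentation loses femoral coverage on the medial side.
        """
        full = np.zeros((64, 128), dtype=np.uint8)
        full[5:20, 4:124] = 1
        full[40:55, 4:124] = 2
        _, tibia_full = extract_margins(LabelMask(labels=full))
        frame = build_frame(tibia_full, "right", MM, MM)
        eroded = full.copy()
        eroded[5:20, femur_end:] = 0
        femur, tibia = extract_margins(LabelMask(labels=eroded))
        return femur, tibia, frame

    def test_partial_overlap_imputes_and_flags(self):
        # medial overlap ends near x~0.85: the last medial sites are missing
        femur, tibia, frame = self._frame_and_eroded_margins(femur_end=100)
        profile = multi_jsw(femur, tibia, frame, SamplingGrid(n_points=8))
        assert profile.n_imputed >= 1
        assert all(np.isfinite(profile.widths))

    def test_excessive_missing_sites_invalidate_profile(self):
        femur, tibia, frame = self._frame_and_eroded_margins(femur_end=50)
        with pytest.raises(ProfileInvalidError):
            multi_jsw(femur, tibia, frame, SamplingGrid(n_points=8))


class TestMinJSW:
    def test_flat_margins_give_vertical_gap(self, flat_phantom):
        _, mask, _, _ = flat_phantom
        femur, tibia = extract_margins(mask)
        frame = build_frame(tibia, "right", MM, MM)
        assert min_jsw(femur, tibia, frame).width == pytest.approx(4.0, abs=MM)

    def test_matches_naive_double_loop_exactly(self, parabolic_margins):
        femur, tibia, frame, _ = parabolic_margins
        result = min_jsw(femur, tibia, frame)
        assert result.width == naive_min_distance(femur, tibia, frame)

    def test_parabolic_minimum_location_and_value(self, parabolic_margins):
        femur, tibia, frame, truth = parabolic_margins
        result = min_jsw(femur, tibia, frame)
        assert result.width == pytest.approx(2.0, abs=1.5 * MM)
        assert abs(result.at[1] - 0.8) <= 0.02

    def test_bounded_above_by_vertical_widths(self, parabolic_margins):
        femur, tibia, frame, _ = parabolic_margins
        result = min_jsw(femur, tibia, frame)
        medial = [width_at(float(x), femur, tibia, frame)
                  for x in sample_sites(SamplingGrid(n_points=64))[32:]]
        assert result.width <= min(medial) + 1e-12

    def test_no_points_in_window_raises(self, parabolic_margins):
        femur, tibia, frame, _ = parabolic_margins
        with pytest.raises(MissingSiteError):
            min_jsw(femur, tibia, frame, search_window=(1.5, 1.6))

    def test_uniform_narrowing_shifts_widths_by_delta(self):
        from kneejsw.phantom import PhantomSpec, make_phantom, parabolic_gap

        delta = 0.4  # two pixel rows at 0.2 mm spacing
        wide = PhantomSpec(gap_profile=parabolic_gap(2.4, 8.0, 0.8), seed=0)
        narrow = PhantomSpec(gap_profile=parabolic_gap(2.4 - delta, 8.0, 0.8), seed=0)
        profiles = []
        for spec in (wide, narrow):
            _, mask, _ = make_phantom(spec)
            femur, tibia = extract_margins(mask)
            frame = build_frame(tibia, "right", MM, MM)
            profiles.append(multi_jsw(femur, tibia, frame, SamplingGrid(n_points=64)))
        shift = profiles[0].widths - profiles[1].widths
        assert np.max(np.abs(shift - delta)) <= MM


class TestCalibrate:
    def test_pixel_to_mm_product(self):
        assert calibrate(20, 0.2) == pytest.approx(4.0)
        assert calibrate(0, 5.0) == 0.0
        assert calibrate(7.3 / 0.31, 0.31) == pytest.approx(7.3)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            calibrate(10, 0.0)


def test_flip_equivariant_measurements():
    """Mirrored phantom + opposite laterality gives identical JSW results."""
    from kneejsw.phantom import PhantomSpec, make_phantom, parabolic_gap

    results = {}
    for lat in ("right", "left"):
        spec = PhantomSpec(gap_profile=parabolic_gap(2.0, 8.0, 0.8),
                           laterality=lat, seed=2)
        _, mask, _ = make_phantom(spec)
        femur, tibia = extract_margins(mask)
        frame = build_frame(tibia, lat, MM, MM)
        profile = multi_jsw(femur, tibia, frame, SamplingGrid(n_points=64))
        results[lat] = (profile.widths, min_jsw(femur, tibia, frame).width)
    assert np.max(np.abs(results["right"][0] - results["left"][0])) < 1e-9
    assert abs(results["right"][1] - results["left"][1]) < 1e-9
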