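"""Alignment, the −45° convention, and quadrant partitioning."""

import numpy as np
import pytest

import cortimap as cm
from cortimap.regionalisation import (
    REGION_NAMES,
    flip_needed,
    principal_axis_angle,
    region_of_point,
    rotate_inplane,
)
from cortimap.volume import VoxelVolume


def _mask(values, vs=1.65):
    return VoxelVolume(np.asarray(values, np.uint8), vs, "mask")


def _rotated_rectangle(angle_deg, half_len=70, half_wid=12, side=201):
    """Rectangle whose long axis lies at ``angle_deg`` (image frame, y down)."""
    yy, xx = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2
    th = np.radians(angle_deg)
    u = (xx - c) * np.cos(th) + (yy - c) * np.sin(th)
    w = -(xx - c) * np.sin(th) + (yy - c) * np.cos(th)
    return ((np.abs(u) <= half_len) & (np.abs(w) <= half_wid)).astype(np.uint8)[None]


class TestPrincipalAxis:
    def test_axis_aligned_rectangle_is_fixed_point(self):
        rect = _rotated_rectangle(0.0)
        aligned, angle = cm.principal_axis_align(_mask(rect))
        assert angle == pytest.approx(0.0, abs=0.2)
        assert principal_axis_angle(aligned.values.any(axis=0)) == pytest.approx(0, abs=0.2)

    @pytest.mark.parametrize("theta", [30.0, -60.0, 75.0])
    def test_recovers_construction_angle_and_is_idempotent(self, theta):
        rect = _rotated_rectangle(theta)
        aligned, applied = cm.principal_axis_align(_mask(rect))
        assert applied == pytest.approx(-theta, abs=1.0)
        # idempotence: re-running yields < 1 degree
        _, residual = cm.principal_axis_align(aligned)
        assert abs(residual) < 1.0

    def test_circle_tie_breaks_to_zero(self):
        yy, xx = np.mgrid[0:101, 0:101]
        circle = (np.hypot(yy - 50, xx - 50) <= 30).astype(np.uint8)[None]
        assert principal_axis_angle(circle[0]) == 0.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cm.principal_axis_align(_mask(np.zeros((1, 8, 8))))


class TestRotateMinus45:
    def test_empty_volume_stays_empty_on_square_canvas(self):
        out = cm.rotate_minus45_and_pad(_mask(np.zeros((2, 10, 10))))
        assert out.foreground_count() == 0
        assert out.shape[1] == out.shape[2] and out.shape[1] % 2 == 0

    def test_centre_pixel_is_rotation_fixed_point(self):
        values = np.zeros((1, 101, 101), np.uint8)
        values[0, 50, 50] = 1
        out = rotate_inplane(_mask(values), -45.0, expand=False)
        assert out.values[0, 50, 50] == 1
        assert out.foreground_count() == 1

    def test_bar_along_x_lands_on_135_degree_diagonal(self):
        """Coordinate-transform oracle: rotated foreground centres match the
        analytic rotation of the original pixel coordinates."""
        bar = np.zeros((1, 121, 121), np.uint8)
        bar[0, 58:63, 15:106] = 1
        out = rotate_inplane(_mask(bar), -45.0)
        # orientation: a bar along +x rotated by −45° (y down) lies at 135°≡−45°
        assert principal_axis_angle(out.values.any(axis=0)) == pytest.approx(-45.0, abs=1.0)
        # centroid oracle: forward-rotate the input centroid analytically
        ys, xs = np.nonzero(bar[0])
        cin = np.array([(121 - 1) / 2] * 2)
        th = np.radians(-45.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expect_xy = rot @ (np.array([xs.mean(), ys.mean()]) - cin[::-1])
        side = out.shape[1]
        yo, xo = np.nonzero(out.values[0])
        got_xy = np.array([xo.mean(), yo.mean()]) - (side - 1) / 2
        np.testing.assert_allclose(got_xy, expect_xy, atol=1.0)

    def test_foreground_conserved_within_tolerance(self):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[0:80, 0:80]
        blob = (np.hypot(yy - 40, xx - 35) <= 25).astype(np.uint8)
        vol = _mask(np.broadcast_to(blob, (4, 80, 80)).copy())
        out = cm.rotate_minus45_and_pad(vol)
        assert abs(out.foreground_count() - vol.foreground_count()) <= 0.005 * vol.foreground_count()


class TestQuadrants:
    def test_paper_pixel_coordinates_on_4000_canvas(self):
        part = cm.assign_quadrants(4000)
        # labels indexed [y, x]
        assert part.labels[100, 100] == part.code("posterior")  # upper-left
        assert part.labels[500, 3000] == part.code("lateral")  # upper-right
        assert part.labels[3000, 500] == part.code("medial")  # lower-left
        assert part.labels[3000, 3000] == part.code("anterior")  # lower-right

    def test_quadrants_tile_the_canvas(self):
        part = cm.assign_quadrants(64)
        total = sum(part.mask(r).sum() for r in REGION_NAMES)
        assert total == 64 * 64
        for r in REGION_NAMES:
            assert part.mask(r).sum() == 32 * 32

    def test_odd_side_errors(self):
        with pytest.raises(ValueError, match="even"):
            cm.assign_quadrants(4001)

    def test_region_of_point_convention(self):
        assert region_of_point(100, 100, 4000) == "posterior"
        assert region_of_point(3000, 500, 4000) == "lateral"
        assert region_of_point(500, 3000, 4000) == "medial"
        assert region_of_point(3000, 3000, 4000) == "anterior"


class TestMaskToRegion:
    def test_all_ones_keeps_exactly_one_quarter(self):
        vol = _mask(np.ones((3, 16, 16)))
        part = cm.assign_quadrants(16)
        out = cm.mask_to_region(vol, part, "posterior")
        assert out.foreground_count() == 3 * 8 * 8

    def test_object_inside_one_quadrant_is_preserved_there_only(self):
        values = np.zeros((2, 16, 16), np.uint8)
        values[:, 2:5, 10:14] = 1  # fully in lateral (x ≥ 8, y < 8)
        vol = _mask(values)
        part = cm.assign_quadrants(16)
        assert cm.mask_to_region(vol, part, "lateral").foreground_count() == vol.foreground_count()
        for other in ("posterior", "medial", "anterior"):
            assert cm.mask_to_region(vol, part, other).foreground_count() == 0

    def test_straddling_object_is_split_with_conserved_voxels(self):
        values = np.zeros((1, 16, 16), np.uint8)
        values[0, 3:6, 5:12] = 1  # spans the posterior/lateral boundary at x=8
        vol = _mask(values)
        part = cm.assign_quadrants(16)
        left = cm.mask_to_region(vol, part, "posterior").foreground_count()
        right = cm.mask_to_region(vol, part, "lateral").foreground_count()
        assert left > 0 and right > 0
        assert left + right == vol.foreground_count()

    def test_unknown_region_errors(self):
        vol = _mask(np.ones((1, 4, 4)))
        with pytest.raises(ValueError, match="unknown region"):
            cm.mask_to_region(vol, cm.assign_quadrants(4), "dorsal")


class TestFlip:
    def _bilobed(self, small_on_top: bool):
        values = np.zeros((40, 40), np.uint8)
        big = (slice(22, 38), slice(8, 32))
        small = (slice(4, 10), slice(16, 24))
        if not small_on_top:
            big, small = (slice(2, 18), slice(8, 32)), (slice(30, 36), slice(16, 24))
        values[big] = 1
        values[small] = 1
        return values

    def test_small_lobe_on_top_needs_no_flip(self):
        assert flip_needed(self._bilobed(small_on_top=True)) is False

    def test_small_lobe_at_bottom_needs_flip(self):
        assert flip_needed(self._bilobed(small_on_top=False)) is True

    def test_single_component_never_flips(self):
        values = np.zeros((20, 20), np.uint8)
        values[12:18, 4:16] = 1
        assert flip_needed(values) is False
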