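"""Road-mask sampling, panorama stitching and bearing-only triangulation."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from oracles import triangulate_grid_search
from treestump.harvest import (
    CameraPose,
    StitchError,
    bearing_of_detection,
    sample_road_points,
    stitch_panorama,
    triangulate,
)


def _smooth_pano(rng, h=200, w=1000):
    return gaussian_filter(rng.uniform(size=(h, w, 3)), (3, 3, 0))


class TestRoadSampling:
    def test_empty_mask_gives_no_points(self):
        assert sample_road_points(np.zeros((20, 20), bool), 5) == []

    def test_straight_road_arc_length_spacing(self):
        mask = np.zeros((50, 120), bool)
        mask[25, 10:110] = True   # 100-px straight road
        points = sample_road_points(mask, 10)
        assert 10 <= len(points) <= 11
        xs = sorted(x for x, _ in points)
        gaps = np.diff(xs)
        assert np.all((gaps >= 10) & (gaps < 20))
        assert all(mask[y, x] for x, y in points)

    def test_all_points_lie_on_mask(self, rng):
        mask = np.zeros((60, 60), bool)
        mask[30, 5:55] = True
        mask[10:50, 40] = True
        for x, y in sample_road_points(mask, 7):
            assert mask[y, x]

    def test_deterministic(self):
        mask = np.zeros((40, 80), bool)
        mask[20, 5:75] = True
        assert sample_road_points(mask, 8) == sample_road_points(mask, 8)


class TestStitching:
    def test_single_image_is_identity(self, rng):
        img = rng.uniform(size=(50, 80, 3))
        result = stitch_panorama([img])
        assert np.array_equal(result.image, img)
        assert result.seam_error == 0.0

    def test_self_crop_recovers_offset_and_low_seam_error(self, rng):
        pano = _smooth_pano(rng)
        left, right = pano[:, :640], pano[:, 360:]
        result = stitch_panorama([left, right], overlap_hint=280)
        assert abs(result.source_offsets[1] - 360) <= 1
        assert result.seam_error <= 0.01

    def test_crop_back_reproduces_sources_outside_overlap(self, rng):
        pano = _smooth_pano(rng)
        left, right = pano[:, :640], pano[:, 360:]
        result = stitch_panorama([left, right], overlap_hint=280)
        off = result.source_offsets[1]
        assert np.allclose(result.image[:, :off], left[:, :off])
        assert np.allclose(result.image[:, 640:], right[:, 640 - off:])

    def test_max_fetch_size_sources_accepted(self, rng):
        pano = gaussian_filter(rng.uniform(size=(640, 1000, 3)), (3, 3, 0))
        left, right = pano[:, :640], pano[:, 360:1000]   # 640x640 views
        assert left.shape[1] == 640 and left.shape[0] == 640
        result = stitch_panorama([left, right], overlap_hint=280)
        assert abs(result.source_offsets[1] - 360) <= 1

    def test_uncorrelated_images_raise_stitch_error(self, rng):
        a = rng.uniform(size=(40, 60, 3))
        b = rng.uniform(size=(40, 60, 3))
        with pytest.raises(StitchError):
            stitch_panorama([a, b], overlap_hint=30)

    def test_heading_order_applied_from_poses(self, rng):
        pano = _smooth_pano(rng)
        left, right = pano[:, :640], pano[:, 360:]
        poses = [CameraPose(0, 0, 90), CameraPose(0, 0, 40)]
        result = stitch_panorama([right, left], poses=poses, overlap_hint=280)
        assert abs(result.source_offsets[1] - 360) <= 1


class TestBearing:
    def test_centred_box_looks_along_optical_axis(self):
        pose = CameraPose(0, 0, 123.0, hfov_deg=90)
        assert bearing_of_detection((310, 0, 330, 40), 640, pose) == \
               pytest.approx(123.0)

    def test_offsets_scale_linearly_towards_half_fov(self):
        # a box hugging the right edge looks (centre/width - 1/2) * hfov
        # clockwise of the axis, approaching +hfov/2 at the edge itself
        pose = CameraPose(0, 0, 0.0, hfov_deg=90)
        near_edge = bearing_of_detection((630, 0, 640, 10), 640, pose)
        assert near_edge == pytest.approx((635 / 640 - 0.5) * 90.0)
        with pytest.raises(ValueError):
            bearing_of_detection((630, 0, 650, 10), 640, pose)

    def test_wraps_around_north(self):
        pose = CameraPose(0, 0, 350.0, hfov_deg=90)
        # +20 degrees off-axis: centre at 0.5 + 20/90 of the width
        cx = (0.5 + 20.0 / 90.0) * 640
        bearing = bearing_of_detection((cx - 5, 0, cx + 5, 10), 640, pose)
        assert bearing == pytest.approx(10.0)


class TestTriangulation:
    def test_two_ray_closed_form(self):
        obs = [(CameraPose(0, 0, 45), 45.0), (CameraPose(10, 0, 315), 315.0)]
        east, north, residual = triangulate(obs)
        assert (east, north) == pytest.approx((5.0, 5.0), abs=1e-9)
        assert residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_observations_recover_target(self):
        target = np.array([12.0, 30.0])
        poses = [CameraPose(0, 0, 0), CameraPose(25, 5, 0), CameraPose(-8, 14, 0)]
        obs = []
        for pose in poses:
            d = target - [pose.east, pose.north]
            bearing = math.degrees(math.atan2(d[0], d[1])) % 360
            obs.append((pose, bearing))
        east, north, residual = triangulate(obs)
        assert (east, north) == pytest.approx(tuple(target), abs=1e-9)

    def test_invariant_to_observation_order_and_translation(self):
        target = np.array([5.0, 22.0])
        poses = [CameraPose(0, 0, 0), CameraPose(18, 2, 0), CameraPose(-6, 9, 0)]
        obs = []
        for pose in poses:
            d = target - [pose.east, pose.north]
            obs.append((pose, (math.degrees(math.atan2(d[0], d[1])) + 0.3) % 360))
        e1, n1, _ = triangulate(obs)
        e2, n2, _ = triangulate(list(reversed(obs)))
        assert (e1, n1) == pytest.approx((e2, n2), abs=1e-9)
        shifted = [(CameraPose(p.east + 100, p.north - 40, p.heading_deg), b)
                   for p, b in obs]
        e3, n3, _ = triangulate(shifted)
        assert (e3 - 100, n3 + 40) == pytest.approx((e1, n1), abs=1e-6)

    def test_parallel_bearings_rejected(self):
        obs = [(CameraPose(0, 0, 0), 30.0), (CameraPose(10, 0, 0), 30.2)]
        with pytest.raises(ValueError):
            triangulate(obs)
        with pytest.raises(ValueError):
            triangulate([(CameraPose(0, 0, 0), 10.0)])

    def test_noisy_bearings_recover_within_a_metre(self):
        # 5 views of a target ~20 m away, 0.5-degree bearing noise
        rng = np.random.default_rng(3)
        target = np.array([8.0, 20.0])
        poses = [CameraPose(x, 0, 0) for x in (-10.0, -5.0, 0.0, 5.0, 10.0)]
        obs = []
        for pose in poses:
            d = target - [pose.east, pose.north]
            bearing = math.degrees(math.atan2(d[0], d[1])) + rng.normal(0, 0.5)
            obs.append((pose, bearing % 360))
        east, north, residual = triangulate(obs)
        assert math.hypot(east - target[0], north - target[1]) < 1.0
        (ge, gn), g_res = triangulate_grid_search(obs, centre=tuple(target))
        assert math.hypot(east - ge, north - gn) < 0.1
        assert residual <= g_res + 1e-6
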