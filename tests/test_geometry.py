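"""Sagittal frame fitting and 2D geometric primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chinpoint import (
    GeometryError,
    ProfilePoint,
    SagittalLine,
    facial_convexity_angle,
    fit_midsagittal_frame,
    lateral_coordinate,
    project,
    signed_distance_to_line,
)
from chinpoint.geometry import horizontal_offset_to_line

from .conftest import BASE_PROFILE, landmarks_from_profile, random_rigid

finite_mm = st.floats(-200.0, 200.0)


class TestFrameFit:
    def test_coplanar_landmarks_recover_their_plane_exactly(self):
        lset = landmarks_from_profile()
        frame = fit_midsagittal_frame(lset)
        for name in lset:
            assert abs(lateral_coordinate(lset[name], frame)) < 1e-9
        # origin convention and axis alignment
        profile = project(lset, frame)
        assert profile["Sn'"].a == pytest.approx(0.0, abs=1e-9)
        assert profile["Sn'"].s == pytest.approx(0.0, abs=1e-9)
        assert profile["Pn'"].a > 0  # pronasale anterior-positive
        for name, (a, s) in BASE_PROFILE.items():
            assert profile[name].a == pytest.approx(a, abs=1e-9)
            assert profile[name].s == pytest.approx(s, abs=1e-9)

    def test_projections_invariant_under_rigid_motion(self, rng):
        lset = landmarks_from_profile()
        frame = fit_midsagittal_frame(lset)
        base = project(lset, frame)
        for _ in range(10):
            R, t = random_rigid(rng)
            moved = lset.transformed(R, t)
            prof = project(moved, fit_midsagittal_frame(moved))
            for name in base:
                assert prof[name].a == pytest.approx(base[name].a, abs=1e-6)
                assert prof[name].s == pytest.approx(base[name].s, abs=1e-6)

    def test_lateral_noise_tilts_plane_only_slightly(self, rng):
        # Monte-Carlo vs the noise-free fit: +/-0.5 mm lateral noise on
        # landmarks spread over ~20 mm (anterior) x 90 mm (superior)
        # tilts the plane by ~noise/lever-arm: typically under a degree,
        # never by more than a few degrees.
        lset = landmarks_from_profile()
        true_normal = fit_midsagittal_frame(lset).lateral_axis
        tilts = []
        for _ in range(200):
            lateral = {n: rng.uniform(-0.5, 0.5) for n in BASE_PROFILE}
            noisy = landmarks_from_profile(lateral=lateral)
            normal = fit_midsagittal_frame(noisy).lateral_axis
            tilts.append(
                math.degrees(math.acos(min(1.0, abs(normal @ true_normal))))
            )
        assert np.median(tilts) < 1.0
        assert max(tilts) < 3.0

    def test_collinear_landmarks_rejected(self):
        profile = {n: (0.0, float(10 * i)) for i, n in enumerate(BASE_PROFILE)}
        with pytest.raises(GeometryError):
            fit_midsagittal_frame(landmarks_from_profile(profile))


class TestConvexityAngle:
    @pytest.mark.parametrize(
        "g, sn, pog, expected",
        [
            ((0, 80), (0, 0), (0, -60), 180.0),  # straight profile
            ((0, 10), (0, 0), (10, 0), 90.0),  # perpendicular rays
            # independently computed: arccos of the normalized dot product
            ((0, 80), (0, 0), (-8, -55), math.degrees(
                math.acos(-4400.0 / (80.0 * math.hypot(8.0, 55.0))))),
        ],
    )
    def test_known_configurations(self, g, sn, pog, expected):
        ang = facial_convexity_angle(
            ProfilePoint(*g), ProfilePoint(*sn), ProfilePoint(*pog)
        )
        assert ang == pytest.approx(expected, abs=1e-9)

    def test_mildly_convex_profile_value(self):
        # frozen from the arccos oracle: a chin 8 mm posterior at 55 mm drop
        ang = facial_convexity_angle(
            ProfilePoint(0, 80), ProfilePoint(0, 0), ProfilePoint(-8, -55)
        )
        assert ang == pytest.approx(171.7241, abs=5e-4)

    def test_zero_length_ray_rejected(self):
        p = ProfilePoint(0, 0)
        with pytest.raises(GeometryError):
            facial_convexity_angle(p, p, ProfilePoint(1, 1))

    @given(
        gx=finite_mm, gy=finite_mm, px=finite_mm, py=finite_mm,
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_in_rays_and_scale_invariant(self, gx, gy, px, py, scale):
        sn = ProfilePoint(0.0, 0.0)
        g, pog = ProfilePoint(gx, gy), ProfilePoint(px, py)
        if math.hypot(gx, gy) < 1e-3 or math.hypot(px, py) < 1e-3:
            return
        a1 = facial_convexity_angle(g, sn, pog)
        a2 = facial_convexity_angle(pog, sn, g)
        a3 = facial_convexity_angle(
            ProfilePoint(scale * gx, scale * gy), sn,
            ProfilePoint(scale * px, scale * py),
        )
        assert a1 == pytest.approx(a2, abs=1e-9)
        # arccos conditioning degrades near 0/180 deg; 1e-5 deg is the
        # attainable scale-invariance tolerance over the full range
        assert a1 == pytest.approx(a3, abs=1e-5)


class TestSignedDistance:
    def test_axis_aligned_vertical_line(self):
        line = SagittalLine(ProfilePoint(0, 0), np.array([0.0, -1.0]))
        assert signed_distance_to_line(ProfilePoint(3, -50), line) == pytest.approx(3.0)

    def test_oblique_line_example(self):
        # cross-product point-line oracle for the line through (12,-5), (8,-65)
        line = SagittalLine.through_points(ProfilePoint(12, -5), ProfilePoint(8, -65))
        d = signed_distance_to_line(ProfilePoint(14, -20), line)
        expected = 180.0 / math.hypot(4.0, 60.0)  # |(p-p0) x d| with sign anterior
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(2.99, abs=5e-3)

    def test_point_on_line_is_zero(self):
        line = SagittalLine.through_points(ProfilePoint(1, 2), ProfilePoint(4, -7))
        on = line.point_at(0.37)
        assert signed_distance_to_line(on, line) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_minimum_distance(self, rng):
        # dense sampling of line points; sign checked against anterior normal
        for _ in range(25):
            p0 = ProfilePoint(*rng.uniform(-50, 50, 2))
            q = ProfilePoint(*(p0.as_array() + rng.uniform(-60, 60, 2)))
            if np.linalg.norm(q.as_array() - p0.as_array()) < 1.0:
                continue
            line = SagittalLine.through_points(p0, q)
            p = ProfilePoint(*rng.uniform(-80, 80, 2))
            ts = np.linspace(-500, 500, 2_000_001)
            pts = p0.as_array()[None, :] + ts[:, None] * line.direction[None, :]
            brute = np.min(np.linalg.norm(pts - p.as_array()[None, :], axis=1))
            d = signed_distance_to_line(p, line)
            assert abs(d) == pytest.approx(brute, abs=1e-3)
            side = np.sign(line.anterior_normal() @ (p.as_array() - p0.as_array()))
            if side != 0:
                assert np.sign(d) == side

    def test_horizontal_offset_mode(self):
        line = SagittalLine.through_points(ProfilePoint(0, 0), ProfilePoint(10, -10))
        # at s = -5 the line passes a = 5; point at a = 8 is 3 mm anterior
        assert horizontal_offset_to_line(ProfilePoint(8, -5), line) == pytest.approx(3.0)
        flat = SagittalLine(ProfilePoint(0, 0), np.array([1.0, 0.0]))
        with pytest.raises(GeometryError):
            horizontal_offset_to_line(ProfilePoint(0, 1), flat)


def test_coincident_points_cannot_define_a_line():
    with pytest.raises(GeometryError):
        SagittalLine.through_points(ProfilePoint(1, 1), ProfilePoint(1, 1))
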