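"""Geometry kernel: rigid fitting, plane fitting, frames, angles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orthomove import (
    DegenerateGeometryError,
    Plane,
    ReferenceFrame,
    RigidTransform,
    build_reference_frame,
    fit_plane,
    fit_rigid_transform,
    orient_normal,
    sagittal_axis_angle,
)
from conftest import random_rigid

GENERIC_POINTS = np.array(
    [[0.0, 0.0, 0.0], [10.0, 1.0, -2.0], [3.0, 8.0, 5.0], [-4.0, 6.0, 9.0]]
)


class TestFitRigidTransform:
    def test_identity_on_equal_sets(self):
        t, fre = fit_rigid_transform(GENERIC_POINTS, GENERIC_POINTS)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)
        assert fre == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform(self):
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        truth = RigidTransform(rot, np.array([1.0, 2.0, 3.0]))
        target = truth.apply(GENERIC_POINTS)
        t, fre = fit_rigid_transform(GENERIC_POINTS, target)
        assert fre < 1e-9
        assert np.allclose(t.apply(GENERIC_POINTS), target, atol=1e-9)
        # held-out point is reproduced too
        held_out = np.array([7.0, -3.0, 2.0])
        assert np.allclose(t.apply(held_out), truth.apply(held_out), atol=1e-9)

    def test_proper_rotation_even_for_mirror_target(self):
        mirrored = GENERIC_POINTS * np.array([1.0, 1.0, -1.0])
        t, _ = fit_rigid_transform(GENERIC_POINTS, mirrored)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noise_monte_carlo_fre_and_angle(self, rng):
        """With sigma=0.1 mm target noise, FRE ~ sigma*sqrt((3n-6)/n) and the
        rotation is recovered to well under a degree on implant-like geometry."""
        implants = np.array(
            [[4.0, 13.0, -27.0], [9.0, 14.0, -22.0], [4.0, 37.0, -16.0], [9.0, 32.0, -19.0]]
        )
        truth = random_rigid(rng)
        target = truth.apply(implants)
        fres, angle_errors = [], []
        for _ in range(1000):
            noisy = target + rng.normal(0.0, 0.1, target.shape)
            t, fre = fit_rigid_transform(implants, noisy)
            fres.append(fre)
            err = t.compose(truth.inverse()).rotation_angle_deg()
            angle_errors.append(err)
        assert 0.05 < np.mean(fres) < 0.15
        assert np.mean(angle_errors) < 1.0

    @pytest.mark.parametrize(
        "source",
        [
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float),
            np.array([[1, 2, 3], [1, 2, 3], [5, 5, 5], [1, 2, 3]], dtype=float),
        ],
        ids=["collinear", "duplicated"],
    )
    def test_degenerate_source_rejected(self, source):
        with pytest.raises(DegenerateGeometryError):
            fit_rigid_transform(source, source + 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_rigid_transform(GENERIC_POINTS, GENERIC_POINTS[:3])


class TestRigidTransform:
    def test_identity_and_translation(self):
        assert np.allclose(RigidTransform.identity().apply(GENERIC_POINTS), GENERIC_POINTS)
        shift = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        assert np.allclose(shift.apply(np.zeros(3)), [1.0, 0.0, 0.0])

    def test_inverse_round_trip_and_isometry(self, rng):
        t = random_rigid(rng)
        pts = rng.normal(0, 20, (10, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)
        moved = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestFitPlane:
    def test_exact_horizontal_plane(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [3, 4, 0]], dtype=float)
        plane = fit_plane(pts)
        assert abs(plane.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)
        assert plane.offset == pytest.approx(0.0, abs=1e-12)

    def test_mirror_pairs_average_out(self):
        eps = 0.3
        base = np.array([[0, 0], [4, 0], [0, 5], [4, 5]], dtype=float)
        pts = np.vstack(
            [np.column_stack([base, np.full(4, eps)]), np.column_stack([base, np.full(4, -eps)])]
        )
        plane = fit_plane(pts)
        assert abs(plane.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert plane.offset == pytest.approx(0.0, abs=1e-9)

    def test_minimality_against_random_candidates(self, rng):
        pts = rng.normal(0, 10, (4, 3))
        plane = fit_plane(pts)
        best = np.sum(plane.signed_distance(pts) ** 2)
        normals = rng.normal(size=(10_000, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        offsets = normals @ pts.mean(axis=0) + rng.normal(0, 1.0, 10_000)
        residuals = ((pts @ normals.T - offsets) ** 2).sum(axis=0)
        assert best <= residuals.min() + 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane(np.array([[0, 0, 0], [1, 2, 3], [2, 4, 6]], dtype=float))


class TestProjection:
    def test_point_on_plane_is_fixed(self):
        plane = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        p = np.array([3.0, -2.0, 0.0])
        assert np.allclose(plane.project(p), p)

    def test_drops_to_foot_point(self):
        plane = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        assert np.allclose(plane.project(np.array([0.0, 0.0, 5.0])), np.zeros(3))

    def test_projection_is_nearest_plane_point(self, rng):
        plane = fit_plane(rng.normal(0, 5, (5, 3)))
        p = rng.normal(0, 10, 3)
        proj = plane.project(p)
        assert abs(plane.signed_distance(proj)) < 1e-9
        # sample many plane points: none is closer than the projection
        e1 = np.linalg.svd(np.eye(3) - np.outer(plane.normal, plane.normal))[0][:, :2]
        grid = proj + (rng.normal(0, 5, (2000, 2)) @ e1.T)
        assert np.linalg.norm(p - proj) <= np.linalg.norm(grid - p, axis=1).min() + 1e-12


class TestReferenceFrame:
    OCCLUSAL = np.array(
        [[-20.0, 5.0, 0.0], [20.0, 5.0, 0.0], [-3.0, 45.0, 0.0], [3.0, 45.0, 0.0]]
    )

    def test_axis_aligned_construction(self):
        # occlusal plane z=0, PNS above it, ANS anterior: frame axes fall on
        # the world axes with origin at the foot of PNS
        frame, plane1, plane2 = build_reference_frame(
            self.OCCLUSAL, ans=[0.0, 40.0, 8.0], pns=[0.0, 0.0, 10.0]
        )
        assert np.allclose(frame.origin, [0.0, 0.0, 0.0], atol=1e-9)
        assert np.allclose(frame.axis_x, [0.0, 0.0, 1.0], atol=1e-9)
        assert np.allclose(frame.axis_y, [0.0, 1.0, 0.0], atol=1e-9)
        assert abs(plane1.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)
        # plane 2 contains ANS, PNS and their projections
        for p in ([0, 40, 8], [0, 0, 10], [0, 40, 0], [0, 0, 0]):
            assert abs(plane2.signed_distance(np.array(p, dtype=float))) < 1e-9

    def test_gauge_invariance_of_frame_coordinates(self, rng):
        motion = random_rigid(rng)
        ans, pns = np.array([0.0, 40.0, 8.0]), np.array([0.0, 0.0, 10.0])
        landmarks = rng.normal(0, 20, (6, 3))
        frame, _, _ = build_reference_frame(self.OCCLUSAL, ans, pns)
        frame2, _, _ = build_reference_frame(
            motion.apply(self.OCCLUSAL), motion.apply(ans), motion.apply(pns)
        )
        # axes transform with the motion; coordinates do not change
        assert np.allclose(frame2.axis_x, motion.rotation @ frame.axis_x, atol=1e-9)
        assert np.allclose(
            frame2.coords(motion.apply(landmarks)), frame.coords(landmarks), atol=1e-9
        )

    def test_degenerate_skeletal_landmarks(self):
        with pytest.raises(DegenerateGeometryError):
            build_reference_frame(self.OCCLUSAL, ans=[0, 40, 8], pns=[0, 0, 1e-8])
        with pytest.raises(DegenerateGeometryError):
            # ANS directly above PNS: projections coincide
            build_reference_frame(self.OCCLUSAL, ans=[0, 0, 8], pns=[0, 0, 10])

    @given(
        coords=st.tuples(
            st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)
        )
    )
    def test_coords_round_trip(self, coords):
        frame, _, _ = build_reference_frame(
            self.OCCLUSAL, ans=[0.0, 40.0, 8.0], pns=[0.0, 0.0, 10.0]
        )
        c = np.array(coords)
        assert np.allclose(frame.coords(frame.point(c)), c, atol=1e-9)

    def test_origin_and_axis_coordinates(self):
        frame, _, _ = build_reference_frame(
            self.OCCLUSAL, ans=[0.0, 40.0, 8.0], pns=[0.0, 0.0, 10.0]
        )
        assert np.allclose(frame.coords(frame.origin), 0.0, atol=1e-12)
        assert np.allclose(
            frame.coords(frame.origin + 3.0 * frame.axis_y), [0.0, 3.0, 0.0], atol=1e-12
        )


class TestSagittalAxisAngle:
    def test_vertical_axis_is_zero(self, axis_frame):
        frame, plane1 = axis_frame
        theta_u, theta_s = sagittal_axis_angle(
            crown=[0.0, 5.0, 0.0], root=[12.0, 5.0, 0.0], frame=frame, plane1=plane1
        )
        assert theta_u == pytest.approx(0.0, abs=1e-9)
        assert theta_s == pytest.approx(0.0, abs=1e-9)

    def test_ten_degree_construction(self, axis_frame):
        frame, plane1 = axis_frame
        crown = [0.0, 5.0 + 10.0 * np.tan(np.radians(10.0)), 0.0]
        theta_u, theta_s = sagittal_axis_angle(crown, [10.0, 5.0, 0.0], frame, plane1)
        assert theta_u == pytest.approx(10.0, abs=1e-9)
        assert theta_s == pytest.approx(10.0, abs=1e-9)

    def test_posterior_crown_gives_negative_sign(self, axis_frame):
        frame, plane1 = axis_frame
        crown = [0.0, 5.0 - 10.0 * np.tan(np.radians(10.0)), 0.0]
        theta_u, theta_s = sagittal_axis_angle(crown, [10.0, 5.0, 0.0], frame, plane1)
        assert theta_u == pytest.approx(10.0, abs=1e-9)
        assert theta_s == pytest.approx(-10.0, abs=1e-9)

    def test_transverse_offset_is_ignored(self, axis_frame):
        frame, plane1 = axis_frame
        crown = np.array([0.0, 6.8, 0.0])
        root = np.array([10.0, 5.0, 0.0])
        ref = sagittal_axis_angle(crown, root, frame, plane1)
        off = np.array([0.0, 0.0, 7.5])
        shifted = sagittal_axis_angle(crown + off, root + off, frame, plane1)
        assert shifted == pytest.approx(ref, abs=1e-9)

    @given(
        theta=st.floats(-80, 80),
        root_x=st.floats(2.0, 20.0),
        root_y=st.floats(-10.0, 10.0),
    )
    def test_unsigned_is_magnitude_of_signed(self, axis_frame, theta, root_x, root_y):
        frame, plane1 = axis_frame
        direction = np.array([-np.cos(np.radians(theta)), np.sin(np.radians(theta)), 0.0])
        root = np.array([root_x, root_y, 0.0])
        crown = root + 11.0 * direction
        theta_u, theta_s = sagittal_axis_angle(crown, root, frame, plane1)
        assert theta_u == pytest.approx(abs(theta_s), abs=1e-12)
        assert theta_s == pytest.approx(theta, abs=1e-9)

    def test_root_on_occlusal_plane_is_degenerate(self, axis_frame):
        frame, plane1 = axis_frame
        with pytest.raises(DegenerateGeometryError):
            sagittal_axis_angle([5.0, 6.0, 0.0], [0.0, 5.0, 0.0], frame, plane1)


def test_orient_normal_flips_toward_point():
    plane = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
    flipped = orient_normal(plane, toward=[0.0, 0.0, -4.0])
    assert np.allclose(flipped.normal, [0.0, 0.0, -1.0])
    same = orient_normal(plane, toward=[0.0, 0.0, 4.0])
    assert np.allclose(same.normal, [0.0, 0.0, 1.0])
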