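"""Geometric validation: meshing, surface distances, ICP, cohort statistics."""

import numpy as np
import pytest

from osteoseg.geometry import (
    CohortStats,
    RigidTransform,
    SurfaceDistanceResult,
    _closest_point_pairwise,
    aggregate_cohort,
    apply_transform,
    closest_on_mesh,
    difference_mesh,
    distance_summary,
    extract_mesh,
    icp_register,
    surface_distance,
)
from osteoseg.io import LabelVolume, TriangleMesh

from conftest import digital_ball


def parallel_square(z, offset=0.0):
    """Unit square in the z-plane, two triangles."""
    v = np.array(
        [[offset, 0, z], [offset + 1, 0, z], [offset + 1, 1, z], [offset, 1, z]], dtype=float
    )
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(v, f)


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.eye(3) * 2.0)

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(rotation=R)

    def test_compose_inverse_is_identity(self):
        T = RigidTransform.from_axis_angle([1, 2, 3], 37.0, (4, -5, 6))
        I = T.compose(T.inverse())
        assert I.rotation_angle_deg() == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(I.translation_mm, 0.0, atol=1e-9)

    def test_apply_matches_matrix_action(self):
        T = RigidTransform.from_axis_angle([0, 0, 1], 90.0, (1, 0, 0))
        out = T.apply(np.array([[1.0, 0.0, 0.0]]))
        assert np.allclose(out, [[1.0, 1.0, 0.0]], atol=1e-12)


class TestExtractMesh:
    def test_ball_area_and_volume_isotropic(self):
        ball = digital_ball(20)
        tm = extract_mesh(ball, smooth_sigma_mm=1.0).as_trimesh()
        r = 20.0
        assert tm.area == pytest.approx(4 * np.pi * r**2, rel=0.03)
        assert tm.volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)
        assert tm.is_watertight

    def test_ball_area_and_volume_anisotropic(self):
        # the same 20 mm ball on the anisotropic MRI-like grid
        ball = digital_ball(None, spacing=(1.0, 0.4, 0.4), radius_mm=20.0)
        tm = extract_mesh(ball, smooth_sigma_mm=1.0).as_trimesh()
        r = 20.0
        assert tm.area == pytest.approx(4 * np.pi * r**2, rel=0.03)
        assert tm.volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)

    def test_vertices_inside_physical_bounding_box(self):
        ball = digital_ball(8, spacing=(1.0, 0.4, 0.4), radius_mm=5.0)
        mesh = extract_mesh(ball)
        lo = np.zeros(3) - ball.spacing_mm  # one padding voxel of slack
        hi = (np.array(ball.shape) - 1) * ball.spacing_mm + ball.spacing_mm
        assert np.all(mesh.vertices >= lo - 1e-9) and np.all(mesh.vertices <= hi + 1e-9)

    def test_empty_mask_errors(self):
        empty = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32),
                            label_codes={"background": 0, "bone": 1})
        with pytest.raises(ValueError, match="no surface"):
            extract_mesh(empty)

    def test_border_touching_object_still_watertight(self):
        mask = np.ones((4, 4, 4), dtype=np.int32)
        lab = LabelVolume(mask, label_codes={"background": 0, "bone": 1})
        assert extract_mesh(lab).is_watertight()


class TestSurfaceDistance:
    def test_identity_gives_zero(self, femur_mask):
        mesh = extract_mesh(femur_mask)
        sd = surface_distance(mesh, mesh)
        assert sd.asd_mm == pytest.approx(0.0, abs=1e-12)
        assert sd.rsd_mm == pytest.approx(0.0, abs=1e-12)

    def test_parallel_planes_distance_exact(self):
        S = parallel_square(z=2.0)
        R = parallel_square(z=0.0)
        sd = surface_distance(S, R, signed=False)
        assert sd.asd_mm == pytest.approx(2.0, abs=1e-12)
        assert sd.rsd_mm == pytest.approx(2.0, abs=1e-12)

    def test_concentric_spheres_analytic_distance(self):
        inner = extract_mesh(digital_ball(10, shape=(33, 33, 33)), smooth_sigma_mm=1.5)
        outer = extract_mesh(digital_ball(12, shape=(33, 33, 33)), smooth_sigma_mm=1.5)
        sd = surface_distance(inner, outer)
        assert sd.asd_mm == pytest.approx(2.0, abs=0.05)
        assert np.all(sd.per_point_signed_mm < 0)  # inner lies inside the reference

    def test_signed_magnitude_equals_unsigned(self):
        inner = extract_mesh(digital_ball(6, shape=(27, 27, 27)), smooth_sigma_mm=1.0)
        outer = extract_mesh(digital_ball(9, shape=(27, 27, 27)), smooth_sigma_mm=1.0)
        sd = surface_distance(inner, outer)
        assert np.allclose(np.abs(sd.per_point_signed_mm), sd.per_point_distance_mm)

    def test_one_directional_asymmetry(self):
        # S = one ball; R = the same ball plus a distant second ball.
        z, y, x = np.mgrid[:21, :21, :60]
        one = (z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2 <= 36
        far = (z - 10) ** 2 + (y - 10) ** 2 + (x - 46) ** 2 <= 36
        codes = {"background": 0, "bone": 1}
        S = extract_mesh(LabelVolume(one.astype(np.int32), label_codes=codes),
                         smooth_sigma_mm=1.0)
        R = extract_mesh(LabelVolume((one | far).astype(np.int32), label_codes=codes),
                         smooth_sigma_mm=1.0)
        fwd = surface_distance(S, R, signed=False)
        rev = surface_distance(R, S, signed=False)
        assert fwd.asd_mm < 0.2  # S is (nearly) a subset of R's surface
        assert rev.asd_mm > 5.0  # the far component has no counterpart in S
        sym = surface_distance(S, R, signed=False, symmetric=True)
        assert sym.asd_mm == pytest.approx(0.5 * (fwd.asd_mm + rev.asd_mm), abs=1e-9)
        assert sym.asd_mm >= max(fwd.asd_mm, rev.asd_mm) / 2

    def test_rms_at_least_mean_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            d = rng.uniform(0, 5, size=rng.integers(1, 40))
            asd, rsd = distance_summary(d)
            assert rsd >= asd - 1e-12

    def test_rsd_equals_asd_iff_constant(self):
        asd, rsd = distance_summary(np.full(50, 3.3))
        assert rsd == pytest.approx(asd, abs=1e-12)
        asd2, rsd2 = distance_summary(np.array([1.0, 3.0]))
        assert rsd2 > asd2

    def test_exact_against_brute_force_scan(self):
        # small meshes: KD-pruned minima must equal an all-triangles scan
        mesh = extract_mesh(digital_ball(2), smooth_sigma_mm=0.0)
        assert mesh.n_faces <= 200
        rng = np.random.default_rng(1)
        points = rng.uniform(-2, 9, size=(50, 3))
        dist, _, _, _ = closest_on_mesh(points, mesh, signed=False)
        tris = mesh.vertices[mesh.faces]
        for k in range(len(points)):
            cp = _closest_point_pairwise(np.tile(points[k], (len(tris), 1)), tris)
            brute = np.linalg.norm(points[k] - cp, axis=1).min()
            assert dist[k] == pytest.approx(brute, abs=1e-12)

    def test_empty_mesh_rejected(self):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            surface_distance(empty, parallel_square(0.0))


class TestAggregateCohort:
    def result(self, asd, rsd=None):
        rsd = asd if rsd is None else rsd
        return SurfaceDistanceResult(
            per_point_distance_mm=np.array([asd]),
            per_point_signed_mm=np.array([asd]),
            asd_mm=asd,
            rsd_mm=rsd,
        )

    def test_single_case_zero_variance(self):
        stats = aggregate_cohort([self.result(1.5)])
        assert stats.asd_avg_mm == 1.5 and stats.asd_var_mm == 0.0 and stats.n_cases == 1

    def test_two_case_arithmetic(self):
        stats = aggregate_cohort([self.result(1.0), self.result(3.0)])
        assert stats.asd_avg_mm == pytest.approx(2.0)
        assert stats.asd_var_mm == pytest.approx(1.0)  # population variance
        assert stats.asd_sd_mm == pytest.approx(1.0)

    def test_permutation_invariance(self):
        cases = [self.result(v) for v in (0.2, 1.1, 0.7, 2.0)]
        a = aggregate_cohort(cases)
        b = aggregate_cohort(cases[::-1])
        assert a == b

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            aggregate_cohort([])


class TestDifferenceMesh:
    def test_identity_case_all_zero_scalar(self, femur_mask):
        mesh = extract_mesh(femur_mask)
        sd = surface_distance(mesh, mesh)
        diff = difference_mesh(mesh, sd)
        assert diff.vertex_scalar.shape == (mesh.n_vertices,)
        assert np.allclose(diff.vertex_scalar, 0.0, atol=1e-12)

    def test_concentric_case_constant_negative_scalar(self):
        inner = extract_mesh(digital_ball(10, shape=(33, 33, 33)), smooth_sigma_mm=1.5)
        outer = extract_mesh(digital_ball(12, shape=(33, 33, 33)), smooth_sigma_mm=1.5)
        sd = surface_distance(inner, outer)
        diff = difference_mesh(inner, sd)
        assert diff.vertex_scalar.mean() == pytest.approx(-2.0, abs=0.05)

    def test_length_mismatch_errors(self, femur_mask):
        mesh = extract_mesh(femur_mask)
        sd = surface_distance(mesh, mesh)
        short = SurfaceDistanceResult(
            per_point_distance_mm=sd.per_point_distance_mm[:-1],
            per_point_signed_mm=sd.per_point_signed_mm[:-1],
            asd_mm=0.0,
            rsd_mm=0.0,
        )
        with pytest.raises(ValueError):
            difference_mesh(mesh, short)


class TestICP:
    def test_identical_meshes_give_identity(self, femur_mask):
        mesh = extract_mesh(femur_mask, smooth_sigma_mm=1.0)
        res = icp_register(mesh, mesh)
        assert res.converged
        assert res.transform.rotation_angle_deg() <= 1e-6
        assert np.linalg.norm(res.transform.translation_mm) <= 1e-6

    def test_known_transform_recovered(self, femur_mask):
        mesh = extract_mesh(femur_mask, smooth_sigma_mm=1.0)
        T = RigidTransform.from_axis_angle([0.3, 0.5, 0.8], 10.0, (1, 2, 3))
        source = apply_transform(mesh, T.inverse())
        res = icp_register(source, mesh)
        err = res.transform.compose(T.inverse())
        assert res.converged
        assert err.rotation_angle_deg() <= 0.05
        centroid = source.vertices.mean(axis=0)
        assert np.linalg.norm(res.transform.apply(centroid) - T.apply(centroid)) <= 0.02

    def test_robust_to_10pct_outliers_with_trimming(self, femur_mask):
        mesh = extract_mesh(femur_mask, smooth_sigma_mm=1.0)
        T = RigidTransform.from_axis_angle([0.3, 0.5, 0.8], 10.0, (1, 2, 3))
        source = apply_transform(mesh, T.inverse())
        rng = np.random.default_rng(12345)
        v = source.vertices.copy()
        idx = rng.choice(len(v), len(v) // 10, replace=False)
        v[idx] += rng.normal(0, 5, size=(len(idx), 3))
        noisy = TriangleMesh(v, source.faces)
        res = icp_register(noisy, mesh, trim_fraction=0.2, seed=0)
        err = res.transform.compose(T.inverse())
        assert err.rotation_angle_deg() <= 0.5
        centroid = source.vertices.mean(axis=0)
        assert np.linalg.norm(res.transform.apply(centroid) - T.apply(centroid)) <= 0.2

    def test_empty_mesh_rejected(self):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            icp_register(empty, parallel_square(0.0))
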