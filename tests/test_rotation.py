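import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import fibonacci_sphere, run_synthetic_pipeline
from ribrot import (
    DegenerateGeometryError,
    MatchedPairs,
    RotationConfig,
    RotationField,
    SyntheticAssemblySpec,
    build_rotation_field,
    fit_rotation_center,
    fit_separating_plane,
    per_atom_angles,
    summarize_rotation,
    tangentiality_objective,
)
from ribrot.rotation import SeparatingPlane


def _mobile_pairs(pos_a, pos_b):
    pos_a = np.asarray(pos_a, dtype=float)
    keys = [("M", i + 1, "", "P") for i in range(pos_a.shape[0])]
    return MatchedPairs(keys=keys, pos_a=pos_a, pos_b=np.asarray(pos_b),
                        role=np.array(["mobile"] * pos_a.shape[0],
                                      dtype=object))


def _circle_field(center, radius, theta_deg, n=40, min_disp=0.5,
                  phase=0.0):
    """Exact in-plane rotation field on a circle (as a RotationField)."""
    phi = phase + np.linspace(0, 2 * np.pi, n, endpoint=False)
    start = np.asarray(center) + radius * np.stack(
        [np.cos(phi), np.sin(phi)], axis=1)
    th = np.radians(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    end = (start - center) @ rot.T + center
    disp = end - start
    disp_3d = np.linalg.norm(disp, axis=1)
    return RotationField(
        keys=[("M", i + 1, "", "P") for i in range(n)],
        start_2d=start, disp_2d=disp, disp_3d=disp_3d,
        retained=disp_3d > min_disp, min_displacement=min_disp)


class TestSeparatingPlane:
    def _symmetric_clouds(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(-30, 30, size=(60, 2))
        ref = np.vstack([np.column_stack([xy, np.full(60, -10.0)]),
                         np.column_stack([xy, np.full(60, -2.0)])])
        mob = np.vstack([np.column_stack([xy, np.full(60, 2.0)]),
                         np.column_stack([xy, np.full(60, 10.0)])])
        return ref, mob

    def test_symmetry_forces_z_normal(self):
        ref, mob = self._symmetric_clouds()
        plane = fit_separating_plane(ref, mob)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-6)
        assert abs(plane.origin[2]) < 1e-6

    def test_normal_points_toward_mobile(self):
        ref, mob = self._symmetric_clouds()
        plane = fit_separating_plane(mob, ref)  # roles swapped
        np.testing.assert_allclose(plane.normal, [0, 0, -1], atol=1e-6)

    def test_fisher_matches_direction_grid_oracle(self):
        """Brute-force search over 10,000 unit directions for the best
        Fisher criterion agrees with the closed form."""
        rng = np.random.default_rng(21)
        ref = rng.normal(size=(50, 3)) @ np.diag([4.0, 1.5, 1.0])
        mob = rng.normal(size=(50, 3)) @ np.diag([1.0, 3.0, 1.5]) \
            + np.array([3.0, 2.0, 6.0])
        plane = fit_separating_plane(ref, mob)

        def criterion(direction):
            pr = ref @ direction
            pm = mob @ direction
            within = 0.5 * (pr.var(ddof=1) + pm.var(ddof=1))
            return (pm.mean() - pr.mean()) ** 2 / within

        grid = fibonacci_sphere(10000)
        values = np.array([criterion(d) for d in grid])
        best = grid[values.argmax()]
        # closed form is at least as good as any grid direction
        assert criterion(plane.normal) >= values.max() * (1 - 1e-9)
        angle = np.degrees(np.arccos(np.clip(abs(best @ plane.normal),
                                             -1, 1)))
        assert angle <= 2.5  # angular resolution of 10k sphere points

    def test_identical_clouds_inseparable(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        with pytest.raises(DegenerateGeometryError, match="inseparable"):
            fit_separating_plane(pts, pts.copy())

    def test_basis_is_right_handed_orthonormal(self):
        rng = np.random.default_rng(22)
        for _ in range(5):
            ref = rng.normal(size=(30, 3)) + rng.uniform(-50, 50, 3)
            mob = rng.normal(size=(30, 3)) + rng.uniform(-50, 50, 3)
            plane = fit_separating_plane(ref, mob)
            np.testing.assert_allclose(
                np.cross(plane.basis_u, plane.basis_v), plane.normal,
                atol=1e-9)

    def test_pca_gap_method_on_separated_clouds(self):
        rng = np.random.default_rng(23)
        ref = rng.normal(size=(40, 3)) + [0, 0, -8]
        mob = rng.normal(size=(40, 3)) + [0, 0, 8]
        plane = fit_separating_plane(ref, mob,
                                     RotationConfig(plane_method="pca_gap"))
        assert abs(plane.normal @ np.array([0, 0, 1.0])) > 0.99

    def test_too_few_atoms(self):
        with pytest.raises(DegenerateGeometryError):
            fit_separating_plane(np.zeros((2, 3)), np.ones((5, 3)))


def _xy_plane():
    return SeparatingPlane(normal=[0, 0, 1.0], origin=[0, 0, 0.0],
                           basis_u=[1.0, 0, 0], basis_v=[0, 1.0, 0],
                           separation_score=10.0)


class TestRotationField:
    @pytest.fixture
    def plane(self):
        return _xy_plane()

    def test_no_motion_nothing_retained(self, plane):
        pos = np.random.default_rng(2).normal(size=(10, 3))
        fld = build_rotation_field(_mobile_pairs(pos, pos), plane)
        assert fld.n_retained == 0
        np.testing.assert_array_equal(fld.disp_3d, np.zeros(10))

    def test_filter_is_strictly_greater_than(self, plane):
        pos_a = np.zeros((4, 3))
        pos_b = np.array([[3.0, 0, 0], [0, 3.0 + 1e-9, 0],
                          [0, 0, 2.999], [4.0, 0, 0]])
        fld = build_rotation_field(_mobile_pairs(pos_a, pos_b), plane)
        np.testing.assert_array_equal(fld.retained,
                                      [False, True, False, True])

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_projection_never_lengthens(self, seed):
        plane = _xy_plane()
        rng = np.random.default_rng(seed)
        pos_a = rng.normal(scale=20, size=(30, 3))
        pos_b = pos_a + rng.normal(scale=4, size=(30, 3))
        fld = build_rotation_field(_mobile_pairs(pos_a, pos_b), plane)
        assert np.all(np.linalg.norm(fld.disp_2d, axis=1)
                      <= fld.disp_3d + 1e-9)

    def test_retained_count_matches_chord_census(self):
        """Noiseless 10° rotation: the retention census follows the chord
        closed form 2·r·sin(θ/2) from the generator manifest."""
        spec = SyntheticAssemblySpec(true_angle_deg=10.0, noise_sd=0.0,
                                     seed=31)
        (_, fld, summary), manifest = run_synthetic_pipeline(
            spec, use_true_plane=True)
        expected = int((manifest.true_chords > 3.0).sum())
        assert fld.n_retained == expected
        assert manifest.expected_retained(3.0) == expected

    @given(t1=st.floats(0, 12), t2=st.floats(0, 12))
    @settings(max_examples=25, deadline=None)
    def test_raising_threshold_monotone(self, t1, t2):
        plane = _xy_plane()
        rng = np.random.default_rng(5)
        pos_a = rng.normal(scale=20, size=(50, 3))
        pos_b = pos_a + rng.normal(scale=4, size=(50, 3))
        lo, hi = sorted([t1, t2])
        pairs = _mobile_pairs(pos_a, pos_b)
        n_lo = build_rotation_field(
            pairs, plane, RotationConfig(min_displacement=lo)).n_retained
        n_hi = build_rotation_field(
            pairs, plane, RotationConfig(min_displacement=hi)).n_retained
        assert n_hi <= n_lo


class TestRotationCenter:
    def test_exact_circle_recovery(self):
        fld = _circle_field(center=(10.0, -5.0), radius=50.0, theta_deg=5.0)
        summary = fit_rotation_center(fld)
        np.testing.assert_allclose(summary.center_2d, [10.0, -5.0],
                                   atol=1e-3)
        assert summary.objective_at_optimum <= 1e-10

    def test_noisy_center_matches_exhaustive_grid(self):
        """0.1 Å-step exhaustive search over a window around the optimum
        agrees with the grid+simplex fit."""
        spec = SyntheticAssemblySpec(seed=41)
        (_, fld, summary), _ = run_synthetic_pipeline(spec,
                                                      use_true_plane=True)
        start = fld.start_2d[fld.retained]
        disp = fld.disp_2d[fld.retained]
        unit = disp / np.linalg.norm(disp, axis=1, keepdims=True)
        mid = start + 0.5 * disp
        span = np.arange(-10.0, 10.0 + 0.1, 0.1)
        gu, gv = np.meshgrid(summary.center_2d[0] + span,
                             summary.center_2d[1] + span, indexing="ij")
        centers = np.stack([gu.ravel(), gv.ravel()], axis=1)
        radial = mid[None, :, :] - centers[:, None, :]
        norms = np.linalg.norm(radial, axis=2)
        cos = np.einsum("cij,ij->ci", radial, unit) / norms
        values = np.mean(cos ** 2, axis=1)
        grid_best = centers[values.argmin()]
        assert np.linalg.norm(summary.center_2d - grid_best) <= 0.1
        assert summary.objective_at_optimum <= values.min() + 1e-12
        # optimum does not sit on the window edge
        assert np.abs(summary.center_2d - grid_best).max() < 9.0

    def test_pure_translation_rejected(self):
        rng = np.random.default_rng(6)
        start = rng.uniform(-50, 50, size=(40, 2))
        disp = np.tile([5.0, 0.0], (40, 1))
        fld = RotationField(
            keys=[("M", i + 1, "", "P") for i in range(40)],
            start_2d=start, disp_2d=disp,
            disp_3d=np.full(40, 5.0), retained=np.full(40, True),
            min_displacement=3.0)
        with pytest.raises(DegenerateGeometryError,
                           match="no rotation center"):
            fit_rotation_center(fld)

    def test_insufficient_retained_atoms(self):
        fld = _circle_field((0, 0), 30.0, 5.0, n=5, min_disp=10.0)
        assert fld.n_retained == 0
        with pytest.raises(DegenerateGeometryError, match="insufficient"):
            fit_rotation_center(fld)

    def test_objective_zero_iff_perpendicular_bisectors_meet(self):
        fld = _circle_field((0.0, 0.0), 40.0, 12.0)
        mid = fld.start_2d + 0.5 * fld.disp_2d
        unit = fld.disp_2d / np.linalg.norm(fld.disp_2d, axis=1,
                                            keepdims=True)
        assert tangentiality_objective(np.zeros(2), mid, unit) < 1e-28
        assert tangentiality_objective(np.array([5.0, 0.0]), mid, unit) > 1e-4


class TestPerAtomAngles:
    def _field_from_rows(self, start, disp2, disp3=None, min_disp=0.5):
        start = np.asarray(start, dtype=float)
        disp2 = np.asarray(disp2, dtype=float)
        disp3 = (np.linalg.norm(disp2, axis=1) if disp3 is None
                 else np.asarray(disp3, dtype=float))
        return RotationField(
            keys=[("M", i + 1, "", "P") for i in range(start.shape[0])],
            start_2d=start, disp_2d=disp2, disp_3d=disp3,
            retained=disp3 > min_disp, min_displacement=min_disp)

    def test_unit_radius_unit_chord_is_sixty_degrees(self):
        fld = self._field_from_rows([[1.0, 0.0]], [[-0.6, 0.8]])
        _, radii, angles = per_atom_angles(fld, np.zeros(2))
        assert radii[0] == pytest.approx(1.0)
        assert angles[0] == pytest.approx(60.0, abs=1e-9)

    def test_zero_chord_is_zero_degrees(self):
        # out-of-plane displacement: retained in 3D, no in-plane chord
        fld = self._field_from_rows([[10.0, 0.0]], [[0.0, 0.0]],
                                    disp3=[4.0])
        _, _, angles = per_atom_angles(fld, np.zeros(2))
        assert angles[0] == 0.0

    def test_pure_rotation_angles_exact_at_all_radii(self):
        spec = SyntheticAssemblySpec(noise_sd=0.0, seed=51)
        (_, fld, summary), _ = run_synthetic_pipeline(spec,
                                                      use_true_plane=True)
        np.testing.assert_allclose(summary.per_atom_angle_deg, 5.2,
                                   atol=1e-6)

    def test_atom_at_center_excluded_with_warning(self, caplog):
        fld = self._field_from_rows([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]],
                                    [[1.0, 0.0], [0.0, 2.0], [-2.0, 0.0]])
        with caplog.at_level("WARNING"):
            idx, radii, angles = per_atom_angles(fld, np.zeros(2))
        assert len(angles) == 2
        assert "center" in caplog.text

    def test_no_retained_atoms_is_error(self):
        fld = self._field_from_rows([[10.0, 0.0]], [[0.1, 0.0]],
                                    min_disp=3.0)
        with pytest.raises(DegenerateGeometryError):
            per_atom_angles(fld, np.zeros(2))


class TestSummarize:
    def test_uniform_rotation_summary_and_iqr(self):
        fld = _circle_field((0.0, 0.0), 45.0, 7.0)
        center = fit_rotation_center(fld)
        summary = summarize_rotation(fld, center)
        assert summary.summary_angle_deg == pytest.approx(7.0, abs=1e-6)
        assert summary.angle_dispersion == pytest.approx(0.0, abs=1e-6)
        assert summary.sign == "ccw"

    def test_median_robust_to_remodeled_outlier(self):
        # three atoms at equal radius rotated by 1°, 2°, 100°
        parts = [_circle_field((0, 0), 30.0, t, n=1, phase=p)
                 for t, p in ((1.0, 0.0), (2.0, 2.0), (100.0, 4.0))]
        fld = RotationField(
            keys=[("M", i + 1, "", "P") for i in range(3)],
            start_2d=np.vstack([p.start_2d for p in parts]),
            disp_2d=np.vstack([p.disp_2d for p in parts]),
            disp_3d=np.concatenate([p.disp_3d for p in parts]),
            retained=np.full(3, True), min_displacement=0.0)
        from ribrot import RotationSummary
        center = RotationSummary(center_2d=np.zeros(2),
                                 objective_at_optimum=0.0, n_retained=3)
        summary = summarize_rotation(fld, center)
        assert summary.summary_angle_deg == pytest.approx(2.0, abs=1e-9)
        mean = summarize_rotation(fld, center,
                                  RotationConfig(angle_summary="mean"))
        assert mean.summary_angle_deg == pytest.approx(103.0 / 3, abs=1e-9)

    def test_clockwise_sign(self):
        fld = _circle_field((0.0, 0.0), 45.0, -6.0)
        center = fit_rotation_center(fld)
        summary = summarize_rotation(fld, center)
        assert summary.sign == "cw"
        assert summary.summary_angle_deg == pytest.approx(6.0, abs=1e-6)

    def test_displacement_filter_reduces_noise_error(self):
        """With the rotation center inside the mobile cloud, small-radius
        atoms barely move and their displacements are noise-dominated;
        filtering them makes the (mean) angle estimate better."""
        filtered_err, unfiltered_err = [], []
        for seed in range(15):
            spec = SyntheticAssemblySpec(seed=seed, true_center_2d=(0.0, 0.0))
            cfg_f = RotationConfig(min_displacement=3.0, angle_summary="mean")
            cfg_u = RotationConfig(min_displacement=0.0, angle_summary="mean")
            (_, _, s_f), _ = run_synthetic_pipeline(spec, cfg_f,
                                                    use_true_plane=True)
            (_, _, s_u), _ = run_synthetic_pipeline(spec, cfg_u,
                                                    use_true_plane=True)
            filtered_err.append(abs(s_f.summary_angle_deg - 5.2))
            unfiltered_err.append(abs(s_u.summary_angle_deg - 5.2))
        assert np.median(filtered_err) < np.median(unfiltered_err)
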