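import numpy as np
import pytest
from scipy.stats import anderson

import femrisk as fr
from femrisk.strength import (
    DOMAIN_AREA,
    AnisotropyShape,
    SurfaceGenParams,
    quadrature_weights,
    synthesize_shape,
)


class TestOrientationGrid:
    @pytest.mark.parametrize("M", [4, 15, 33, 66, 231])
    def test_coverage_and_count(self, M):
        grid = fr.build_orientation_grid(M)
        assert grid.M == M
        assert grid.triangle_areas().sum() == pytest.approx(DOMAIN_AREA)
        assert grid.points[:, 0].min() == -30 and grid.points[:, 0].max() == 30
        assert grid.points[:, 1].min() == 0 and grid.points[:, 1].max() == 30

    def test_four_point_grid_is_corners(self):
        grid = fr.build_orientation_grid(4)
        corners = {(-30.0, 0.0), (30.0, 0.0), (-30.0, 30.0), (30.0, 30.0)}
        assert {tuple(p) for p in grid.points} == corners
        assert len(grid.triangles) == 2

    def test_33_point_lattice_spacing(self):
        grid = fr.build_orientation_grid(33)
        alphas = np.unique(grid.points[:, 0])
        betas = np.unique(grid.points[:, 1])
        assert len(alphas) == 11 and np.allclose(np.diff(alphas), 6.0)
        assert len(betas) == 3 and np.allclose(np.diff(betas), 15.0)

    def test_unsupported_count_rejected(self):
        with pytest.raises(ValueError):
            fr.build_orientation_grid(7)


class TestIntegrateField:
    def test_constant_field_normalisation(self):
        grid = fr.build_orientation_grid(15)
        assert fr.integrate_field(np.full(15, 0.2), grid) == pytest.approx(0.2)

    @pytest.mark.parametrize("M", [15, 33, 231])
    def test_odd_field_integrates_to_zero(self, M):
        grid = fr.build_orientation_grid(M)
        assert fr.integrate_field(grid.points[:, 0] / 30.0, grid) == pytest.approx(0.0, abs=1e-14)

    def test_against_dense_midpoint_oracle(self):
        # random smooth field sampled at the nodes: the closed-form quadrature
        # of its interpolant must agree with a brute-force dense midpoint rule
        # applied to the same interpolant
        rng = np.random.default_rng(4)
        c = rng.normal(0, 0.3, 6)

        def func(a, b):
            x, y = a / 30.0, (b - 15.0) / 15.0
            return 1.0 + c[0] * x + c[1] * y + c[2] * x * y + c[3] * x**2 + c[4] * y**2 + c[5] * np.sin(x)

        grid = fr.build_orientation_grid(231)
        values = func(grid.points[:, 0], grid.points[:, 1])
        nodal = fr.integrate_field(values, grid)
        xs = np.linspace(-30, 30, 600, endpoint=False) + 30 / 600
        ys = np.linspace(0, 30, 300, endpoint=False) + 15 / 300
        dense = np.nanmean(fr.interpolate_field(values, grid, *np.meshgrid(xs, ys)))
        assert nodal == pytest.approx(dense, rel=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fr.integrate_field(np.ones(10), fr.build_orientation_grid(15))

    def test_quadrature_weights_agree_with_integral(self):
        grid = fr.build_orientation_grid(33)
        w = quadrature_weights(grid)
        v = np.random.default_rng(0).random(33)
        assert w.sum() == pytest.approx(1.0)
        assert w @ v == pytest.approx(fr.integrate_field(v, grid))

    def test_indicator_integral_monotone_in_force(self):
        grid = fr.build_orientation_grid(33)
        S = 2000 + 500 * np.random.default_rng(1).random(33)
        probs = [fr.integrate_field((F >= S).astype(float), grid) for F in np.linspace(1500, 3000, 20)]
        assert np.all(np.diff(probs) >= 0)


class TestInterpolation:
    def test_exact_at_nodes(self):
        grid = fr.build_orientation_grid(33)
        v = np.random.default_rng(2).random(33) + 1
        out = fr.interpolate_field(v, grid, grid.points[:, 0], grid.points[:, 1])
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_linear_field_reproduced_between_nodes(self):
        grid = fr.build_orientation_grid(33)
        v = 2.0 + 0.1 * grid.points[:, 0] - 0.05 * grid.points[:, 1]
        a, b = np.array([-12.3, 7.7]), np.array([4.4, 22.2])
        np.testing.assert_allclose(fr.interpolate_field(v, grid, a, b), 2.0 + 0.1 * a - 0.05 * b, atol=1e-12)


class TestSurface:
    def test_stats(self):
        grid = fr.build_orientation_grid(4)
        surf = fr.StrengthSurface("s", grid, np.array([1000.0, 2000.0, 3000.0, 2000.0]))
        assert fr.surface_stats(surf) == (1000.0, 3000.0, 2000.0)

    def test_constant_surface(self):
        grid = fr.build_orientation_grid(15)
        surf = fr.StrengthSurface("s", grid, np.full(15, 3000.0))
        assert fr.surface_stats(surf) == (3000.0, 3000.0, 3000.0)

    def test_nonpositive_values_rejected(self):
        grid = fr.build_orientation_grid(4)
        with pytest.raises(ValueError):
            fr.StrengthSurface("s", grid, np.array([1000.0, -1.0, 2000.0, 1.0]))


class TestSynthesizer:
    def test_unit_grid_mean(self):
        subject = fr.Subject("s", 60, 1.6)
        surf = fr.synthesize_surface(subject, fr.SurfaceGenParams(), np.random.default_rng(3), mean_strength=2500.0)
        assert surf.values.mean() == pytest.approx(2500.0)
        assert np.all(surf.values > 0)

    def test_degenerate_generator_perfectly_correlated(self):
        # zero shape variance: every surface is a scalar multiple of the mean surface
        params = fr.SurfaceGenParams(coeff_sd=0.0)
        rng = np.random.default_rng(4)
        subj = fr.Subject("s", 60, 1.6)
        a = fr.synthesize_surface(subj, params, rng, mean_strength=2000.0)
        b = fr.synthesize_surface(subj, params, rng, mean_strength=3500.0)
        assert np.corrcoef(a.values, b.values)[0, 1] == pytest.approx(1.0)

    def test_excessive_anisotropy_rejected(self):
        params = fr.SurfaceGenParams(shared_coeffs=(5.0, 0.0, 0.0, 0.0, 0.0), coeff_sd=0.0)
        with pytest.raises(ValueError):
            fr.synthesize_surface(fr.Subject("s", 60, 1.6), params, np.random.default_rng(0))

    def test_shape_continuous_unit_mean(self):
        shape = synthesize_shape(SurfaceGenParams(), np.random.default_rng(5))
        xs = np.linspace(-30, 30, 400, endpoint=False) + 30 / 400
        ys = np.linspace(0, 30, 200, endpoint=False) + 15 / 200
        assert shape.evaluate(*np.meshgrid(xs, ys)).mean() == pytest.approx(1.0, abs=1e-4)


class TestCohortSurfaceStatistics:
    def test_normality_across_subjects_at_most_orientations(self, cohort):
        # strength is normally distributed across subjects at >= 75% of orientations
        subjects, surfaces, _ = cohort
        vals = np.array([surfaces[s.subject_id].values for s in subjects])
        passed = 0
        for j in range(vals.shape[1]):
            res = anderson(vals[:, j], dist="norm")
            crit = res.critical_values[list(res.significance_level).index(5.0)]
            passed += res.statistic < crit
        assert passed >= 0.75 * vals.shape[1]

    def test_surfaces_correlate_with_population_mean(self, cohort):
        # >= 85% of subjects at least moderately correlated (r >= 0.5) with the mean surface
        subjects, surfaces, _ = cohort
        vals = np.array([surfaces[s.subject_id].values for s in subjects])
        mean_surface = vals.mean(axis=0)
        r = np.array([np.corrcoef(v, mean_surface)[0, 1] for v in vals])
        assert np.mean(r >= 0.5) >= 0.85

    def test_per_subject_extrema_finite_positive(self, cohort):
        subjects, surfaces, _ = cohort
        for s in subjects:
            smin, smax, _ = fr.surface_stats(surfaces[s.subject_id])
            assert 0 < smin <= smax < np.inf
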