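import numpy as np
import pytest

import femrisk as fr
from femrisk.domain import TruncatedNormalSpec
from femrisk.strength import quadrature_weights


def _constant_surface(value, M=33, sid="s"):
    grid = fr.build_orientation_grid(M)
    return fr.StrengthSurface(sid, grid, np.full(M, float(value)))


SUBJECT = fr.Subject("s", m=63.75, H=1.58)


class TestFractureIndicator:
    @pytest.mark.parametrize("F, S, expected", [(2500, 2000, 1), (1500, 2000, 0), (2000, 2000, 1)])
    def test_inclusive_comparison(self, F, S, expected):
        assert fr.fracture_indicator(F, S) == expected

    def test_vectorised(self):
        np.testing.assert_array_equal(fr.fracture_indicator([1.0, 3.0], [2.0, 2.0]), [0, 1])


class TestArf0:
    def test_guideline_fall_fracture_rate(self):
        # 3% of falls fracturing at 0.65 falls/yr gives a 1.96% annual risk
        assert fr.arf0_from_p(0.03, 0.65) == pytest.approx(1.96, abs=0.005)

    def test_zero_probability(self):
        assert fr.arf0_from_p(0.0, 1.3) == 0.0

    def test_certain_fracture(self):
        assert fr.arf0_from_p(1.0, 0.65) == 100.0

    def test_closed_form_case(self):
        assert fr.arf0_from_p(0.10, 0.65) == pytest.approx(6.62, abs=0.005)

    def test_monotone_in_p_and_rate(self):
        p = np.linspace(0, 1, 50)
        assert np.all(np.diff(fr.arf0_from_p(p, 0.65)) >= 0)
        assert fr.arf0_from_p(0.3, 1.0) > fr.arf0_from_p(0.3, 0.65)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            fr.arf0_from_p(1.2, 0.65)


class TestFallFractureProbability:
    def test_unbreakable_bone(self, fall_model):
        assert fr.fall_fracture_probability(SUBJECT, fall_model, _constant_surface(1e6), 200, seed=0) == 0.0

    def test_fragile_bone(self, fall_model):
        assert fr.fall_fracture_probability(SUBJECT, fall_model, _constant_surface(1.0), 200, seed=0) == 1.0

    def test_near_degenerate_distributions_reduce_to_indicator(self):
        # squeeze every fall parameter to a sliver: a single deterministic outcome
        eps = 1e-6
        fm = fr.FallStochasticModel(
            theta_i=TruncatedNormalSpec(15, 15 + eps),
            theta_f=TruncatedNormalSpec(90, 90 + eps),
            v_i=TruncatedNormalSpec(0.7, 0.7 + eps),
            a_i=TruncatedNormalSpec(2.55, 2.55 + eps),
            eta_P=TruncatedNormalSpec(0.65, 0.65 + eps),
            eta_I=TruncatedNormalSpec(-0.818, -0.818 + eps),
        )
        F0 = fr.attenuated_force(
            fr.peak_impact_force(SUBJECT.m, fr.impact_velocity(fr.kinetic_energy(SUBJECT.H, 15, 90, 0.7, 2.55), 0.65)),
            -0.818,
            fr.eta_st_from_bmi(SUBJECT.bmi),
        )
        for S0, expected in [(F0 - 100, 1.0), (F0 + 100, 0.0)]:
            P = fr.fall_fracture_probability(SUBJECT, fm, _constant_surface(S0), 100, seed=1)
            assert P == expected

    def test_fubini_equivalence(self, fall_model):
        # averaging over falls then orientations equals the reverse order
        rng = np.random.default_rng(6)
        grid = fr.build_orientation_grid(33)
        surface = fr.StrengthSurface("s", grid, 2800 * (1 + 0.3 * rng.random(33)))
        P = fr.fall_fracture_probability(SUBJECT, fall_model, surface, 500, seed=7)
        F = fr.fall_forces(SUBJECT, fall_model, 500, seed=7)
        w = quadrature_weights(grid)
        P_alt = np.mean([(w @ (f >= surface.values)) for f in F])
        assert abs(P - P_alt) < 1e-12

    def test_monotone_in_strength_and_mass_scaling(self, fall_model):
        rng = np.random.default_rng(8)
        grid = fr.build_orientation_grid(33)
        values = 2500 * (1 + 0.2 * rng.random(33))
        P = []
        for scale in (0.8, 1.0, 1.25):
            surf = fr.StrengthSurface("s", grid, values * scale)
            P.append(fr.fall_fracture_probability(SUBJECT, fall_model, surf, 2000, seed=9))
        assert P[0] >= P[1] >= P[2]  # stronger bone, lower risk

        surf = fr.StrengthSurface("s", grid, values)
        P_m = [
            fr.fall_fracture_probability(fr.Subject("s", m, 1.58), fall_model, surf, 2000, seed=9)
            for m in (45.0, 55.0, 65.0)
        ]
        assert P_m[0] <= P_m[1] <= P_m[2]  # heavier body, higher risk (below the soft-tissue cap)

    def test_determinism(self, fall_model):
        surf = _constant_surface(2800)
        a = fr.fall_fracture_probability(SUBJECT, fall_model, surf, 1000, seed=3)
        b = fr.fall_fracture_probability(SUBJECT, fall_model, surf, 1000, seed=3)
        assert a == b


class TestRunCohort:
    def test_single_subject_unbreakable(self, fall_model):
        res = fr.run_cohort([SUBJECT], {"s": _constant_surface(1e6)}, fall_model, N=100, seed=0)
        assert len(res) == 1 and res[0].ARF0 == 0.0

    def test_identical_runs_identical_results(self, fall_model):
        subs = [fr.Subject("a", 60, 1.6), fr.Subject("b", 70, 1.55)]
        surfs = {"a": _constant_surface(2500, sid="a"), "b": _constant_surface(3000, sid="b")}
        r1 = fr.run_cohort(subs, surfs, fall_model, N=500, seed=5)
        r2 = fr.run_cohort(subs, surfs, fall_model, N=500, seed=5)
        assert [r.ARF0 for r in r1] == [r.ARF0 for r in r2]

    def test_missing_surface_skipped_with_log(self, fall_model, caplog):
        subs = [fr.Subject("a", 60, 1.6), fr.Subject("b", 70, 1.55)]
        surfs = {"a": _constant_surface(2500, sid="a")}
        with caplog.at_level("ERROR"):
            res = fr.run_cohort(subs, surfs, fall_model, N=100, seed=1)
        assert [r.subject_id for r in res] == ["a"]
        assert "b" in caplog.text

    def test_population_model_matches_engine(self, fall_model):
        model = fr.arf0_population_model(fall_model, N_falls=512, seed=13)
        from femrisk.strength import AnisotropyShape, SurfaceGenParams

        shape = AnisotropyShape(SurfaceGenParams().shared_coeffs)
        grid = fr.build_orientation_grid(33)
        f = shape.evaluate(grid.points[:, 0], grid.points[:, 1])
        surf = fr.StrengthSurface("s", grid, 2800 * f / f.mean())
        P = fr.fall_fracture_probability(SUBJECT, fall_model, surf, 512, seed=13)
        assert model(np.array([[63.75, 1.58, 2800.0]]))[0] == pytest.approx(fr.arf0_from_p(P), abs=1e-10)
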