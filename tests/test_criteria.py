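import math

import numpy as np
import pytest

from odefit.criteria import (
    ALL_CRITERIA,
    CRITERION_COMPONENTS,
    CriterionEvaluator,
    CriterionSettings,
    CriterionSpec,
    DivisionGuardError,
    composite_simpson,
    continuous_error,
    discrete_derivative_error,
    discrete_value_error,
    evaluate_criterion,
    roughness_penalty,
)
from odefit.interpolation import fit_spline
from odefit.ode_models import SimulationFailure, TimeSeries, ValidationError


def _series(times, values, names=None):
    values = np.atleast_2d(np.asarray(values, float))
    names = names or tuple(f"c{i}" for i in range(values.shape[0]))
    return TimeSeries(np.asarray(times, float), values, names)


class TestCriterionSpec:
    def test_all_sixteen_ids(self):
        assert len(ALL_CRITERIA) == 16

    @pytest.mark.parametrize("cid,comps", list(CRITERION_COMPONENTS.items()))
    def test_table_compositions(self, cid, comps):
        spec = CriterionSpec.from_id(cid)
        assert spec.components == comps
        assert spec.weights == (1.0,) * len(comps)

    def test_cae3_components(self):
        assert CriterionSpec.from_id("CAE3").components == (10, 12, 14)

    def test_cae4_components(self):
        assert CriterionSpec.from_id("CAE4").components == (10, 12, 16)

    def test_modes_and_kinds(self):
        assert CriterionSpec.from_id("DAE2").mode == "discrete"
        assert CriterionSpec.from_id("CRE3").mode == "continuous"
        assert CriterionSpec.from_id("DRE1").error_kind == "relative"
        assert CriterionSpec.from_id("CAE1").error_kind == "absolute"

    def test_unknown_id_rejected(self):
        with pytest.raises(ValidationError):
            CriterionSpec.from_id("XAE1")

    def test_mismatched_components_rejected(self):
        with pytest.raises(ValidationError):
            CriterionSpec("DAE1", "discrete", "absolute", (2, 4), (1.0, 1.0))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValidationError):
            CriterionSpec.from_id("DAE2", weights=(1.0,))


class TestDiscreteValueError:
    def test_identity_is_zero(self):
        obs = _series([0, 1, 2], [[1.0, 2.0, 3.0]])
        assert discrete_value_error(obs, obs, "absolute") == 0.0
        assert discrete_value_error(obs, obs, "relative") == 0.0

    def test_hand_computed_absolute(self):
        obs = _series([0, 1], [[1.0, 2.0]])
        sim = _series([0, 1], [[1.5, 2.0]])
        assert discrete_value_error(sim, obs, "absolute") == pytest.approx(0.25)

    def test_hand_computed_relative(self):
        obs = _series([0, 1], [[1.0, 2.0]])
        sim = _series([0, 1], [[1.5, 2.0]])
        assert discrete_value_error(sim, obs, "relative") == pytest.approx(0.25)

    def test_grid_mismatch_rejected(self):
        obs = _series([0, 1, 2], [[1.0, 2.0, 3.0]])
        sim = _series([0, 1, 3], [[1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError):
            discrete_value_error(sim, obs)

    def test_zero_observation_guard(self):
        obs = _series([0, 1], [[0.0, 2.0]])
        sim = _series([0, 1], [[1.0, 2.0]])
        with pytest.raises(DivisionGuardError):
            discrete_value_error(sim, obs, "relative")
        # masked mode excludes the offending entry
        assert discrete_value_error(sim, obs, "relative", mask_zeros=True) == 0.0


class TestDiscreteDerivativeError:
    def test_identity_zero_all_orders_kinds(self):
        obs = _series([0, 1, 2, 3], [[0.0, 1.0, 4.0, 9.0]])
        for order in (1, 2):
            for kind in ("absolute", "relative"):
                assert discrete_derivative_error(obs, obs, order, kind, mask_zeros=True) == 0.0

    def test_lines_slope_error(self):
        t = [0, 1, 2, 3]
        obs = _series(t, [[0.0, 1.0, 2.0, 3.0]])  # y = t, spline slope == 1
        sim = _series(t, [[0.0, 2.0, 4.0, 6.0]])  # y = 2t, spline slope == 2
        assert discrete_derivative_error(sim, obs, 1, "absolute") == pytest.approx(4.0)

    def test_lines_curvature_error_zero(self):
        t = [0, 1, 2, 3]
        obs = _series(t, [[0.0, 1.0, 2.0, 3.0]])
        sim = _series(t, [[0.0, 2.0, 4.0, 6.0]])
        assert discrete_derivative_error(sim, obs, 2, "absolute") == pytest.approx(0.0, abs=1e-20)

    def test_invalid_order(self):
        obs = _series([0, 1, 2], [[0.0, 1.0, 2.0]])
        with pytest.raises(ValidationError):
            discrete_derivative_error(obs, obs, 3)


class TestRoughnessPenalty:
    def test_straight_lines_zero(self):
        t = [0, 1, 2, 3]
        sim = _series(t, [[0.0, 2.0, 4.0, 6.0]])
        obs = _series(t, [[0.0, 1.0, 2.0, 3.0]])
        assert roughness_penalty(sim, obs, "absolute", "discrete") == pytest.approx(0.0, abs=1e-20)

    def test_identity_zero(self):
        t = np.linspace(0, 3, 5)
        obs = _series(t, [np.sin(t)])
        assert roughness_penalty(obs, obs, "absolute", "discrete") == 0.0
        assert roughness_penalty(obs, obs, "absolute", "continuous") == 0.0

    def test_continuous_matches_brute_force_max(self):
        t = np.linspace(0, 3, 6)
        sim = fit_spline(_series(t, [np.sin(t)]))
        obs = fit_spline(_series(t, [np.cos(t)]))
        val = roughness_penalty(sim, obs, "absolute", "continuous", n_panels=400)
        dense = np.linspace(0, 3, 100001)
        brute = np.max((sim(dense, 2) - obs(dense, 2)) ** 2)
        assert val == pytest.approx(brute, rel=1e-3)


class TestContinuousError:
    def test_identity_zero_everywhere(self):
        t = np.linspace(0, 3, 6)
        traj = fit_spline(_series(t, [np.sin(t), np.cos(t)], ("a", "b")))
        for order in (0, 1, 2):
            for kind in ("absolute", "relative"):
                assert continuous_error(traj, traj, order, kind, mask_zeros=True) == 0.0

    def test_constant_offset_analytic(self):
        t = np.linspace(0, 2, 5)
        obs = fit_spline(_series(t, [np.ones(5)]))
        sim = fit_spline(_series(t, [np.full(5, 1.5)]))
        assert continuous_error(sim, obs, 0, "absolute") == pytest.approx(0.5, rel=1e-12)

    def test_odd_panels_rejected(self):
        t = np.linspace(0, 2, 5)
        traj = fit_spline(_series(t, [np.ones(5)]))
        with pytest.raises(ValidationError):
            continuous_error(traj, traj, 0, "absolute", n_panels=3)

    def test_span_mismatch_rejected(self):
        a = fit_spline(_series([0, 1, 2], [[0.0, 1.0, 2.0]]))
        b = fit_spline(_series([0, 1, 3], [[0.0, 1.0, 2.0]]))
        with pytest.raises(ValidationError):
            continuous_error(a, b)

    def test_simpson_panel_convergence(self, g1s_dataset):
        obs = g1s_dataset.observations
        shifted = TimeSeries(obs.times, obs.values * 1.07 + 0.1, obs.component_names)
        a, b = fit_spline(shifted), fit_spline(obs)
        v200 = continuous_error(a, b, 0, "absolute", n_panels=200)
        v400 = continuous_error(a, b, 0, "absolute", n_panels=400)
        assert abs(v200 - v400) / v400 < 1e-8


class TestCompositeSimpson:
    def test_exact_for_cubic_two_panels(self):
        grid = np.linspace(0, 1, 3)
        assert composite_simpson(grid**3, 0.5) == pytest.approx(0.25, rel=1e-15)

    def test_rejects_odd_panel_count(self):
        with pytest.raises(ValidationError):
            composite_simpson(np.ones(4), 0.1)

    def test_matches_scipy(self):
        from scipy.integrate import simpson

        x = np.linspace(0, 2, 41)
        y = np.exp(x) * np.sin(3 * x)
        assert composite_simpson(y, x[1] - x[0]) == pytest.approx(simpson(y, x=x), rel=1e-12)


class TestEvaluateCriterion:
    @pytest.mark.parametrize("cid", ALL_CRITERIA)
    def test_identity_zero_g1s(self, cid, g1s_dataset):
        obs = g1s_dataset.observations
        fv = evaluate_criterion(cid, obs, obs)
        assert fv.total == 0.0
        assert not fv.failed

    def test_dae1_identity_single_term(self, g1s_dataset):
        obs = g1s_dataset.observations
        fv = evaluate_criterion("DAE1", obs, obs)
        assert fv.per_term == {2: 0.0}

    def test_failure_maps_to_inf(self, g1s_dataset):
        obs = g1s_dataset.observations
        fv = evaluate_criterion("DAE1", SimulationFailure(np.ones(3), "boom"), obs)
        assert fv.failed and fv.total == math.inf

    def test_total_is_weighted_sum(self, g1s_dataset):
        obs = g1s_dataset.observations
        sim = TimeSeries(obs.times, obs.values * 1.1, obs.component_names)
        spec = CriterionSpec.from_id("DAE3", weights=(1.0, 2.0, 0.5))
        fv = evaluate_criterion(spec, sim, obs)
        expected = fv.per_term[2] + 2 * fv.per_term[4] + 0.5 * fv.per_term[6]
        assert fv.total == pytest.approx(expected, rel=1e-12)

    def test_relative_masks_erk_zero_observations(self, erk_dataset):
        obs = erk_dataset.observations  # four components are 0 at t=0
        fv = evaluate_criterion("DRE1", obs, obs)
        assert fv.total == 0.0 and np.isfinite(fv.total)

    @pytest.mark.parametrize("cid", ALL_CRITERIA)
    def test_nonnegative_on_perturbed_sim(self, cid, g1s_dataset, rng):
        obs = g1s_dataset.observations
        sim = TimeSeries(
            obs.times,
            obs.values * (1 + 0.2 * rng.standard_normal(obs.values.shape)),
            obs.component_names,
        )
        assert evaluate_criterion(cid, sim, obs).total >= 0.0

    @pytest.mark.parametrize("cid", ["DAE1", "DAE2", "DAE3", "DAE4", "CAE1", "CAE2", "CAE3", "CAE4"])
    def test_monotone_dominance_absolute(self, cid, g1s_dataset):
        # enlarging the pointwise gap by a factor c > 1 scales every absolute
        # criterion by c^2 (splines are linear in the data)
        obs = g1s_dataset.observations
        delta = np.sin(np.outer([1.0, 2.0], obs.times / 40.0))
        near = TimeSeries(obs.times, obs.values + delta, obs.component_names)
        far = TimeSeries(obs.times, obs.values + 2.0 * delta, obs.component_names)
        v_near = evaluate_criterion(cid, near, obs).total
        v_far = evaluate_criterion(cid, far, obs).total
        assert v_far == pytest.approx(4.0 * v_near, rel=1e-9)
        assert v_far >= v_near

    def test_discrete_continuous_consistency_under_knot_densification(self):
        # CAE1 and knot-spacing-weighted DAE1 both approximate the L2 gap
        f = lambda t: np.exp(-t) + 0.3 * np.sin(t)
        g = lambda t: np.exp(-t)
        l2_gap = 0.09 * (1.5 - np.sin(6.0) / 4)  # analytic integral of (f-g)^2
        cae_errors = []
        for n in (8, 16, 32):
            t = np.linspace(0, 3, n + 1)
            obs = _series(t, [f(t)])
            sim = _series(t, [g(t)])
            h = 3.0 / n
            dae1_weighted = h * evaluate_criterion("DAE1", sim, obs).total
            cae1 = evaluate_criterion("CAE1", sim, obs).total
            assert abs(cae1 - dae1_weighted) / cae1 < 1e-3
            cae_errors.append(abs(cae1 - l2_gap) / l2_gap)
        assert cae_errors[0] > cae_errors[1] > cae_errors[2]
        assert cae_errors[2] < 1e-5

    def test_evaluator_reuse_matches_one_shot(self, g1s_dataset):
        obs = g1s_dataset.observations
        sim = TimeSeries(obs.times, obs.values * 1.05, obs.component_names)
        spec = CriterionSpec.from_id("CAE2")
        ev = CriterionEvaluator(spec, obs, CriterionSettings())
        assert ev.evaluate(sim).total == pytest.approx(
            evaluate_criterion(spec, sim, obs).total, rel=1e-14
        )
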