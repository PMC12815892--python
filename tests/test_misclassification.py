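"""Estimation of the misclassification functions a(t), b(t) and their parameters."""

import math

import numpy as np
import pytest

from rgsurv import (MisclassModel, MisclassParams, ValidationSample,
                    a_nonparametric, a_parametric, b_nonparametric, b_parametric,
                    estimate_params, x_component, y_component, z_component)
from rgsurv.misclassification import classify_records

from conftest import make_validation


def val_from_rows(rows):
    gt, ge, ot, oe = map(np.array, zip(*rows))
    return ValidationSample(gold_time=gt, gold_event=ge, obs_time=ot, obs_event=oe)


class TestValidationSample:
    def test_shared_censoring_enforced(self):
        with pytest.raises(ValueError, match="shared censoring"):
            val_from_rows([(1.0, 0, 2.0, 0)])

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="no records"):
            ValidationSample([], [], [], [])


class TestNonparametricEstimators:
    def test_a_perfect_single_event(self):
        val = val_from_rows([(1.0, 1, 1.0, 1)])
        np.testing.assert_allclose(a_nonparametric(val, [1.0, 2.0]), [1.0, 1.0])

    def test_a_one_missed_event(self):
        # second subject's event at t=1 was missed (censored at 2 in W)
        val = val_from_rows([(1.0, 1, 1.0, 1), (1.0, 1, 2.0, 0)])
        assert a_nonparametric(val, [1.5])[0] == pytest.approx(0.5)

    def test_a_undefined_set_to_one(self):
        # no gold events before any grid point
        val = val_from_rows([(5.0, 1, 5.0, 1)])
        np.testing.assert_allclose(a_nonparametric(val, [1.0, 2.0]), [1.0, 1.0])

    def test_b_no_false_positives(self):
        val = val_from_rows([(1.0, 1, 1.0, 1), (2.0, 0, 2.0, 0)])
        np.testing.assert_allclose(b_nonparametric(val, [0.5, 1.5]), [0.0, 0.0])

    def test_b_one_early_registration(self):
        # one false positive at t=1 among two subjects still event-free at 1.5
        val = val_from_rows([(2.0, 1, 1.0, 1), (2.0, 1, 2.0, 1)])
        assert b_nonparametric(val, [1.5])[0] == pytest.approx(0.5)

    def test_b_undefined_set_to_zero(self):
        # all gold times at or before the grid point -> empty risk set
        val = val_from_rows([(1.0, 1, 1.0, 1)])
        assert b_nonparametric(val, [1.0])[0] == 0.0

    def test_unsorted_grid_rejected(self):
        val = val_from_rows([(1.0, 1, 1.0, 1)])
        with pytest.raises(ValueError, match="sorted"):
            a_nonparametric(val, [2.0, 1.0])
        with pytest.raises(ValueError, match="sorted"):
            b_nonparametric(val, [2.0, 1.0])


class TestParametricForms:
    P = MisclassParams(theta=0.7, lambda_fp=0.1, lambda_d=0.3)

    def test_b_closed_form(self):
        assert b_parametric(self.P, 2.0) == pytest.approx(1 - math.exp(-0.2))
        assert b_parametric(self.P, 0.0) == 0.0
        zero = MisclassParams(1.0, 0.0, 0.0)
        assert b_parametric(zero, 7.3) == 0.0

    def test_y_midpoint_form(self):
        assert y_component(self.P, 2.0) == pytest.approx(1 - math.exp(-0.1))
        assert y_component(self.P, 2.0) <= b_parametric(self.P, 2.0)

    def test_x_form(self):
        assert x_component(MisclassParams(0.7, 0.0, 0.0), 5.0) == pytest.approx(0.7)
        assert x_component(self.P, 2.0) == pytest.approx(0.7 * math.exp(-0.1))

    def test_z_form(self):
        no_late = MisclassParams(0.7, 0.1, 0.0)
        assert z_component(no_late, 2.0) == 0.0
        # theta=1, no false positives: x+y=1 leaves nothing to detect late
        assert z_component(MisclassParams(1.0, 0.0, 0.3), 2.0) == pytest.approx(0.0)
        only_late = MisclassParams(0.7, 0.0, 0.3)
        assert z_component(only_late, 2.0) == pytest.approx((1 - math.exp(-0.3)) * 0.3)

    def test_a_decomposition(self):
        assert a_parametric(MisclassParams(1.0, 0.0, 0.0), 3.3) == 1.0
        assert a_parametric(MisclassParams(0.7, 0.0, 0.0), 3.3) == pytest.approx(0.7)
        y = 1 - math.exp(-0.1)
        x = 0.7 * (1 - y)
        z = (1 - math.exp(-0.3)) * (1 - x - y)
        assert a_parametric(self.P, 2.0) == pytest.approx(x + y + z)

    def test_bounds_and_monotonicity(self):
        t = np.linspace(0, 10, 200)
        for params in (self.P, MisclassParams(0.2, 0.5, 1.0)):
            a = a_parametric(params, t)
            b = b_parametric(params, t)
            assert np.all((a >= 0) & (a <= 1)) and np.all((b >= 0) & (b <= 1))
            assert np.all(np.diff(b) >= 0)
            assert np.all(np.diff(y_component(params, t)) >= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            b_parametric(self.P, -1.0)


class TestEstimateParams:
    def test_perfect_measurement_identity(self, perfect_validation):
        p = estimate_params(perfect_validation)
        assert p.theta == 1.0
        assert p.lambda_fp == 0.0
        assert p.lambda_d == 0.0

    def test_registry_cohort_counts(self):
        # 33 gold deaths: 16 detected on time, 1 detected early (a false
        # positive before the true event), 16 missed entirely; no false
        # positives among the 67 nonevents.  theta conditions on no prior
        # false positive: 16 / (33 - 1) = 0.5.
        rows = []
        rows += [(1.0, 1, 1.0, 1)] * 16          # on time
        rows += [(1.5, 1, 0.5, 1)]               # detected early
        rows += [(1.0, 1, 10.0, 0)] * 16         # missed, censored at 10
        rows += [(10.0, 0, 10.0, 0)] * 67        # true nonevents
        p = estimate_params(val_from_rows(rows))
        assert p.theta == pytest.approx(16 / 32)
        assert p.theta == pytest.approx(0.48, abs=0.05)
        assert p.lambda_d == 0.0
        # person-time at risk of a false positive: 0.5 (up to the early
        # registration) + 16 + 16 (up to the true events) + 670 (nonevents)
        assert p.lambda_fp == pytest.approx(1 / 702.5, rel=1e-12)

    def test_degenerate_validation_data(self):
        # a false positive at time 0 with zero person-time everywhere
        with pytest.raises(ValueError, match="degenerate"):
            estimate_params(val_from_rows([(0.0, 0, 0.0, 1)]))

    def test_recovery_under_constant_rate_mechanism(self):
        # Under the exponential error mechanism the three person-time
        # estimators are censored-exponential MLEs and recover the
        # generating parameters (theta=0.7, lambda_fp=0.1, lambda_d=0.3).
        _, _, val = make_validation("F", m=5000, seed=77, mechanism="exponential")
        p = estimate_params(val)
        # margins: 3 binomial/Poisson SEs at the expected event counts
        assert p.theta == pytest.approx(0.7, abs=0.045)
        assert p.lambda_fp == pytest.approx(0.1, abs=0.015)
        assert p.lambda_d == pytest.approx(0.3, abs=0.11)

    def test_recovery_improves_with_m(self):
        errs = []
        for m in (200, 2500, 10000):
            draws = []
            for seed in range(4):
                _, _, val = make_validation("B", m=m, seed=100 + seed,
                                            mechanism="exponential")
                draws.append(estimate_params(val).theta)
            errs.append(abs(np.mean(draws) - 0.7))
        assert errs[-1] < errs[0]

    def test_classification_taxonomy(self):
        rows = [
            (1.0, 1, 1.0, 1),   # on time
            (1.5, 1, 0.5, 1),   # early / false positive before the event
            (1.0, 1, 1.6, 1),   # late detection
            (1.0, 1, 2.0, 0),   # missed
            (2.0, 0, 0.7, 1),   # false positive among nonevents
            (2.0, 0, 2.0, 0),   # nonevent
        ]
        cls = classify_records(val_from_rows(rows))
        assert cls["on_time"].tolist() == [1, 0, 0, 0, 0, 0]
        assert cls["false_positive"].tolist() == [0, 1, 0, 0, 1, 0]
        assert cls["late"].tolist() == [0, 0, 1, 0, 0, 0]
        assert cls["missed"].tolist() == [0, 0, 0, 1, 0, 0]
        assert cls["nonevent"].tolist() == [0, 0, 0, 0, 0, 1]


class TestNonparametricConsistency:
    """Large-m agreement between the nonparametric and parametric estimators.

    Stands in for the pointwise-consistency argument: on data generated under
    the constant-rate mechanism, the nonparametric step estimators evaluated
    at the generating parameters' parametric forms agree within Monte-Carlo
    tolerance.  (a(t) additionally involves the midpoint approximation for
    the unknown true event time, so only the no-delay scenarios admit exact
    agreement.)
    """

    GRID = np.array([0.5, 1.0, 1.5, 1.9])

    def test_b_converges_to_exponential_form(self):
        _, _, val = make_validation("D", m=5000, seed=31, mechanism="exponential")
        b_np = b_nonparametric(val, self.GRID)
        b_p = b_parametric(MisclassParams(1.0, 0.1, 0.0), self.GRID)
        np.testing.assert_allclose(b_np, b_p, atol=0.03)

    def test_a_converges_to_theta_without_false_positives(self):
        _, _, val = make_validation("B", m=5000, seed=32, mechanism="exponential")
        a_np = a_nonparametric(val, self.GRID)
        a_p = a_parametric(MisclassParams(0.7, 0.0, 0.0), self.GRID)
        np.testing.assert_allclose(a_np, a_p, atol=0.045)

    def test_a_close_to_midpoint_form_with_delays(self):
        # the t/2 stand-in for the unknown T makes the parametric a(t) an
        # approximation; agreement is asserted at a coarser tolerance
        _, _, val = make_validation("F", m=5000, seed=33, mechanism="exponential")
        a_np = a_nonparametric(val, self.GRID)
        a_p = a_parametric(MisclassParams(0.7, 0.1, 0.3), self.GRID)
        np.testing.assert_allclose(a_np, a_p, atol=0.06)


class TestMisclassModel:
    def test_identity_model(self):
        model = MisclassModel.identity()
        t = np.array([0.0, 1.0, 5.0])
        np.testing.assert_array_equal(model.a(t), 1.0)
        np.testing.assert_array_equal(model.b(t), 0.0)

    def test_nonparametric_step_lookup(self):
        val = val_from_rows([(1.0, 1, 1.0, 1), (1.0, 1, 2.0, 0)])
        model = MisclassModel.nonparametric(val, np.array([1.5]))
        # left of the grid: denominator-zero conventions
        assert model.a(np.array([0.5]))[0] == 1.0
        assert model.b(np.array([0.5]))[0] == 0.0
        assert model.a(np.array([1.7]))[0] == pytest.approx(0.5)

    def test_fixed_bounds_checked(self):
        with pytest.raises(ValueError):
            MisclassModel.fixed(1.2, 0.0)
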