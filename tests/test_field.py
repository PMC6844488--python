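"""Underlying-field decomposition: bump evaluation, epsilon, relaxation fit."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment, minimize

from stemfate import (
    FactorModel,
    FactorSet,
    FieldFactor,
    RelaxationConfig,
    epsilon_deviation,
    factor_value,
    fit_factors,
    make_probability_curves_from_factors,
    predict_probabilities,
    select_factor_count,
)
from stemfate.errors import ParameterError

from conftest import random_factor_set

TIMES = np.linspace(0.0, 10.0, 101)


def _match(fitted, truth):
    """Assign fitted factors to true ones by center distance (Hungarian)."""
    cost = np.abs(np.subtract.outer([f.c for f in fitted], [t.c for t in truth]))
    ri, ci = linear_sum_assignment(cost)
    return [(fitted[i], truth[j]) for i, j in zip(ri, ci)]


class TestFactorValue:
    def test_peak_and_width(self):
        f = FieldFactor(a=2.0, c=4.0, m=6, b_weights=np.full(6, 0.7))
        assert factor_value(f, 4.0) == pytest.approx(0.7)
        half_width = 2.0 ** (-1.0 / 6.0)
        assert factor_value(f, 4.0 + half_width) == pytest.approx(0.7 / np.e)

    def test_direct_exponentiation(self):
        f = FieldFactor(a=1.0, c=5.0, m=6, b_weights=np.zeros(6))
        assert factor_value(f, 6.0, b=2.0) == pytest.approx(2.0 * np.exp(-1.0))

    @pytest.mark.parametrize("kw", [dict(a=-1.0), dict(a=0.0), dict(m=5), dict(m=0)])
    def test_invalid_factor(self, kw):
        with pytest.raises(ParameterError):
            FieldFactor(**{"a": 1.0, "c": 0.0, **kw})


class TestPredict:
    def test_zero_amplitudes(self):
        fset = FactorSet(factors=[FieldFactor(a=1.0, c=5.0, m=6)])
        assert np.all(predict_probabilities(fset, TIMES) == 0.0)

    def test_underflow_far_from_center(self):
        f = FieldFactor(a=1.0, c=0.0, m=6, b_weights=np.full(6, 0.5))
        val = predict_probabilities(FactorSet(factors=[f]), np.array([50.0]))
        assert np.all(val == 0.0)
        assert np.all(np.isfinite(val))

    def test_matches_fixture_generator(self):
        fset = random_factor_set(seed=5, K=2)
        a = predict_probabilities(fset, TIMES)
        b, _ = make_probability_curves_from_factors(fset, TIMES)
        assert np.array_equal(a, b)


class TestEpsilon:
    def test_perfect_fit(self):
        Y = np.random.default_rng(0).uniform(0, 1, (6, 20))
        assert epsilon_deviation(Y, Y) == 0.0

    def test_uniform_offset(self):
        Y = np.zeros((6, 50))
        assert epsilon_deviation(Y + 0.01, Y) == pytest.approx(1.0)

    def test_single_channel_offset(self):
        Y = np.zeros((6, 50))
        P = Y.copy()
        P[2] += 0.01
        assert epsilon_deviation(P, Y) == pytest.approx(1.0 / 6.0)

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            epsilon_deviation(np.zeros((6, 5)), np.zeros((6, 6)))


class TestFitFactors:
    def test_single_factor_recovery(self):
        truth = FieldFactor(a=1.0, c=5.0, m=6,
                            b_weights=np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.35]))
        Y, _ = make_probability_curves_from_factors(FactorSet(factors=[truth]), TIMES)
        fit = fit_factors(Y, TIMES, K=1)
        f = fit.factors[0]
        assert abs(f.a - truth.a) / truth.a < 0.02
        assert abs(f.c - truth.c) / truth.c < 0.02
        assert np.max(np.abs(f.b_weights - truth.b_weights)) < 0.02 * 0.5
        assert fit.epsilon < 0.1

    def test_zero_target(self):
        fit = fit_factors(np.zeros((6, TIMES.size)), TIMES, K=1)
        assert np.max(np.abs(fit.factors[0].b_weights)) < 1e-10
        assert fit.epsilon < 1e-8

    def test_three_factor_recovery_with_matching(self):
        truth = random_factor_set(seed=1, K=3)
        Y, valid = make_probability_curves_from_factors(truth, TIMES)
        assert valid
        fit = fit_factors(Y, TIMES, K=3)
        assert fit.epsilon < 1.0
        for fitted, true in _match(fit.factors, truth.factors):
            assert abs(fitted.c - true.c) < 0.2

    def test_objective_never_above_warm_start(self):
        truth = random_factor_set(seed=2, K=2)
        Y, _ = make_probability_curves_from_factors(truth, TIMES)
        # perturbed warm start
        warm = FactorSet(factors=[
            FieldFactor(a=f.a * 1.5, c=f.c + 0.5, m=6, b_weights=f.b_weights * 0.7)
            for f in truth.factors
        ])
        init_obj = float(np.sum((predict_probabilities(warm, TIMES) - Y) ** 2))
        fit = fit_factors(Y, TIMES, K=2, init=warm)
        assert fit.objective <= init_obj + 1e-12

    def test_objective_epsilon_consistency(self):
        truth = random_factor_set(seed=3, K=1)
        Y, _ = make_probability_curves_from_factors(truth, TIMES)
        fit = fit_factors(Y, TIMES, K=1)
        assert (fit.objective < 1e-12) == (fit.epsilon < 1e-4)

    def test_bitwise_reproducibility(self):
        truth = random_factor_set(seed=4, K=2)
        Y, _ = make_probability_curves_from_factors(truth, TIMES)
        cfg = RelaxationConfig(max_iters=300, seed=9, n_restarts=2)
        f1 = fit_factors(Y, TIMES, K=2, config=cfg)
        f2 = fit_factors(Y, TIMES, K=2, config=cfg)
        for a, b in zip(f1.factors, f2.factors):
            assert a.a == b.a and a.c == b.c
            assert np.array_equal(a.b_weights, b.b_weights)

    def test_not_worse_than_scipy_cross_check(self):
        """Dual route: our relaxation vs an off-the-shelf optimizer from
        the same start, on data one bump cannot represent exactly."""
        truth = random_factor_set(seed=6, K=2)
        Y, _ = make_probability_curves_from_factors(truth, TIMES)
        fit = fit_factors(Y, TIMES, K=1)

        def objective(theta):
            a, c = np.exp(theta[0]), theta[1]
            b = theta[2:].reshape(6, 1)
            E = np.exp(np.maximum(-a * (TIMES[:, None] - c) ** 6, -745.0))
            return float(np.sum((b @ E.T - Y) ** 2))

        x0 = np.concatenate([[np.log(5.0 ** -6)], [5.0], np.zeros(6)])
        ref = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "fatol": 1e-12})
        assert fit.objective <= ref.fun * 1.05 + 1e-9


class TestSelectFactorCount:
    def test_one_factor_accepted_immediately(self):
        truth = random_factor_set(seed=7, K=1)
        Y, _ = make_probability_curves_from_factors(truth, TIMES)
        sel = select_factor_count(Y, TIMES, epsilon_p=1.0, K_start=1)
        assert sel.K == 1 and sel.epsilon < 1.0

    def test_oversized_start_prunes_to_essential(self):
        truth = random_factor_set(seed=8, K=3)
        Y, _ = make_probability_curves_from_factors(truth, TIMES)
        sel = select_factor_count(Y, TIMES, epsilon_p=1.0, K_start=4)
        assert sel.K == 3
        assert sel.epsilon < 1.0

    def test_escalates_to_five(self):
        truth = random_factor_set(seed=9, K=5)
        Y, valid = make_probability_curves_from_factors(truth, TIMES)
        assert valid
        sel = select_factor_count(Y, TIMES, epsilon_p=1.0, K_start=4)
        assert sel.K == 5
        assert sel.epsilon < 1.0


class TestModelWrapper:
    def test_fit_and_summary(self):
        truth = random_factor_set(seed=10, K=2)
        Y, _ = make_probability_curves_from_factors(truth, TIMES)
        fm = FactorModel(Y, TIMES)
        fr = fm.fit_select(epsilon_p=1.0, K_start=2)
        assert fr.K == 2
        assert fr.predict().shape == (6, TIMES.size)
        assert fr.factor_curves().shape == (2, TIMES.size)
        assert "epsilon" in fr.summary()
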