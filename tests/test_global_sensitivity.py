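"""Sampling, eFAST spectral indices, RS-HDMR indices and the trend fit."""

import numpy as np
import pytest
from scipy import stats

from thermosens import (
    EfastConfig,
    HdmrConfig,
    efast_curve,
    efast_indices,
    frequency_sensitivity_trend,
    global_local,
    hdmr_expansion,
    sample_uniform,
)
from thermosens.global_sensitivity import SensitivityResult, efast_frequencies
from thermosens.parameter_space import Parameter, ParameterSpace

UNIT2 = ParameterSpace([Parameter("x1", 0, 1), Parameter("x2", 0, 1)])
UNIT4 = ParameterSpace([Parameter(f"x{i}", 0, 1) for i in range(1, 5)])


def linear(c):
    c = np.asarray(c, dtype=float)
    return lambda x: float(c @ x)


def product2(x):
    return float((x[0] - 0.5) * (x[1] - 0.5))


class TestSampleUniform:
    def test_same_seed_identical(self):
        a = sample_uniform(UNIT4, 50, seed=9)
        b = sample_uniform(UNIT4, 50, seed=9)
        assert np.array_equal(a, b)

    def test_mean_near_midpoint(self):
        space = ParameterSpace([Parameter("a", 2.0, 6.0)])
        x = sample_uniform(space, 10_000, seed=1)
        se = (6 - 2) / np.sqrt(12) / np.sqrt(10_000)
        assert abs(x.mean() - 4.0) < 3 * se

    def test_log_scale_uniform_in_log(self):
        space = ParameterSpace([Parameter("k", 1e8, 1e10, "log10")])
        x = sample_uniform(space, 5_000, seed=2)
        logs = np.log10(x[:, 0])
        assert stats.kstest((logs - 8) / 2, "uniform").pvalue > 0.01

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_uniform(UNIT2, 0)


class TestEfastCurve:
    def test_samples_stay_in_range(self):
        space = ParameterSpace([Parameter("a", -3, -1), Parameter("b", 10, 20)])
        s = np.linspace(-np.pi, np.pi, 501)
        X = efast_curve(space, 0, np.array([16, 3]), np.zeros(2), s)
        assert X[:, 0].min() >= -3 and X[:, 0].max() <= -1
        assert X[:, 1].min() >= 10 and X[:, 1].max() <= 20

    def test_zero_phase_midpoint_at_origin(self):
        space = ParameterSpace([Parameter("a", 2, 8)])
        X = efast_curve(space, 0, np.array([1]), np.zeros(1), np.array([0.0]))
        assert X[0, 0] == pytest.approx(5.0)

    def test_near_uniform_marginal(self):
        s = np.pi * (2 * np.arange(10_001) + 1 - 10_001) / 10_001
        X = efast_curve(UNIT2, 0, np.array([11, 1]), np.array([0.37, 1.2]), s)
        assert stats.kstest(X[:, 0], "uniform").pvalue > 0.01

    def test_focus_must_carry_max_frequency(self):
        with pytest.raises(ValueError, match="maximum frequency"):
            efast_curve(UNIT2, 1, np.array([8, 2]), np.zeros(2), np.zeros(3))

    def test_aliasing_budget_rejected(self):
        cfg = EfastConfig(Ns=101)  # far below 2*M*omega_max+1 for k=2
        with pytest.raises(ValueError, match="alias"):
            cfg.ns(2)


class TestEfastIndices:
    def test_single_factor_function(self):
        res = efast_indices(linear([1, 0, 0, 0]), UNIT4, EfastConfig(seed=3))
        assert res.first_order[0] == pytest.approx(1.0, abs=0.02)
        assert np.all(res.first_order[1:] < 0.02)

    def test_linear_variance_shares(self):
        c = np.array([1.0, 2.0, 0.5, 1.5])
        res = efast_indices(linear(c), UNIT4, EfastConfig(seed=4))
        expected = c ** 2 / (c ** 2).sum()
        assert np.allclose(res.first_order, expected, atol=0.03)
        assert np.all(res.first_order <= res.total_order + 0.02)
        assert res.first_order.sum() <= 1.0 + 0.05

    def test_pure_interaction_function(self):
        res = efast_indices(product2, UNIT2, EfastConfig(seed=5))
        assert np.all(res.first_order < 0.05)
        assert np.all(res.total_order > 0.95)

    def test_seed_stability(self):
        c = np.array([1.0, 2.0, 0.5, 1.5])
        r1 = efast_indices(linear(c), UNIT4, EfastConfig(seed=11))
        r2 = efast_indices(linear(c), UNIT4, EfastConfig(seed=12))
        assert np.allclose(r1.first_order, r2.first_order, atol=0.02)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="variance"):
            res = efast_indices(lambda x: 1.0, UNIT2, EfastConfig(seed=6))
        assert np.all(res.first_order == 0)

    def test_frequency_assignment_rule(self):
        cfg = EfastConfig()
        freqs = efast_frequencies(9, 4, cfg)
        assert freqs[4] == cfg.omega_max(9)
        comp = np.delete(freqs, 4)
        assert len(set(comp)) == 8
        assert comp.max() <= cfg.omega_max(9) // (2 * cfg.M)


class TestHdmr:
    def test_single_factor(self):
        res = hdmr_expansion(linear([1, 0, 0, 0]), UNIT4, HdmrConfig(N=5000, seed=7))
        assert res.first_order[0] == pytest.approx(1.0, abs=0.02)
        assert np.triu(res.second_order, 1).max() < 0.02

    def test_symmetric_sum(self):
        res = hdmr_expansion(linear([1, 1, 0, 0]), UNIT4, HdmrConfig(N=5000, seed=8))
        assert res.first_order[0] == pytest.approx(0.5, abs=0.03)
        assert res.first_order[1] == pytest.approx(0.5, abs=0.03)

    def test_pure_interaction(self):
        res = hdmr_expansion(product2, UNIT2, HdmrConfig(N=5000, seed=9))
        assert res.s2("x1", "x2") == pytest.approx(1.0, abs=0.05)
        assert np.all(res.first_order < 0.02)

    def test_additive_first_order_sums_to_one(self):
        c = np.array([1.0, 0.7, 0.2, 1.3])
        res = hdmr_expansion(linear(c), UNIT4, HdmrConfig(N=10_000, seed=10))
        assert res.first_order.sum() == pytest.approx(1.0, abs=0.03)
        assert np.triu(res.second_order, 1).sum() < 0.03

    def test_sample_budget_invariant(self):
        with pytest.raises(ValueError, match="N="):
            hdmr_expansion(product2, UNIT2, HdmrConfig(N=100, seed=1))

    def test_f0_and_variance_reported(self):
        res = hdmr_expansion(linear([2, 0, 0, 0]), UNIT4, HdmrConfig(N=5000, seed=2))
        assert res.f0 == pytest.approx(1.0, abs=0.02)
        assert res.variance == pytest.approx(4 / 12, rel=0.1)


class TestGlobalLocal:
    def test_inactive_parameter_scores_zero(self):
        f = lambda x: float(x[0] ** 2 + 1.0)
        res = global_local(f, UNIT2, n=300, seed=1)
        assert res.first_order[1] == pytest.approx(0.0, abs=1e-9)
        assert res.first_order[0] == 1.0

    def test_symmetric_additive_equal_averages(self):
        f = lambda x: float(x.sum() + 1.0)
        res = global_local(f, UNIT2, n=500, seed=2)
        assert res.first_order[0] == pytest.approx(res.first_order[1], abs=0.05)

    def test_degenerate_objective_aborts(self):
        with pytest.raises(RuntimeError, match="undefined"):
            global_local(lambda x: 0.0, UNIT2, n=50, seed=3)

    def test_unknown_weighting(self):
        with pytest.raises(ValueError):
            global_local(lambda x: 1.0, UNIT2, n=10, weighting="softmax")


class TestFrequencyTrend:
    def _result(self, values):
        names = tuple(values)
        v = np.array(list(values.values()), dtype=float)
        return SensitivityResult(method="test", names=names, first_order=v, first_order_raw=v)

    def test_flat_sensitivities_zero_slope(self):
        res = self._result({"Q1": 0.2, "Q2": 0.2, "Q3": 0.2})
        tr = frequency_sensitivity_trend(res, {"Q1": 5, "Q2": 3, "Q3": 2})
        assert tr.slope_first == pytest.approx(0.0, abs=1e-12)

    def test_proportional_sensitivities_recover_constant(self):
        counts = {"Q1": 5, "Q2": 3, "Q3": 2, "Q4": 4}
        res = self._result({k: 0.07 * v for k, v in counts.items()})
        tr = frequency_sensitivity_trend(res, counts)
        assert tr.slope_first == pytest.approx(0.07)
        assert tr.intercept_first == pytest.approx(0.0, abs=1e-12)
        assert set(tr.table["parameter"]) == set(counts)

    def test_refuses_fewer_than_three(self):
        res = self._result({"Q1": 0.1, "Q2": 0.3})
        with pytest.raises(ValueError, match="3"):
            frequency_sensitivity_trend(res, {"Q1": 5, "Q2": 2})
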