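"""Life-history primitives: curves, fitness, elasticity, projection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sexalloc import (
    AllocationCurve,
    DomainError,
    LifeHistoryModel,
    OffspringSurvivalCurve,
    ValidationError,
    allocation_at,
    female_output,
    fitness,
    point_elasticity,
    project_population,
    survival_at,
    validate_model,
)
from .conftest import power_model


class TestAllocationCurve:
    @pytest.mark.parametrize(
        "family, x, expected_E, expected_dE",
        [
            ("exponential", 0.0, 0.8, -0.4),
            ("rational", 0.0, 0.8, -0.4),
            ("linear_clamped", 0.0, 0.8, -0.4),
            ("exponential", 1.0, 0.8 * math.exp(-0.5), -0.4 * math.exp(-0.5)),
            ("rational", 1.0, 0.8 / 1.5, -0.4 / 1.5**2),
        ],
    )
    def test_value_and_analytic_derivative(self, family, x, expected_E, expected_dE):
        E, dE = allocation_at(AllocationCurve(family=family, E0=0.8, k=0.5), x)
        assert E == pytest.approx(expected_E, rel=1e-14)
        assert dE == pytest.approx(expected_dE, rel=1e-14)

    def test_decays_to_zero_at_large_pressure(self):
        curve = AllocationCurve(family="exponential", E0=0.8, k=0.5)
        assert curve.value(80.0) < 1e-15
        assert curve.value(80.0) > 0.0

    def test_domain_errors(self):
        curve = AllocationCurve(family="linear_clamped", E0=0.8, k=0.5)
        with pytest.raises(DomainError):
            curve.value(-0.1)
        with pytest.raises(DomainError):
            curve.value(2.0)  # domain is [0, 1/k) = [0, 2)
        with pytest.raises(DomainError):
            AllocationCurve(E0=0.0)
        with pytest.raises(DomainError):
            AllocationCurve(k=-1.0)

    @given(
        family=st.sampled_from(["exponential", "rational", "linear_clamped"]),
        E0=st.floats(0.01, 1.0),
        k=st.floats(0.05, 5.0),
        frac=st.floats(0.0, 0.99),
    )
    def test_derivative_negative_everywhere(self, family, E0, k, frac):
        curve = AllocationCurve(family=family, E0=E0, k=k)
        x = frac * min(curve.domain_end, 10.0)
        E, dE = allocation_at(curve, x)
        assert E > 0
        assert dE < 0


class TestSurvivalCurve:
    @pytest.mark.parametrize(
        "curve, E, expected_C, expected_dC",
        [
            (OffspringSurvivalCurve(family="power", c0=0.5, delta=1.0), 0.8, 0.4, 0.5),
            (OffspringSurvivalCurve(family="constant", c0=0.6), 0.8, 0.6, 0.0),
            (
                OffspringSurvivalCurve(family="saturating", a=2.0),
                0.5,
                1.0 - math.exp(-1.0),
                2.0 * math.exp(-1.0),
            ),
        ],
    )
    def test_value_and_derivative(self, curve, E, expected_C, expected_dC):
        C, dC = survival_at(curve, E)
        assert C == pytest.approx(expected_C, rel=1e-14)
        assert dC == pytest.approx(expected_dC, rel=1e-14)

    def test_errors(self):
        curve = OffspringSurvivalCurve(family="power", c0=0.5, delta=1.0)
        with pytest.raises(DomainError):
            survival_at(curve, 0.0)
        with pytest.raises(ValidationError):
            # C = 2 * 1 = 2 > 1
            survival_at(OffspringSurvivalCurve(family="power", c0=2.0, delta=1.0), 1.0)
        with pytest.raises(DomainError):
            OffspringSurvivalCurve(family="power", c0=0.5, delta=None)
        with pytest.raises(DomainError):
            OffspringSurvivalCurve(family="saturating", a=-2.0)

    @pytest.mark.parametrize(
        "curve, E, expected",
        [
            (OffspringSurvivalCurve(family="power", c0=0.5, delta=-2.0), 0.3, -2.0),
            (OffspringSurvivalCurve(family="constant", c0=0.6), 0.3, 0.0),
            (
                OffspringSurvivalCurve(family="saturating", a=2.0),
                0.5,
                math.exp(-1.0) / (1.0 - math.exp(-1.0)),  # aE e^-aE / (1-e^-aE) at aE=1
            ),
        ],
    )
    def test_point_elasticity_analytic(self, curve, E, expected):
        assert point_elasticity(curve, E) == pytest.approx(expected, abs=1e-12)

    @given(
        delta=st.floats(-3.0, 3.0),
        c0=st.floats(0.01, 2.0),
        E=st.floats(0.01, 1.0),
    )
    def test_power_elasticity_identity_both_paths(self, delta, c0, E):
        curve = OffspringSurvivalCurve(family="power", c0=c0, delta=delta)
        assert abs(point_elasticity(curve, E) - delta) <= 1e-8
        fd = point_elasticity(curve, E, method="finite-difference")
        assert abs(fd - delta) <= 1e-6

    def test_saturating_elasticity_in_unit_interval(self):
        curve = OffspringSurvivalCurve(family="saturating", a=3.0)
        for E in np.geomspace(1e-3, 1.0, 25):
            assert 0.0 < point_elasticity(curve, E) < 1.0


class TestFitness:
    def test_female_output_examples(self, default_model):
        assert female_output(default_model, 0.0, 0.5) == pytest.approx(4.0)
        assert female_output(default_model, 0.0, 1.0) == 0.0
        assert female_output(default_model, 0.0, 0.0) == pytest.approx(8.0)
        with pytest.raises(DomainError):
            female_output(default_model, 0.0, 1.5)

    def test_fitness_examples(self, default_model):
        # lambda = P + M (1-mu) E C = 0.5 + 10*0.5*0.8*0.4 = 2.1
        assert fitness(default_model, 0.0, 0.5) == pytest.approx(2.1, rel=1e-14)
        assert fitness(default_model, 0.0, 1.0) == pytest.approx(default_model.P)
        const_model = LifeHistoryModel(
            P=0.5, M=10.0,
            survival=OffspringSurvivalCurve(family="constant", c0=0.5),
        )
        assert fitness(const_model, 0.0, 0.5) == pytest.approx(2.5, rel=1e-14)

    @given(
        mu1=st.floats(0.0, 1.0),
        mu2=st.floats(0.0, 1.0),
        x=st.floats(0.0, 2.0),
    )
    def test_fitness_strictly_decreasing_in_mu(self, mu1, mu2, x):
        model = power_model(delta=1.0)
        lo, hi = sorted((mu1, mu2))
        if hi - lo > 1e-12:
            assert fitness(model, x, hi) < fitness(model, x, lo)


class TestProjection:
    def test_geometric_growth(self, default_model):
        states = project_population(default_model, 0.0, 0.5, N0=100.0, T=2)
        assert [s.T for s in states] == [0, 1, 2]
        assert states[-1].N == pytest.approx(441.0, rel=1e-12)  # 100 * 2.1**2

    def test_stationary_when_lambda_is_one(self):
        # P + M*mu_f*E*c0 = 0.5 + 10*0.5*0.8*0.125 = 1
        model = LifeHistoryModel(
            P=0.5, M=10.0,
            survival=OffspringSurvivalCurve(family="constant", c0=0.125),
        )
        states = project_population(model, 0.0, 0.5, N0=50.0, T=5)
        assert all(s.N == pytest.approx(50.0, rel=1e-14) for s in states)

    def test_zero_steps_and_errors(self, default_model):
        assert [s.N for s in project_population(default_model, 0, 0.5, 7.0, 0)] == [7.0]
        with pytest.raises(DomainError):
            project_population(default_model, 0, 0.5, -1.0, 3)
        with pytest.raises(DomainError):
            project_population(default_model, 0, 0.5, 1.0, -3)

    def test_stepwise_ratio_is_exactly_lambda(self, default_model):
        lam = fitness(default_model, 0.3, 0.4)
        states = project_population(default_model, 0.3, 0.4, N0=12.5, T=20)
        for a, b in zip(states, states[1:]):
            assert b.N == a.N * lam  # bitwise: projection is iterated multiply


class TestValidation:
    def test_negative_delta_scale_flagged(self):
        # C = 0.5 E^-3 > 1 once E < 0.794, reached on a wide pressure domain
        model = power_model(delta=-3.0, c0=0.5)
        report = validate_model(model, x_domain=(0.0, 3.0))
        assert not report.ok
        assert any("C(E(x))" in v for v in report.violations)

    def test_constant_family_valid(self):
        model = LifeHistoryModel(
            survival=OffspringSurvivalCurve(family="constant", c0=0.6)
        )
        assert validate_model(model, (0.0, 3.0)).ok

    def test_adult_survival_bound_flagged(self):
        model = LifeHistoryModel(
            P=1.2, survival=OffspringSurvivalCurve(family="constant", c0=0.6)
        )
        report = validate_model(model, (0.0, 3.0))
        assert any("adult survival" in v for v in report.violations)
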