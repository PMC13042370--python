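"""Core curve: evaluation, tipping points, regimes, branches, forces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ecohyst import (
    DomainError,
    E,
    ModelParams,
    ParameterError,
    RangeError,
    RegimeError,
    classify_regime,
    critical_constant,
    evaluate_driver,
    force_decomposition,
    invert_branch,
    tipping_points,
)

from conftest import grid_scan_extrema


def refined_extrema(params: ModelParams) -> list[float]:
    """Grid-scan extrema refined by bracketed root finding on f'."""

    def fprime(y):
        f = (y - params.c0) / (params.c1 - y) * math.exp(params.k / y)
        g1h = (params.c1 - params.c0) / (params.c1 - y) ** 2 * math.exp(params.k / y)
        return g1h - params.k / y**2 * f

    out = []
    for y in grid_scan_extrema(params, n=100_000):
        out.append(brentq(fprime, y - 1e-4, y + 1e-4))
    return out


@st.composite
def model_params(draw, k_factor=st.floats(0.3, 3.0)):
    """Random valid parameter triples, K scaled off the critical constant.

    The factor avoids the window (0.97, 1.03) around K*, where a finite
    grid scan cannot resolve the vanishing extrema and the oracle itself
    becomes unreliable.
    """
    c0 = draw(st.floats(0.2, 5.0))
    c1 = c0 * draw(st.floats(1.2, 4.0))
    factor = draw(k_factor)
    if 0.97 < factor < 1.03:
        factor = 1.05
    return ModelParams(c0, c1, factor * critical_constant(c0, c1))


class TestEvaluateDriver:
    @pytest.mark.parametrize(
        "y, params, expected",
        [
            (1.0, ModelParams(1, E, 9), 0.0),
            (2.0, ModelParams(1, E, 9), math.exp(4.5) / (E - 2.0)),
            (1.5, ModelParams(1, E, 0), 0.5 / (E - 1.5)),
        ],
    )
    def test_values(self, y, params, expected):
        assert evaluate_driver(y, params) == pytest.approx(expected, rel=1e-12)

    def test_zero_only_at_lower_state(self):
        p = ModelParams(1, E, 9)
        assert evaluate_driver(1.0, p) == 0.0
        assert evaluate_driver(1.0 + 1e-9, p) > 0.0

    @pytest.mark.parametrize("y", [0.5, 0.999, E, 3.0])
    def test_domain_errors(self, y):
        with pytest.raises(DomainError):
            evaluate_driver(y, ModelParams(1, E, 9))

    def test_vectorized(self):
        p = ModelParams(1, E, 9)
        ys = np.array([1.0, 1.5, 2.0])
        out = evaluate_driver(ys, p)
        assert out.shape == (3,)
        assert out[0] == 0.0


class TestCriticalConstant:
    def test_standardized_value_rounds_to_printed_constant(self):
        assert round(critical_constant(1.0, E), 2) == 6.33

    @pytest.mark.parametrize(
        "c0, c1, expected", [(1, 2, 8.0), (2, 4, 16.0)]
    )
    def test_closed_form(self, c0, c1, expected):
        assert critical_constant(c0, c1) == pytest.approx(expected)

    @pytest.mark.parametrize("c0, c1", [(2, 1), (0, 1), (-1, 1), (1, 1)])
    def test_parameter_errors(self, c0, c1):
        with pytest.raises(ParameterError):
            critical_constant(c0, c1)


class TestRegime:
    def test_hysteretic(self):
        assert classify_regime(ModelParams(1, E, 9)).label == "hysteretic"

    def test_critical_equality(self):
        k_star = 4 * E / (E - 1)
        assert classify_regime(ModelParams(1, E, k_star)).label == "critical"

    def test_continuous_confirmed_by_scan(self):
        p = ModelParams(1, E, 3)
        assert classify_regime(p).label == "continuous"
        assert len(grid_scan_extrema(p)) == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(params=model_params())
    def test_classification_matches_monotonicity_oracle(self, params):
        """K > K* if and only if a dense scan of f finds interior extrema."""
        hysteretic = classify_regime(params).label == "hysteretic"
        assert hysteretic == (len(grid_scan_extrema(params)) > 0)


class TestTippingPoints:
    def test_matches_grid_scan_oracle(self):
        p = ModelParams(1, E, 9)
        tp = tipping_points(p)
        lo, hi = refined_extrema(p)
        assert tp.forward.state == pytest.approx(lo, abs=1e-6)
        assert tp.backward.state == pytest.approx(hi, abs=1e-6)
        assert tp.forward.driver == pytest.approx(240.62781767064945, rel=1e-9)
        assert tp.backward.driver == pytest.approx(124.91875372366256, rel=1e-9)

    def test_none_below_critical(self):
        assert tipping_points(ModelParams(1, E, 5)) is None

    def test_degenerate_at_critical(self):
        k_star = 4 * E / (E - 1)
        tp = tipping_points(ModelParams(1, E, k_star))
        assert tp.degenerate
        assert tp.forward.state == pytest.approx(1.4621171572600096, rel=1e-9)
        assert tp.forward.state == tp.backward.state

    def test_ordering_invariants(self):
        p = ModelParams(1, E, 9)
        tp = tipping_points(p)
        assert p.c0 < tp.forward.state < tp.backward.state < p.c1
        assert tp.forward.driver > tp.backward.driver

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(params=model_params(k_factor=st.floats(1.05, 3.0)))
    def test_vieta_identities(self, params):
        """Root sum and product obey the tipping quadratic's coefficients."""
        tp = tipping_points(params)
        c0, c1, k = params.c0, params.c1, params.k
        denom = c1 - c0 + k
        s = tp.forward.state + tp.backward.state
        prod = tp.forward.state * tp.backward.state
        assert s == pytest.approx(k * (c0 + c1) / denom, rel=1e-10)
        assert prod == pytest.approx(k * c0 * c1 / denom, rel=1e-10)

    def test_derivative_vanishes_at_tipping_states(self):
        p = ModelParams(1, E, 9)
        tp = tipping_points(p)
        for y in (tp.forward.state, tp.backward.state):
            forces = force_decomposition(y, p)
            assert abs(forces.total) <= 1e-8 * forces.inertial


class TestBranches:
    def test_monotone_on_each_branch(self, norm9):
        tp = tipping_points(norm9)
        lower = np.linspace(1.0, tp.forward.state, 500)
        upper = np.linspace(tp.backward.state, E - 1e-6, 500)
        assert np.all(np.diff(evaluate_driver(lower, norm9)) > 0)
        assert np.all(np.diff(evaluate_driver(upper, norm9)) > 0)

    def test_monotone_everywhere_below_critical(self):
        p = ModelParams(1, E, 3)
        ys = np.linspace(1.0, E - 1e-6, 2000)
        assert np.all(np.diff(evaluate_driver(ys, p)) > 0)

    def test_invert_round_trip(self, norm9):
        x = math.exp(4.5) / (E - 2.0)
        y = invert_branch(x, norm9, "upper")
        assert y == pytest.approx(2.0, rel=1e-9)
        assert evaluate_driver(y, norm9) == pytest.approx(x, rel=1e-8)

    def test_invert_zero_is_lower_state(self, norm9):
        assert invert_branch(0.0, norm9, "lower") == norm9.c0

    def test_invert_hits_branch_endpoint(self, norm9):
        tp = tipping_points(norm9)
        y = invert_branch(tp.forward.driver, norm9, "lower")
        assert y == pytest.approx(tp.forward.state, rel=1e-9)

    def test_out_of_range_error_names_interval(self, norm9):
        tp = tipping_points(norm9)
        with pytest.raises(RangeError, match="range"):
            invert_branch(tp.forward.driver * 2, norm9, "lower")

    def test_no_upper_branch_when_continuous(self):
        with pytest.raises(RegimeError):
            invert_branch(1.0, ModelParams(1, E, 3), "upper")


class TestForces:
    def test_example_values(self, norm9):
        forces = force_decomposition(2.0, norm9)
        assert forces.inertial == pytest.approx(299.79874244732605, rel=1e-9)
        assert forces.conservative == pytest.approx(-281.9764295870982, rel=1e-9)
        assert forces.total == pytest.approx(17.82231286022784, rel=1e-9)

    def test_sum_identity_exact(self, norm9):
        ys = np.linspace(1.001, E - 0.001, 50)
        inertial, conservative, total = force_decomposition(ys, norm9)
        assert np.array_equal(inertial + conservative, total)

    def test_matches_finite_difference(self, norm9):
        ys = np.linspace(1.01, E - 0.01, 200)
        _, _, total = force_decomposition(ys, norm9)
        h = 1e-6
        fd = (evaluate_driver(ys + h, norm9) - evaluate_driver(ys - h, norm9)) / (2 * h)
        assert np.allclose(total, fd, rtol=1e-4)

    def test_zero_k_has_no_conservative_force(self):
        forces = force_decomposition(2.0, ModelParams(1, E, 0))
        assert forces.conservative == 0.0
        assert forces.total == forces.inertial

    def test_signs_inside_interval(self, norm9):
        ys = np.linspace(1.01, E - 0.01, 100)
        inertial, conservative, _ = force_decomposition(ys, norm9)
        assert np.all(inertial > 0)
        assert np.all(conservative < 0)

    @pytest.mark.parametrize("y", [1.0, E])
    def test_domain_errors(self, y, norm9):
        with pytest.raises(DomainError):
            force_decomposition(y, norm9)


class TestModelParams:
    @pytest.mark.parametrize(
        "c0, c1, k", [(0, 1, 1), (-1, 1, 1), (2, 1, 1), (1, E, -0.5), (1, E, float("nan"))]
    )
    def test_invalid(self, c0, c1, k):
        with pytest.raises(ParameterError):
            ModelParams(c0, c1, k)

    def test_normalized_constructor(self):
        p = ModelParams.normalized(9.0)
        assert (p.c0, p.c1, p.k) == (1.0, E, 9.0)
        assert p.k_star == pytest.approx(4 * E / (E - 1))
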