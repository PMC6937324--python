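"""Unit and property tests for the closed-form Q-model equations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from qsoc.model import (
    GenericKinetics,
    LocalParams,
    ParameterValidityError,
    SiteKinetics,
    decay_exponent,
    effective_beta,
    initial_som_quality,
    mean_quality,
    plant_fraction,
    soc_stock,
    steady_state_plant_pool,
    validate_parameters,
)

# strategies spanning the prior box, constrained to valid combinations
u0_s = st.floats(0.01, 0.98)
eta11_s = st.floats(0.05, 0.72)
q0_s = st.floats(0.5, 1.5)
e0_s = st.floats(0.05, 0.55)
beta_s = st.floats(0.5, 1.3)


def valid(e0, eta11, beta):
    return decay_exponent(e0, eta11, beta) > 0 and (1 - e0 - eta11 * e0 * beta) > 0


@pytest.mark.parametrize(
    "beta0, clay, expected",
    [(0.7, 0.0, 0.7), (0.7, 36.0, 1.06), (0.7, 17.0, 0.87)],
)
def test_effective_beta_values(beta0, clay, expected):
    assert effective_beta(beta0, clay) == pytest.approx(expected)


def test_effective_beta_domain_errors():
    with pytest.raises(ParameterValidityError):
        effective_beta(-0.1, 10.0)
    with pytest.raises(ParameterValidityError):
        effective_beta(0.7, -5.0)


def test_mean_quality_frozen_value():
    # direct evaluation of the closed form in extended precision
    assert mean_quality(10, 1.08, 0.87, 0.36, 0.49, 1.0) == pytest.approx(
        0.3537049, rel=1e-5
    )


def test_mean_quality_at_zero_is_q0():
    assert mean_quality(0.0, 1.08, 0.87, 0.36, 0.49) == pytest.approx(1.08)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(q0=q0_s, beta=beta_s, eta11=eta11_s, u0=u0_s)
def test_mean_quality_monotone_and_bounded(q0, beta, eta11, u0):
    t = np.array([0.0, 5.0, 10.0, 20.0, 40.0, 80.0])
    q = mean_quality(t, q0, beta, eta11, u0)
    assert np.all(np.diff(q) < 0)
    assert np.all(q > 0)
    assert q[0] == pytest.approx(q0)


def test_mean_quality_beta_limit():
    """For beta -> 0 the closed form converges to the exponential limit."""
    t = np.linspace(0.0, 80.0, 41)
    q0, eta11, u0, re = 1.08, 0.36, 0.49, 1.0
    beta = 1e-6
    exact = mean_quality(t, q0, beta, eta11, u0, re)
    limit = q0 * np.exp(-eta11 * u0 * re * q0**beta * t)
    assert np.max(np.abs(exact - limit) / limit) < 1e-4


@pytest.mark.parametrize(
    "e0, eta11, beta, expected",
    [(0.3, 0.36, 0.87, 5.611481), (0.5, 0.5, 1.0, 1.0)],
)
def test_decay_exponent_values(e0, eta11, beta, expected):
    assert decay_exponent(e0, eta11, beta) == pytest.approx(expected, rel=1e-6)


def test_decay_exponent_domain_error():
    with pytest.raises(ParameterValidityError):
        decay_exponent(0.0, 0.36, 0.87)


def test_soc_stock_frozen_value():
    # chained evaluation of the quality and stock closed forms
    got = soc_stock(10, 65.5, 1.08, 0.87, 0.36, 0.05, 0.3, 1.0)
    assert got == pytest.approx(24.1307, rel=1e-4)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(q0=q0_s, beta=beta_s, eta11=eta11_s, u0=u0_s, e0=e0_s)
def test_soc_stock_decreasing_positive_no_floor(q0, beta, eta11, u0, e0):
    """Stock equals Css at t=0, decreases strictly, and stays positive at
    every finite time — no inert pool."""
    if not valid(e0, eta11, beta):
        return
    t = np.array([0.0, 10.0, 300.0, 1000.0, 3000.0])
    c = soc_stock(t, 65.5, q0, beta, eta11, u0, e0)
    assert c[0] == pytest.approx(65.5)
    # the exact log-stock is monotone decreasing and finite at all finite t;
    # the direct evaluation must agree wherever doubles can represent it
    expo = decay_exponent(e0, eta11, beta)
    log_c = np.log(65.5) + expo * (
        np.log(mean_quality(t, q0, beta, eta11, u0)) - np.log(q0)
    )
    assert np.all(np.diff(log_c) < 0)
    representable = log_c > -700.0
    assert np.all(c[representable] > 0)
    assert np.all(np.diff(c[representable]) < 0)


def test_soc_stock_invalid_parameters_raise():
    # e0 = 0.95 makes the decay exponent negative for these kinetics
    with pytest.raises(ParameterValidityError):
        soc_stock(10, 65.5, 1.08, 0.87, 0.36, 0.05, 0.95)


def test_initial_som_quality_values():
    assert initial_som_quality(1.08, 0.3, 0.36, 0.87) == pytest.approx(
        0.9166478, rel=1e-5
    )
    # linear in q0
    a = initial_som_quality(1.0, 0.3, 0.36, 0.87)
    assert initial_som_quality(2.0, 0.3, 0.36, 0.87) == pytest.approx(2 * a)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(q0=q0_s, beta=beta_s, eta11=eta11_s, e0=e0_s)
def test_initial_som_quality_below_q0(q0, beta, eta11, e0):
    if not valid(e0, eta11, beta):
        return
    assert initial_som_quality(q0, e0, eta11, beta) < q0


def test_steady_state_plant_pool():
    assert steady_state_plant_pool(0.0, 0.3, 0.05, 1.08, 0.87) == 0.0
    got = steady_state_plant_pool(1.0, 0.3, 0.05, 1.08, 0.87)
    assert got == pytest.approx(5.61142, rel=1e-5)
    assert steady_state_plant_pool(2.0, 0.3, 0.05, 1.08, 0.87) == pytest.approx(
        2 * got
    )


def test_plant_fraction_conventions():
    assert plant_fraction(0.0, 1.08, 0.87, 0.3, 0.05) == pytest.approx(1.0)
    assert plant_fraction(10, 1.08, 0.87, 0.3, 0.05) == pytest.approx(
        0.168288, rel=1e-5
    )
    assert plant_fraction(
        1, 1.08, 0.87, 0.3, 0.05, rate_convention="eq6_printed"
    ) == pytest.approx(0.0036559, rel=1e-4)
    with pytest.raises(ValueError):
        plant_fraction(1, 1.08, 0.87, 0.3, 0.05, rate_convention="bogus")


def test_plant_fraction_matches_ode_integration():
    """The default convention reproduces the mass-balance ODE with zero
    input to near machine precision."""
    q0, beta, e0, u0, re = 1.08, 0.87, 0.3, 0.05, 1.0
    k = u0 * re * q0**beta / e0
    sol = solve_ivp(
        lambda t, y: -k * y,
        (0.0, 80.0),
        [1.0],
        t_eval=np.linspace(0, 80, 81),
        rtol=1e-12,
        atol=1e-14,
    )
    closed = plant_fraction(sol.t, q0, beta, e0, u0, re)
    assert np.max(np.abs(closed - sol.y[0]) / sol.y[0]) < 1e-6


def test_validate_parameters_verdicts():
    gk = GenericKinetics(u0=0.49, eta11=0.36)
    lp = LocalParams(q0=1.08, e0=0.3, beta0=0.7)
    site = SiteKinetics(beta=effective_beta(0.7, 17.0), re=1.0, css=65.5)
    assert validate_parameters(gk, lp, site).valid

    bad_e0 = LocalParams(q0=1.08, e0=0.99, beta0=0.7)
    verdict = validate_parameters(gk, bad_e0, site)
    assert not verdict.valid and any("e0" in r or "quality" in r for r in verdict.reasons)

    bad_u0 = GenericKinetics(u0=-1.0, eta11=0.36)
    verdict = validate_parameters(bad_u0, lp, site)
    assert not verdict.valid
    assert any("positivity" in r for r in verdict.reasons)
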