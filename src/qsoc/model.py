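"""Closed-form continuous-quality (Q) model of soil organic carbon decay.

The Q model describes soil organic matter (SOM) as a continuum of *quality*
values rather than a set of discrete pools.  Each carbon atom carries a
dimensionless quality ``q`` inversely related to its persistence; decomposers
consume high-quality carbon faster and return it to the soil at lower quality,
so the stock-average quality ``q_bar`` drifts downward over time.  Under a
long-term bare fallow (inputs held at zero) the model admits closed forms for
the stock-average quality, the total SOC stock and the surviving
plant-derived fraction, which is what this module provides.

Parameters
----------
The kinetic parameters split into two groups:

* generic (assumed thermodynamically constrained, shared across sites):
  ``u0`` — decomposer metabolic rate (the carbon concentration of decomposer
  biomass is absorbed into it) and ``eta11`` — the rate at which average
  quality declines as material is reprocessed.
* local (site history and soil dependent): ``q0`` — quality of the litter
  input that built the stock, ``e0`` — decomposer carbon-use efficiency, and
  ``beta0`` — the edaphic offset of the shape parameter ``beta`` linking
  decomposer growth rate to quality.  ``beta`` itself is ``beta0`` plus a
  clay-content term, and the whole kinetics is rescaled by a dimensionless
  climate scalar ``re`` (see :mod:`qsoc.climate`).

All functions are vectorised over time ``t`` (years since the start of the
fallow) and raise :class:`ParameterValidityError` rather than returning
silently wrong numbers when the parameter combination leaves the model's
domain of validity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "ParameterValidityError",
    "GenericKinetics",
    "LocalParams",
    "SiteKinetics",
    "ValidityVerdict",
    "BETA_SINGULAR_TOL",
    "effective_beta",
    "mean_quality",
    "decay_exponent",
    "soc_stock",
    "initial_som_quality",
    "steady_state_plant_pool",
    "plant_fraction",
    "validate_parameters",
]

#: Below this value of beta, Eq-2-type expressions switch to their beta -> 0
#: exponential limit to avoid the 1/beta singularity.
BETA_SINGULAR_TOL = 1e-8

RATE_CONVENTIONS = ("eq4_consistent", "eq6_printed")


class ParameterValidityError(ValueError):
    """Raised when a parameter combination violates the model's validity rules."""


@dataclass(frozen=True)
class GenericKinetics:
    """Kinetic parameters shared across all sites.

    u0
        Decomposer metabolic rate (per year, on the quality scale).
    eta11
        Rate of decrease in quality per pass through the decomposers.
    """

    u0: float
    eta11: float


@dataclass(frozen=True)
class LocalParams:
    """Site-specific parameters.

    q0
        Initial litter input quality (dimensionless, near 1).
    e0
        Decomposer carbon-use efficiency, fraction in (0, 1).
    beta0
        Edaphic offset of the quality-shape parameter beta.
    """

    q0: float
    e0: float
    beta0: float


@dataclass(frozen=True)
class SiteKinetics:
    """Derived per-site quantities entering the closed forms.

    beta
        Effective shape parameter, ``beta0 + 0.01 * clay_percent``.
    re
        Normalised climate scalar (dimensionless, about 1).
    css
        SOC stock at steady state = at the start of the fallow (Mg C/ha).
    cp_ss
        Plant-derived pool at steady state; optional, only used when the
        plant-fraction observable is modelled in absolute units.
    """

    beta: float
    re: float
    css: float
    cp_ss: float | None = None


@dataclass(frozen=True)
class ValidityVerdict:
    valid: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # truthiness mirrors the verdict
        return self.valid


def effective_beta(beta0: float, clay_percent: float) -> float:
    """Effective shape parameter: calibrated offset plus the clay term.

    ``beta = beta0 + 0.01 * chi`` where ``chi`` is the clay concentration
    of the soil in percent.
    """
    if beta0 <= 0:
        raise ParameterValidityError(f"beta0 must be positive, got {beta0}")
    if not 0 <= clay_percent <= 100:
        raise ParameterValidityError(
            f"clay_percent must lie in [0, 100], got {clay_percent}"
        )
    return beta0 + 0.01 * clay_percent


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ParameterValidityError(f"{name} must be positive, got {value}")


def mean_quality(
    t: float | np.ndarray,
    q0: float,
    beta: float,
    eta11: float,
    u0: float,
    re: float = 1.0,
) -> float | np.ndarray:
    """Stock-average SOM quality ``q_bar(t)`` under zero input.

    Closed form ``q0 / (1 + beta*eta11*u0*re*q0**beta * t)**(1/beta)``;
    strictly decreasing in ``t`` and tending to zero.  For ``beta`` below
    :data:`BETA_SINGULAR_TOL` the exponential limit
    ``q0 * exp(-eta11*u0*re*q0**beta * t)`` is used instead.
    """
    _check_positive(q0=q0, eta11=eta11, u0=u0, re=re)
    if beta < 0:
        raise ParameterValidityError(f"beta must be non-negative, got {beta}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    rate = eta11 * u0 * re * q0**beta
    if beta < BETA_SINGULAR_TOL:
        out = q0 * np.exp(-rate * t)
    else:
        out = q0 * (1.0 + beta * rate * t) ** (-1.0 / beta)
    return out if out.ndim else float(out)


def decay_exponent(e0: float, eta11: float, beta: float) -> float:
    """Exponent ``(1 - e0)/(eta11 * e0) - beta`` governing stock decay.

    This is the power to which the quality ratio ``q_bar/q0`` is raised in the
    stock closed form; it must be positive for the model to describe decay.
    """
    if not 0 < e0 < 1:
        raise ParameterValidityError(f"e0 must lie in (0, 1), got {e0}")
    _check_positive(eta11=eta11)
    return (1.0 - e0) / (eta11 * e0) - beta


def soc_stock(
    t: float | np.ndarray,
    css: float,
    q0: float,
    beta: float,
    eta11: float,
    u0: float,
    e0: float,
    re: float = 1.0,
) -> float | np.ndarray:
    """SOC stock ``C(t) = Css * (q_bar(t)/q0)**decay_exponent`` (Mg C/ha).

    Equals ``css`` at ``t = 0``, decreases strictly and approaches zero
    without ever reaching an inert floor.  Raises
    :class:`ParameterValidityError` when the decay exponent is not positive.
    """
    _check_positive(Css=css)
    expo = decay_exponent(e0, eta11, beta)
    if expo <= 0:
        raise ParameterValidityError(
            f"decay exponent must be positive for SOC decay, got {expo}"
        )
    ratio = mean_quality(t, q0, beta, eta11, u0, re) / q0
    out = css * np.asarray(ratio) ** expo
    return out if out.ndim else float(out)


def initial_som_quality(q0: float, e0: float, eta11: float, beta: float) -> float:
    """Average SOM quality at the pre-fallow steady state.

    ``q_bar0 = q0 * (1 - e0 - eta11*e0*beta) / (1 - e0 - eta11*e0*(beta-1))``.
    Linear in ``q0``, below ``q0`` whenever ``eta11*e0 > 0``.
    """
    if not 0 < e0 < 1:
        raise ParameterValidityError(f"e0 must lie in (0, 1), got {e0}")
    _check_positive(eta11=eta11, beta=beta, q0=q0)
    num = 1.0 - e0 - eta11 * e0 * beta
    if num <= 0:
        raise ParameterValidityError(
            "equilibrium quality undefined: 1 - e0 - eta11*e0*beta must be "
            f"positive, got {num}"
        )
    den = 1.0 - e0 - eta11 * e0 * (beta - 1.0)
    return q0 * num / den


def steady_state_plant_pool(
    input_rate: float, e0: float, u0: float, q0: float, beta: float
) -> float:
    """Plant-derived pool at steady state, ``e0 * I / (u0 * q0**beta)``.

    ``I`` is the litter input rate that maintained the pool before the fallow
    started; the pool is linear in ``I``.
    """
    if input_rate < 0:
        raise ParameterValidityError(f"input rate must be >= 0, got {input_rate}")
    _check_positive(u0=u0, q0=q0)
    return e0 * input_rate / (u0 * q0**beta)


def plant_fraction(
    t: float | np.ndarray,
    q0: float,
    beta: float,
    e0: float,
    u0: float,
    re: float = 1.0,
    rate_convention: str = "eq4_consistent",
) -> float | np.ndarray:
    """Fraction of the original plant-derived carbon remaining at time ``t``.

    The pool of material still at input quality decays exponentially once
    inputs stop, ``Cp(t)/Cp(0) = exp(-k t)``.  Two conventions for the rate
    constant ``k`` are supported:

    * ``"eq4_consistent"`` (default): ``k = u0 * re * q0**beta / e0`` — the
      decomposition rate of the pre-fallow mass-balance equation with the
      input switched off.
    * ``"eq6_printed"``: ``k = e0 / (u0 * re * q0**beta)`` — the reciprocal
      form as it is sometimes typeset; retained so both readings can be
      compared explicitly.

    The climate scalar ``re`` rescales ``u0`` wherever it appears.
    """
    _check_positive(q0=q0, e0=e0, u0=u0, re=re)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if rate_convention == "eq4_consistent":
        k = u0 * re * q0**beta / e0
    elif rate_convention == "eq6_printed":
        k = e0 / (u0 * re * q0**beta)
    else:
        raise ValueError(
            f"unknown rate_convention {rate_convention!r}; "
            f"expected one of {RATE_CONVENTIONS}"
        )
    out = np.exp(-k * t)
    return out if out.ndim else float(out)


def validate_parameters(
    generic: GenericKinetics,
    local: LocalParams,
    site: SiteKinetics,
) -> ValidityVerdict:
    """Check a full parameter set against every model validity rule.

    Returns a verdict object listing the violated rules instead of raising,
    so samplers can treat invalid proposals as zero-probability.
    """
    reasons: list[str] = []
    for name, value in (
        ("u0", generic.u0),
        ("eta11", generic.eta11),
        ("q0", local.q0),
        ("beta0", local.beta0),
        ("beta", site.beta),
        ("re", site.re),
        ("Css", site.css),
    ):
        if not value > 0:
            reasons.append(f"positivity: {name} = {value} must be > 0")
    if not 0 < local.e0 < 1:
        reasons.append(f"positivity: e0 = {local.e0} must lie in (0, 1)")
    if not reasons:
        expo = decay_exponent(local.e0, generic.eta11, site.beta)
        if expo <= 0:
            reasons.append(f"decay exponent = {expo:.4g} must be > 0")
        eq_num = 1.0 - local.e0 - generic.eta11 * local.e0 * site.beta
        if eq_num <= 0:
            reasons.append(
                f"equilibrium quality numerator = {eq_num:.4g} must be > 0"
            )
    return ValidityVerdict(valid=not reasons, reasons=tuple(reasons))
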