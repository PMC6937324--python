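"""Prior distributions for the Q-model calibration.

Defaults follow the literature-anchored choices used for bare-fallow
calibrations of the model:

* ``eta11`` ~ Uniform(0, 0.72) and ``u0`` ~ Uniform(0, 0.98) — wide, weakly
  informative boxes spanning plus/minus 100 % of the literature values
  (0.36 for eta11; 0.49 = 0.5 x 0.98 for u0 once the decomposer carbon
  concentration is absorbed into it),
* ``beta0`` ~ Normal(0.7, sd 0.07) truncated to [0.469, 0.931] (plus/minus
  33 % of the literature value),
* ``q0`` ~ Normal(1.08, sd 0.108) truncated to [0.5, 1.5], per site,
* ``e0`` ~ Normal(0.3, sd 0.03) truncated to [0, 0.6], per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PriorSpec", "build_priors", "DEFAULT_PRIORS"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior: uniform or truncated normal on a finite interval."""

    name: str
    family: str  # "uniform" | "truncnorm"
    loc: float
    scale: float
    lower: float
    upper: float
    _log_z: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("truncation bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError("truncation bounds must be ordered")
        if self.family == "uniform":
            log_z = math.log(self.upper - self.lower)
        elif self.family == "truncnorm":
            a = (self.lower - self.loc) / self.scale
            b = (self.upper - self.loc) / self.scale
            z = stats.norm.cdf(b) - stats.norm.cdf(a)
            log_z = math.log(z) + math.log(self.scale) + _LOG_SQRT_2PI
        else:
            raise ValueError(f"unknown prior family {self.family!r}")
        object.__setattr__(self, "_log_z", log_z)

    def logpdf(self, x: float) -> float:
        """Normalised log density (integrates to 1 over the bounds)."""
        if x < self.lower or x > self.upper:
            return -math.inf
        if self.family == "uniform":
            return -self._log_z
        return -0.5 * ((x - self.loc) / self.scale) ** 2 - self._log_z

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "uniform":
            return rng.uniform(self.lower, self.upper, size=size)
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        return stats.truncnorm.rvs(
            a, b, loc=self.loc, scale=self.scale, size=size, random_state=rng
        )

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF over the truncated support (used by goodness-of-fit tests)."""
        x = np.clip(np.asarray(x, dtype=float), self.lower, self.upper)
        if self.family == "uniform":
            return (x - self.lower) / (self.upper - self.lower)
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        return stats.truncnorm.cdf(x, a, b, loc=self.loc, scale=self.scale)

    @property
    def sd(self) -> float:
        """Spread used to initialise proposal scales (not the exact moment)."""
        if self.family == "uniform":
            return (self.upper - self.lower) / math.sqrt(12.0)
        return self.scale


DEFAULT_PRIORS: dict[str, PriorSpec] = {
    "u0": PriorSpec("u0", "uniform", 0.49, 0.0, 0.0, 0.98),
    "eta11": PriorSpec("eta11", "uniform", 0.36, 0.0, 0.0, 0.72),
    "q0": PriorSpec("q0", "truncnorm", 1.08, 0.108, 0.5, 1.5),
    "e0": PriorSpec("e0", "truncnorm", 0.3, 0.03, 0.0, 0.6),
    "beta0": PriorSpec("beta0", "truncnorm", 0.7, 0.07, 0.469, 0.931),
}


def build_priors(overrides: dict | None = None) -> dict[str, PriorSpec]:
    """Return the default prior set, optionally overriding entries.

    ``overrides`` maps a parameter name to either a :class:`PriorSpec` or a
    dict of PriorSpec fields (``family, loc, scale, lower, upper``).
    """
    priors = dict(DEFAULT_PRIORS)
    for name, spec in (overrides or {}).items():
        if isinstance(spec, PriorSpec):
            priors[name] = spec
        else:
            priors[name] = PriorSpec(name=name, **spec)
    return priors
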