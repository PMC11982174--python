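"""Priors on the standardized effect size for Bayes factor t-tests.

Two families cover the analyses here: the zero-centered Cauchy prior of the
Jeffreys-Zellner-Siow (JZS) setup, and shifted/scaled Student-t priors used
to encode an informed ("adversarial") expert position, conventionally with
3 degrees of freedom so the prior keeps heavy tails around its centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import InvalidInputError

#: default JZS Cauchy scale, sqrt(2)/2
DEFAULT_CAUCHY_SCALE = 0.707


@dataclass(frozen=True)
class EffectSizePrior:
    """Prior on the standardized effect delta.

    family ``"cauchy"``: location fixed at 0, scale r (JZS).
    family ``"student_t"``: location/scale/df, e.g. an informed t(3) prior.
    """

    family: str
    scale: float
    location: float = 0.0
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("cauchy", "student_t"):
            raise InvalidInputError(f"unknown prior family: {self.family!r}")
        if not (self.scale > 0):
            raise InvalidInputError(f"prior scale must be > 0, got {self.scale}")
        if self.family == "cauchy" and self.location != 0.0:
            raise InvalidInputError("the Cauchy effect-size prior is centered at 0")
        if self.family == "student_t":
            if self.df is None or self.df < 1:
                raise InvalidInputError("student_t prior needs df >= 1")

    def _dist(self):
        if self.family == "cauchy":
            return stats.cauchy(loc=0.0, scale=self.scale)
        return stats.t(self.df, loc=self.location, scale=self.scale)

    def logpdf(self, delta) -> np.ndarray:
        return self._dist().logpdf(delta)

    def cdf(self, delta):
        return self._dist().cdf(delta)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self._dist().rvs(size=size, random_state=rng)

    def support_points(self) -> list[float]:
        """Breakpoints bracketing the prior mass, for adaptive quadrature."""
        loc, s = self.location, self.scale
        return [loc + k * s for k in (-100.0, -10.0, -1.0, 0.0, 1.0, 10.0, 100.0)]


def cauchy_prior(scale: float = DEFAULT_CAUCHY_SCALE) -> EffectSizePrior:
    return EffectSizePrior(family="cauchy", scale=scale)


def informed_t_prior(location: float, scale: float, df: float = 3.0) -> EffectSizePrior:
    return EffectSizePrior(family="student_t", location=location, scale=scale, df=df)


def adversarial_scale(se: float, df: float) -> float:
    """Scale of an informed t prior matching a given SE: se * sqrt(df/(df-2)).

    A Student t with df degrees of freedom and scale s has standard deviation
    s * sqrt(df/(df-2)); inverting puts the prior's SD at the estimate's SE.
    Requires df >= 3 so the factor is defined.
    """
    if df < 3:
        raise InvalidInputError(f"adversarial scale needs df >= 3, got {df}")
    if se < 0:
        raise InvalidInputError("SE must be non-negative")
    return se * math.sqrt(df / (df - 2.0))
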