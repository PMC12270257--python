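"""Age-of-onset models for variant carriers and noncarriers.

The carrier penetrance is a threshold-shifted Weibull CDF scaled by a
lifetime asymptote:

    F(t) = gamma * (1 - exp(-((t - delta)/alpha)**beta))   for t > delta
    F(t) = 0                                               otherwise

with scale ``alpha > 0``, shape ``beta > 0``, asymptote ``0 < gamma < 1``
and onset threshold ``delta >= 0``.  Estimation runs in an equivalent
quantile-space parameterization (first-quartile age, median age, asymptote,
threshold) which maps one-to-one onto ``(alpha, beta)`` in closed form.

Noncarrier risk is a registry-style cumulative probability table by sex on
an annual age grid (1..max_age).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_MAX_AGE = 94

_LN2 = math.log(2.0)
_LN43 = math.log(4.0 / 3.0)

# sex codes used throughout the package
FEMALE, MALE, UNKNOWN_SEX = "F", "M", "U"


class ModelDomainError(ValueError):
    """Raised when parameters violate their stated bounds."""


@dataclass(frozen=True)
class WeibullParams:
    """Carrier penetrance parameters (scale, shape, asymptote, threshold)."""

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0):
            raise ModelDomainError(f"scale alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0.0):
            raise ModelDomainError(f"shape beta must be > 0, got {self.beta}")
        if not (0.0 < self.gamma < 1.0):
            raise ModelDomainError(f"asymptote gamma must lie in (0,1), got {self.gamma}")
        if not (self.delta >= 0.0):
            raise ModelDomainError(f"threshold delta must be >= 0, got {self.delta}")


@dataclass(frozen=True)
class QuantileParams:
    """Quantile-space parameterization: quartile ages among the eventually affected.

    ``q1`` and ``med`` are the ages by which 25% and 50% of eventually
    affected carriers have onset; ``gamma`` and ``delta`` are shared with
    :class:`WeibullParams`.
    """

    q1: float
    med: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ModelDomainError(f"asymptote gamma must lie in (0,1), got {self.gamma}")
        if not (self.delta >= 0.0):
            raise ModelDomainError(f"threshold delta must be >= 0, got {self.delta}")
        if not (self.delta < self.q1 < self.med):
            raise ModelDomainError(
                f"require delta < q1 < med, got delta={self.delta}, q1={self.q1}, med={self.med}"
            )


def penetrance_cdf(theta: WeibullParams, age) -> np.ndarray | float:
    """Cumulative onset probability for carriers at ``age`` (scalar or array)."""
    age_arr = np.asarray(age, dtype=float)
    shifted = np.clip(age_arr - theta.delta, 0.0, None)
    with np.errstate(over="ignore"):  # (t/alpha)**beta may overflow; expm1(-inf) -> -1
        out = theta.gamma * -np.expm1(-((shifted / theta.alpha) ** theta.beta))
    if np.ndim(age) == 0:
        return float(out)
    return out


def annual_onset_prob(theta: WeibullParams, max_age: int = DEFAULT_MAX_AGE) -> np.ndarray:
    """Probability of onset in each year of age 1..max_age (vector of length max_age).

    Entry ``a-1`` is ``F(a) - F(a-1)``; the vector plus the never-affected
    mass ``1 - F(max_age)`` sums to one.
    """
    grid = np.arange(0, max_age + 1, dtype=float)
    cdf = penetrance_cdf(theta, grid)
    return np.diff(cdf)


def quantiles_to_weibull(q: QuantileParams, min_spread: float = 1e-6) -> WeibullParams:
    """Map quantile-space parameters to (alpha, beta, gamma, delta).

    Solves ``F(q1)/gamma = 1/4`` and ``F(med)/gamma = 1/2`` in closed form:

        beta  = ln(ln(4/3)/ln 2) / ln((q1 - delta)/(med - delta))
        alpha = (med - delta) / (ln 2)**(1/beta)
    """
    if q.med - q.q1 < min_spread:
        raise ModelDomainError(
            f"median and first quartile too close: med - q1 = {q.med - q.q1}"
        )
    beta = math.log(_LN43 / _LN2) / math.log((q.q1 - q.delta) / (q.med - q.delta))
    alpha = (q.med - q.delta) / _LN2 ** (1.0 / beta)
    return WeibullParams(alpha=alpha, beta=beta, gamma=q.gamma, delta=q.delta)


def weibull_to_quantiles(theta: WeibullParams) -> QuantileParams:
    """Inverse of :func:`quantiles_to_weibull` (for reporting)."""
    q1 = theta.delta + theta.alpha * _LN43 ** (1.0 / theta.beta)
    med = theta.delta + theta.alpha * _LN2 ** (1.0 / theta.beta)
    return QuantileParams(q1=q1, med=med, gamma=theta.gamma, delta=theta.delta)


class BaselineRisk:
    """Noncarrier cumulative disease risk by sex on the annual age grid.

    Stores, per sex, a nondecreasing vector ``cum`` of length ``max_age``
    where ``cum[a-1]`` is the cumulative probability of disease by age ``a``.
    """

    def __init__(self, cum: Mapping[str, np.ndarray], max_age: int = DEFAULT_MAX_AGE):
        self.max_age = int(max_age)
        self.cum: dict[str, np.ndarray] = {}
        for sex in (FEMALE, MALE):
            v = np.asarray(cum[sex], dtype=float)
            if v.shape != (self.max_age,):
                raise ModelDomainError(
                    f"baseline vector for sex {sex} must have length {self.max_age}"
                )
            if np.any(v < 0.0) or np.any(v > 1.0):
                raise ModelDomainError("baseline cumulative risk must lie in [0,1]")
            if np.any(np.diff(v) < -1e-12):
                raise ModelDomainError("baseline cumulative risk must be nondecreasing")
            self.cum[sex] = v

    @classmethod
    def from_points(
        cls,
        ages,
        risks_female,
        risks_male=None,
        max_age: int = DEFAULT_MAX_AGE,
    ) -> "BaselineRisk":
        """Build from sparse (age, cumulative risk) points, linearly interpolated.

        A virtual anchor (0, 0) is prepended; risk is held constant beyond
        the last supplied age.
        """
        ages = np.asarray(ages, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ModelDomainError("baseline ages must be strictly increasing")
        grid = np.arange(1, max_age + 1, dtype=float)

        def interp(risks):
            risks = np.asarray(risks, dtype=float)
            if np.any(np.diff(risks) < 0):
                raise ModelDomainError("baseline cumulative risk must be nondecreasing")
            return np.interp(grid, np.concatenate([[0.0], ages]), np.concatenate([[0.0], risks]))

        female = interp(risks_female)
        male = interp(risks_male if risks_male is not None else risks_female)
        return cls({FEMALE: female, MALE: male}, max_age=max_age)

    @classmethod
    def zero(cls, max_age: int = DEFAULT_MAX_AGE) -> "BaselineRisk":
        z = np.zeros(max_age)
        return cls({FEMALE: z, MALE: z.copy()}, max_age=max_age)

    @classmethod
    def read(cls, path, max_age: int = DEFAULT_MAX_AGE) -> "BaselineRisk":
        """Read a delimited table: (age, risk) or (age, female, male)."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] == 2:
            return cls.from_points(df.iloc[:, 0], df.iloc[:, 1], max_age=max_age)
        if df.shape[1] >= 3:
            return cls.from_points(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2], max_age=max_age)
        raise ModelDomainError("baseline table needs 2 or 3 columns")

    def annual(self, sex: str) -> np.ndarray:
        """Annual onset probabilities for noncarriers (length max_age)."""
        c = self.cum[sex]
        return np.diff(np.concatenate([[0.0], c]))

    def cumulative(self, sex: str) -> np.ndarray:
        return self.cum[sex]


def baseline_annual_onset(b: BaselineRisk) -> dict[str, np.ndarray]:
    """Per-sex annual noncarrier onset probabilities over ages 1..max_age."""
    return {FEMALE: b.annual(FEMALE), MALE: b.annual(MALE)}


def theta_as_dict(theta: WeibullParams) -> dict[str, float]:
    return dataclasses.asdict(theta)
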