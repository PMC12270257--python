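"""Prior distributions over the quantile-space penetrance parameters.

The default prior is: threshold delta ~ Uniform(5, 30); given delta, the
first-quartile age is delta + B1*(max_age - delta) with B1 ~ Beta(6, 3);
given q1, the median age is q1 + B2*(max_age - q1) with B2 ~ Beta(2, 2);
the asymptote gamma ~ Beta(1, 1).  The sequential scaling guarantees
delta < q1 < med by construction.

Literature-based elicitation replaces components by moment-matched Betas:
relative-risk summaries inform the asymptote; age-specific risk points
(e.g. read off a Kaplan-Meier curve) inform the quartile ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .model import DEFAULT_MAX_AGE, ModelDomainError, QuantileParams


class PriorError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSet:
    """Component priors: Beta shapes for q1/med/gamma, Uniform bounds for delta."""

    q1_shapes: tuple[float, float] = (6.0, 3.0)
    med_shapes: tuple[float, float] = (2.0, 2.0)
    gamma_shapes: tuple[float, float] = (1.0, 1.0)
    delta_bounds: tuple[float, float] = (5.0, 30.0)

    def __post_init__(self) -> None:
        for name, (a, b) in (
            ("q1", self.q1_shapes),
            ("med", self.med_shapes),
            ("gamma", self.gamma_shapes),
        ):
            if a <= 0 or b <= 0:
                raise PriorError(f"{name} Beta shapes must be positive, got ({a}, {b})")
        lo, hi = self.delta_bounds
        if not (0 <= lo < hi):
            raise PriorError(f"delta bounds must satisfy 0 <= lo < hi, got ({lo}, {hi})")


@dataclass(frozen=True)
class RiskSummary:
    """A published-study summary usable for prior elicitation.

    Exactly one route is populated: a relative risk with its confidence
    interval, or age-specific cumulative risk points with the study size.
    """

    relative_risk: float | None = None
    rr_ci: tuple[float, float] | None = None
    risk_points: tuple[tuple[float, float], ...] | None = None  # (age, cum risk)
    n_subjects: float | None = None
    follow_up_age: float | None = None
    lifetime_risk: float | None = None


def default_priors() -> PriorSet:
    return PriorSet()


def sample_prior(
    ps: PriorSet, rng: np.random.Generator, max_age: int = DEFAULT_MAX_AGE
) -> QuantileParams:
    """One draw from the prior; always satisfies delta < q1 < med < max_age."""
    lo, hi = ps.delta_bounds
    delta = rng.uniform(lo, hi)
    b1 = rng.beta(*ps.q1_shapes)
    q1 = delta + b1 * (max_age - delta)
    b2 = rng.beta(*ps.med_shapes)
    med = q1 + b2 * (max_age - q1)
    gamma = rng.beta(*ps.gamma_shapes)
    # Beta draws can hit the boundary at floating-point resolution
    gamma = min(max(gamma, 1e-12), 1.0 - 1e-12)
    q1 = min(q1, max_age - 2e-6)
    med = max(min(med, max_age - 1e-6), q1 + 1e-9)
    q1 = max(q1, delta + 1e-9)
    return QuantileParams(q1=q1, med=med, gamma=gamma, delta=delta)


def _beta_logpdf(x: float, a: float, b: float) -> float:
    # math.lgamma is ~100x cheaper than scipy.stats.beta.logpdf here
    if not (0.0 < x < 1.0):
        return -math.inf
    return (
        (a - 1.0) * math.log(x)
        + (b - 1.0) * math.log1p(-x)
        + math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
    )


def log_prior_density(
    ps: PriorSet, q: QuantileParams, max_age: int = DEFAULT_MAX_AGE
) -> float:
    """Log prior density at q (includes interval-scaling Jacobians); -inf off support."""
    lo, hi = ps.delta_bounds
    if not (lo < q.delta < hi):
        return -math.inf
    if not (q.delta < q.q1 < q.med < max_age):
        return -math.inf
    if not (0.0 < q.gamma < 1.0):
        return -math.inf
    lp = -math.log(hi - lo)
    span1 = max_age - q.delta
    b1 = (q.q1 - q.delta) / span1
    lp += _beta_logpdf(b1, *ps.q1_shapes) - math.log(span1)
    span2 = max_age - q.q1
    b2 = (q.med - q.q1) / span2
    lp += _beta_logpdf(b2, *ps.med_shapes) - math.log(span2)
    lp += _beta_logpdf(q.gamma, *ps.gamma_shapes)
    return float(lp)


def _beta_shapes_from_moments(mean: float, var: float) -> tuple[float, float]:
    """Beta(a, b) with the given mean and variance (variance capped to be proper)."""
    mean = min(max(mean, 1e-6), 1.0 - 1e-6)
    var = min(var, 0.999 * mean * (1.0 - mean))
    var = max(var, 1e-12)
    kappa = mean * (1.0 - mean) / var - 1.0
    return (mean * kappa, (1.0 - mean) * kappa)


def elicit_from_relative_risk(
    rs: RiskSummary, baseline_lifetime: float, base: PriorSet | None = None
) -> PriorSet:
    """Asymptote prior from a relative-risk summary.

    The implied carrier lifetime risk is rr * baseline lifetime risk (capped
    at 0.99); its standard error follows from the rr confidence-interval
    width on the log scale by the delta method.  Other components keep their
    defaults.
    """
    base = base or default_priors()
    rr = rs.relative_risk
    if rr is None or rr <= 0:
        raise PriorError(f"relative risk must be positive, got {rr}")
    if not (0.0 < baseline_lifetime < 1.0):
        raise PriorError("baseline lifetime risk must lie in (0,1)")
    mean = min(rr * baseline_lifetime, 0.99)
    if rs.rr_ci is not None:
        lo, hi = rs.rr_ci
        if not (0 < lo <= rr <= hi):
            raise PriorError("rr confidence interval must bracket the point estimate")
        se_log = (math.log(hi) - math.log(lo)) / (2.0 * 1.959963984540054) if hi > lo else 0.0
        sd = baseline_lifetime * rr * se_log  # delta method through r = b * rr
    else:
        sd = 0.25 * mean
    sd = max(sd, 1e-4)
    shapes = _beta_shapes_from_moments(mean, sd * sd)
    return replace(base, gamma_shapes=shapes)


def _quartile_ages_from_points(points, lifetime: float) -> tuple[float, float]:
    ages = np.array([a for a, _ in points], dtype=float)
    risks = np.array([r for _, r in points], dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise PriorError("risk-point ages must be strictly increasing")
    if np.any(np.diff(risks) < 0) or np.any(risks < 0) or np.any(risks > 1):
        raise PriorError("risk points must be a nondecreasing cumulative risk in [0,1]")
    norm = risks / lifetime
    ages_ext = np.concatenate([[0.0], ages])
    norm_ext = np.concatenate([[0.0], norm])
    if norm[-1] < 0.5:
        raise PriorError("risk points never reach half of the lifetime risk")
    q1_age = float(np.interp(0.25, norm_ext, ages_ext))
    med_age = float(np.interp(0.5, norm_ext, ages_ext))
    return q1_age, med_age


def elicit_from_risk_points(
    rs: RiskSummary,
    base: PriorSet | None = None,
    max_age: int = DEFAULT_MAX_AGE,
    max_ess: float = 1e3,
) -> PriorSet:
    """Quartile-age and asymptote priors from age-specific risk points.

    The reported quartile ages become the prior means of q1 and med under
    the sequential scaling (so the unconditional prior mean of the scaled
    quantile equals the reported age exactly); the Beta effective sample
    size equals the study size, floored at the default's and capped at
    ``max_ess``.  The asymptote prior is centered at the lifetime risk with
    binomial uncertainty at the study size.
    """
    base = base or default_priors()
    if rs.risk_points is None or len(rs.risk_points) < 2:
        raise PriorError("need at least two (age, cumulative risk) points")
    n = rs.n_subjects if rs.n_subjects is not None else 1.0
    terminal = max(r for _, r in rs.risk_points)
    lifetime = rs.lifetime_risk if rs.lifetime_risk is not None else min(2.0 * terminal, 0.99)
    q1_age, med_age = _quartile_ages_from_points(rs.risk_points, lifetime)
    if not (0 < q1_age < med_age < max_age):
        raise PriorError("elicited quartile ages out of range")

    lo, hi = base.delta_bounds
    delta_mean = 0.5 * (lo + hi)
    mean_b1 = (q1_age - delta_mean) / (max_age - delta_mean)
    if not (0.0 < mean_b1 < 1.0):
        raise PriorError("first-quartile age incompatible with threshold prior")
    mean_b2 = (med_age - q1_age) / (max_age - q1_age)
    if not (0.0 < mean_b2 < 1.0):
        raise PriorError("median age incompatible with first-quartile age")

    def shapes(mean, default_shapes):
        default_ess = sum(default_shapes)
        ess = float(np.clip(n, default_ess, max_ess))
        return (mean * ess, (1.0 - mean) * ess)

    gamma_var = lifetime * (1.0 - lifetime) / max(n, sum(base.gamma_shapes))
    return replace(
        base,
        q1_shapes=shapes(mean_b1, base.q1_shapes),
        med_shapes=shapes(mean_b2, base.med_shapes),
        gamma_shapes=_beta_shapes_from_moments(lifetime, gamma_var),
    )


def prior_component_sd(ps: PriorSet, max_age: int = DEFAULT_MAX_AGE) -> np.ndarray:
    """Approximate marginal prior standard deviations of (q1, med, gamma, delta).

    Used to scale the initial MCMC proposal covariance; computed from the
    component Beta/Uniform variances at the mean threshold.
    """
    lo, hi = ps.delta_bounds
    delta_sd = (hi - lo) / math.sqrt(12.0)
    delta_mean = 0.5 * (lo + hi)

    def beta_stats(shapes):
        a, b = shapes
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return m, math.sqrt(v)

    m1, s1 = beta_stats(ps.q1_shapes)
    span1 = max_age - delta_mean
    q1_sd = s1 * span1
    q1_mean = delta_mean + m1 * span1
    _, s2 = beta_stats(ps.med_shapes)
    span2 = max_age - q1_mean
    med_sd = s2 * span2
    _, sg = beta_stats(ps.gamma_shapes)
    return np.array([q1_sd, med_sd, sg, delta_sd])
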