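"""Parameterize and sample the distributions assigned to model parameters.

Resource quantities are gamma distributed.  The printed 95% CIs of every
strictly positive quantity in the source elicitation are consistent with a
single coefficient of variation of 0.4 (gamma shape 1/0.4**2 = 6.25), so
that CV is the default parameterization when only a mean is known; when a
CI is declared, the shape is recovered by a 1-D fit of the 2.5%/97.5%
quantiles with the mean held exact.  Probabilities are beta distributed
(moment-matched from mean and standard deviation), on-demand events are
Bernoulli, and ``fixed`` parameters are degenerate point masses.

Reproducibility: every parameter draws from its own substream derived from
a master seed and the parameter *name* (SHA-256), so adding or removing a
parameter never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .config import UncertainQuantity
from .errors import DomainError, FitError

#: Default coefficient of variation for gamma-distributed resource quantities.
DEFAULT_CV = 0.4

#: Beta sd convention: sd = min(DEFAULT_CV * mean, BETA_SD_SAFETY * feasibility bound).
BETA_SD_SAFETY = 0.95


@dataclass(frozen=True)
class FittedDistribution:
    """A distribution ready to sample, with its provenance.

    ``params`` is family-specific: gamma ``(shape, scale)``, beta
    ``(alpha, beta)``, bernoulli ``(p,)``, uniform ``(lo, hi)``, fixed
    ``(value,)``.
    """

    family: str
    params: tuple[float, ...]
    source_mean: float
    source_ci: tuple[float, float] | None = None
    fit_residual: float = 0.0

    def _frozen(self):
        if self.family == "gamma":
            shape, scale = self.params
            return stats.gamma(shape, scale=scale)
        if self.family == "beta":
            a, b = self.params
            return stats.beta(a, b)
        if self.family == "bernoulli":
            return stats.bernoulli(self.params[0])
        if self.family == "uniform":
            lo, hi = self.params
            return stats.uniform(lo, hi - lo)
        raise DomainError(f"no scipy counterpart for family '{self.family}'")

    @property
    def mean(self) -> float:
        if self.family == "gamma":
            return self.params[0] * self.params[1]
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "bernoulli":
            return self.params[0]
        if self.family == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return self.params[0]

    def quantile(self, p):
        if self.family == "fixed":
            return np.full_like(np.asarray(p, dtype=float), self.params[0])
        return self._frozen().ppf(p)

    def cdf(self, x):
        if self.family == "fixed":
            return np.where(np.asarray(x, dtype=float) >= self.params[0], 1.0, 0.0)
        return self._frozen().cdf(x)

    def ci95(self) -> tuple[float, float]:
        """Central 95% interval implied by the fitted parameters."""
        if self.family == "fixed":
            return (self.params[0], self.params[0])
        lo, hi = self._frozen().ppf([0.025, 0.975])
        return (float(lo), float(hi))


def gamma_from_mean_cv(mean: float, cv: float) -> FittedDistribution:
    """Gamma with the given mean and coefficient of variation.

    shape = 1/cv**2, scale = mean*cv**2, so shape*scale == mean exactly.
    """
    if mean <= 0 or cv <= 0:
        raise DomainError(f"mean and cv must be positive, got mean={mean}, cv={cv}")
    shape = cv ** -2
    return FittedDistribution("gamma", (shape, mean / shape), mean)


def fit_shape_to_quantiles(mean: float, ci_low: float, ci_high: float) -> FittedDistribution:
    """Gamma with exact mean whose 2.5%/97.5% quantiles best match a CI.

    The shape is found by minimizing the summed squared relative quantile
    errors over log-shape (scale = mean/shape keeps the mean exact).  A
    zero lower bound is handled by scaling that residual by the mean
    instead, which drives the fit toward shapes below 1 (density unbounded
    at zero).
    """
    if mean <= 0:
        raise DomainError(f"mean must be positive, got {mean}")
    if not (ci_low < ci_high) or ci_low < 0:
        raise DomainError(f"require 0 <= ci_low < ci_high, got ({ci_low}, {ci_high})")
    if not (ci_low <= mean <= ci_high):
        raise DomainError(f"mean {mean} outside CI ({ci_low}, {ci_high})")

    lo_scale = ci_low if ci_low > 1e-9 * mean else mean

    def objective(log_shape: float) -> float:
        shape = math.exp(log_shape)
        q = stats.gamma.ppf([0.025, 0.975], shape, scale=mean / shape)
        return ((q[0] - ci_low) / lo_scale) ** 2 + ((q[1] - ci_high) / ci_high) ** 2

    result = optimize.minimize_scalar(
        objective, bounds=(math.log(1e-4), math.log(1e6)), method="bounded",
        options={"xatol": 1e-10},
    )
    if not result.success:  # pragma: no cover - bounded search rarely fails
        raise FitError(f"gamma shape fit failed for mean={mean}, ci=({ci_low}, {ci_high})")
    shape = math.exp(result.x)
    return FittedDistribution(
        "gamma", (shape, mean / shape), mean,
        source_ci=(ci_low, ci_high), fit_residual=float(result.fun),
    )


def beta_from_mean_sd(mean: float, sd: float) -> FittedDistribution:
    """Beta moment-matched to a mean and standard deviation.

    alpha = mean*nu, beta = (1-mean)*nu with nu = mean(1-mean)/sd**2 - 1;
    the mean is preserved exactly.  Raises when sd**2 >= mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise DomainError(f"mean must be a probability strictly inside (0, 1), got {mean}")
    if sd <= 0:
        raise DomainError(f"sd must be positive, got {sd}")
    bound = math.sqrt(mean * (1.0 - mean))
    if sd >= bound:
        raise DomainError(
            f"infeasible sd {sd} for beta with mean {mean}: "
            f"requires sd < sqrt(mean*(1-mean)) = {bound:.6g}"
        )
    nu = mean * (1.0 - mean) / sd ** 2 - 1.0
    return FittedDistribution("beta", (mean * nu, (1.0 - mean) * nu), mean)


def beta_default_sd(mean: float) -> float:
    """The package's beta sd convention (mirrors the gamma CV of 0.4)."""
    return min(DEFAULT_CV * mean, BETA_SD_SAFETY * math.sqrt(mean * (1.0 - mean)))


def bernoulli_dist(p: float) -> FittedDistribution:
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"bernoulli probability outside [0, 1]: {p}")
    return FittedDistribution("bernoulli", (p,), p)


def uniform_dist(lo: float, hi: float) -> FittedDistribution:
    if not lo < hi:
        raise DomainError(f"uniform requires lo < hi, got ({lo}, {hi})")
    return FittedDistribution("uniform", (lo, hi), 0.5 * (lo + hi), source_ci=(lo, hi))


def fixed_dist(value: float) -> FittedDistribution:
    return FittedDistribution("fixed", (value,), value)


def fit_parameter(param: UncertainQuantity, cv: float = DEFAULT_CV) -> FittedDistribution:
    """Assign the sampling distribution for one configured parameter.

    gamma: fitted to the declared CI when present, else the default-CV
    parameterization; beta: mean with the package sd convention;
    bernoulli/uniform/fixed: direct.  Degenerate means (0, or 0/1 for
    probabilities) collapse to point masses.
    """
    if param.dist == "fixed":
        return fixed_dist(param.mean)
    if param.dist == "gamma":
        if param.mean == 0:
            return fixed_dist(0.0)
        if param.has_ci and param.ci_low < param.ci_high:
            return fit_shape_to_quantiles(param.mean, param.ci_low, param.ci_high)
        return gamma_from_mean_cv(param.mean, cv)
    if param.dist == "beta":
        if param.mean in (0.0, 1.0):
            return fixed_dist(param.mean)
        return beta_from_mean_sd(param.mean, beta_default_sd(param.mean))
    if param.dist == "bernoulli":
        return bernoulli_dist(param.mean)
    if param.dist == "uniform":
        return uniform_dist(param.ci_low, param.ci_high)
    raise DomainError(f"unknown distribution family '{param.dist}'")  # pragma: no cover


def parameter_rng(master_seed: int, name: str) -> np.random.Generator:
    """Deterministic per-parameter substream, keyed by parameter name."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def sample(dist: FittedDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. values; identical stream state gives identical draws."""
    if n < 1:
        raise DomainError(f"sample size must be >= 1, got {n}")
    if dist.family == "fixed":
        return np.full(n, dist.params[0], dtype=float)
    if dist.family == "gamma":
        shape, scale = dist.params
        return rng.gamma(shape, scale, size=n)
    if dist.family == "beta":
        a, b = dist.params
        return rng.beta(a, b, size=n)
    if dist.family == "bernoulli":
        return rng.binomial(1, dist.params[0], size=n).astype(float)
    if dist.family == "uniform":
        lo, hi = dist.params
        return rng.uniform(lo, hi, size=n)
    raise DomainError(f"unknown distribution family '{dist.family}'")  # pragma: no cover
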