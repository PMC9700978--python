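"""The Bayesian unknown change-point (BUCP) probability model.

A single-case AB series y_1..y_n is modelled as a level shift at an unknown
discrete change point CP with AR(1)-correlated normal errors:

    y_t = beta11 + e_t   for t < CP        (phase A intercept)
    y_t = beta21 + e_t   for t >= CP       (phase B intercept)
    e_t = rho * e_{t-1} + eps_t,  eps_t ~ Normal(0, sigma^2)

CP is a discrete index between observations, matching the weekly sampling
of the outcome; its posterior mean can still be non-integer because it
averages over the discrete posterior.  The likelihood is the exact
stationary Gaussian AR(1) density: the first residual carries the marginal
variance sigma^2 / (1 - rho^2) and each later residual is conditionally
Normal(rho * e_{t-1}, sigma^2).  A conditional-on-first-observation variant
is available for sensitivity checks.

Priors (the model is agnostic; these are weakly-informative defaults on
the outcome's own scale): both intercepts Normal(mean(y), (10*sd(y))^2),
sigma Uniform(0, 5*sd(y)), and CP discrete-uniform over its support — every
onset index that leaves at least ``min_per_phase`` (default 3) observations
in each phase.

The autocorrelation prior is Normal(0, 0.2^2) truncated to (-1, 1) by
default rather than Uniform(-1, 1).  Eighteen weekly observations carry
almost no information about rho, and under a flat prior substantial
posterior mass sits near |rho| = 1, where a near-random-walk error process
can mimic any level shift and the phase intercepts lose identification.
Shrinking rho toward independence encodes the design assumption that
week-to-week carry-over in a stable trait rating is modest; set
``rho_sd=None`` to recover the flat Uniform(-1, 1) prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .abcds import ABSeries, MIN_PER_PHASE
from .errors import ValidationError

_LOG_2PI = math.log(2.0 * math.pi)


def cp_support(n: int, min_per_phase: int = MIN_PER_PHASE) -> np.ndarray:
    """All admissible change-point (onset) indices for a length-n series.

    An index t is admissible when phase A keeps ``t >= min_per_phase``
    points and phase B keeps ``n - t >= min_per_phase`` points.
    """
    if min_per_phase < 1:
        raise ValidationError("min_per_phase must be >= 1")
    if n < 2 * min_per_phase:
        raise ValidationError(
            f"series of length {n} cannot hold {min_per_phase} points per phase"
        )
    return np.arange(min_per_phase, n - min_per_phase + 1)


@dataclass(frozen=True)
class BucpParams:
    """One point in the BUCP parameter space."""

    beta11: float
    beta21: float
    sigma: float
    rho: float
    cp: int

    def validate(self, n: int, min_per_phase: int = MIN_PER_PHASE) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if not (-1.0 < self.rho < 1.0):
            raise ValidationError(f"rho must be in (-1, 1), got {self.rho}")
        if not (min_per_phase <= self.cp <= n - min_per_phase):
            raise ValidationError(f"cp={self.cp} outside support for n={n}")


@dataclass(frozen=True)
class BucpPriors:
    """Hyperparameters of the independent priors.

    Both intercepts share a Normal(beta_mean, beta_sd^2) prior; sigma is
    Uniform(0, sigma_upper); rho is Normal(0, rho_sd^2) truncated to
    (-1, 1), or Uniform(-1, 1) when ``rho_sd`` is None; CP is
    discrete-uniform over :func:`cp_support`.
    """

    beta_mean: float
    beta_sd: float
    sigma_upper: float
    rho_sd: Optional[float] = 0.2
    min_per_phase: int = MIN_PER_PHASE

    def __post_init__(self) -> None:
        if self.beta_sd <= 0:
            raise ValidationError("beta_sd must be > 0")
        if self.sigma_upper <= 0:
            raise ValidationError("sigma_upper must be > 0")
        if self.rho_sd is not None and self.rho_sd <= 0:
            raise ValidationError("rho_sd must be > 0 or None")

    def log_prior_rho(self, rho: float) -> float:
        """Log prior density of the autocorrelation at ``rho``."""
        if not (-1.0 < rho < 1.0):
            return -math.inf
        if self.rho_sd is None:
            return -math.log(2.0)
        z = rho / self.rho_sd
        mass = 2.0 * norm.cdf(1.0 / self.rho_sd) - 1.0  # truncation to (-1, 1)
        return -0.5 * (_LOG_2PI + z * z) - math.log(self.rho_sd) - math.log(mass)

    @classmethod
    def default_for(cls, series: ABSeries, min_per_phase: int = MIN_PER_PHASE) -> "BucpPriors":
        """Weakly-informative defaults on the series' own scale."""
        y = series.values
        sd = float(np.std(y, ddof=1))
        if sd == 0.0:
            sd = 1.0  # flat series still needs a proper prior scale
        return cls(
            beta_mean=float(np.mean(y)),
            beta_sd=10.0 * sd,
            sigma_upper=5.0 * sd,
            min_per_phase=min_per_phase,
        )


def phase_means(n: int, cp: int, beta11: float, beta21: float) -> np.ndarray:
    """Step mean function mu_t: beta11 before cp, beta21 from cp on."""
    return np.where(np.arange(n) < cp, beta11, beta21)


def log_likelihood(
    series: ABSeries,
    params: BucpParams,
    stationary: bool = True,
) -> float:
    """Exact Gaussian AR(1) log-likelihood of the series under ``params``.

    With ``stationary`` (default) the first residual uses the marginal
    variance sigma^2/(1-rho^2); otherwise the likelihood conditions on the
    first observation (its factor is dropped).

    Raises
    ------
    ValidationError
        If sigma <= 0 or |rho| >= 1.
    """
    if params.sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {params.sigma}")
    if not (-1.0 < params.rho < 1.0):
        raise ValidationError(f"rho must be in (-1, 1), got {params.rho}")
    y = series.values
    n = len(y)
    e = y - phase_means(n, params.cp, params.beta11, params.beta21)
    sig2 = params.sigma**2
    rho = params.rho
    u = e[1:] - rho * e[:-1]
    ll = -0.5 * (n - 1) * (_LOG_2PI + math.log(sig2)) - float(u @ u) / (2.0 * sig2)
    if stationary:
        v0 = sig2 / (1.0 - rho**2)
        ll += -0.5 * (_LOG_2PI + math.log(v0)) - e[0] ** 2 / (2.0 * v0)
    return ll


def log_prior(params: BucpParams, priors: BucpPriors, n: int) -> float:
    """Sum of independent log prior densities; -inf outside support."""
    support = cp_support(n, priors.min_per_phase)
    if params.sigma <= 0 or params.sigma >= priors.sigma_upper:
        return -math.inf
    if not (-1.0 < params.rho < 1.0):
        return -math.inf
    if params.cp not in support:
        return -math.inf
    lp = 0.0
    for b in (params.beta11, params.beta21):
        z = (b - priors.beta_mean) / priors.beta_sd
        lp += -0.5 * (_LOG_2PI + z * z) - math.log(priors.beta_sd)
    lp += -math.log(priors.sigma_upper)  # Uniform(0, upper)
    lp += priors.log_prior_rho(params.rho)
    lp += -math.log(len(support))        # discrete uniform over cp support
    return lp


def log_posterior(
    series: ABSeries,
    params: BucpParams,
    priors: BucpPriors,
    stationary: bool = True,
) -> float:
    """Unnormalized log posterior density."""
    lp = log_prior(params, priors, series.n)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(series, params, stationary=stationary)
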