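"""Brute-force reference posteriors for small change-point instances.

These routines are deliberately independent of the MCMC code path: they are
the correctness gate the sampler is tested against.

:func:`enumerate_cp_posterior` is exact (up to sigma quadrature) for the
rho = 0 model: with independent errors the likelihood factorizes across
phases, the normal intercept priors are conjugate, so each phase's
intercept integrates out in closed form (the phase marginal is multivariate
normal with covariance sigma^2 I + beta_sd^2 J), and only sigma is
integrated numerically over its Uniform(0, upper) prior.

:func:`grid_posterior_mean` covers the full parameter space (including
rho != 0) with a dense-grid quadrature of the joint posterior; coarser, but
applicable where conjugacy is lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .abcds import ABSeries, MIN_PER_PHASE
from .errors import ValidationError
from .model import BucpPriors, cp_support

_LOG_2PI = np.log(2.0 * np.pi)

MAX_GRID_POINTS = 10_000_000


def _phase_marginal_loglik(
    v: np.ndarray, m0: float, s0sq: float, sigma: np.ndarray
) -> np.ndarray:
    """log p(v | sigma) with the phase intercept integrated out.

    v are the k phase observations; intercept prior Normal(m0, s0sq);
    errors iid Normal(0, sigma^2).  Vectorized over a sigma grid.
    Uses the rank-one structure sigma^2 I + s0sq J (Sherman-Morrison).
    """
    k = len(v)
    d = v - m0
    s1 = float(d.sum())
    s2 = float(d @ d)
    sig2 = sigma**2
    logdet = k * np.log(sig2) + np.log1p(k * s0sq / sig2)
    quad = s2 / sig2 - (s0sq / (sig2 * (sig2 + k * s0sq))) * s1**2
    return -0.5 * (k * _LOG_2PI + logdet + quad)


def enumerate_cp_posterior(
    series: ABSeries,
    priors: BucpPriors,
    n_sigma: int = 400,
    min_per_phase: int = MIN_PER_PHASE,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact rho = 0 change-point posterior by enumeration.

    For every admissible onset index the intercepts are integrated out
    analytically and sigma numerically (midpoint rule over its uniform
    prior).  Returns ``(support, probabilities)``; the probabilities sum
    to 1 up to floating error.
    """
    support = cp_support(series.n, min_per_phase)
    y = series.values
    s0sq = priors.beta_sd**2
    # midpoint grid over the Uniform(0, sigma_upper) prior
    edges = np.linspace(0.0, priors.sigma_upper, n_sigma + 1)
    sigma = 0.5 * (edges[:-1] + edges[1:])
    log_post = np.empty(len(support))
    for i, cp in enumerate(support):
        la = _phase_marginal_loglik(y[:cp], priors.beta_mean, s0sq, sigma)
        lb = _phase_marginal_loglik(y[cp:], priors.beta_mean, s0sq, sigma)
        # uniform sigma prior: equal midpoint weights cancel on normalization
        log_post[i] = logsumexp(la + lb)
    log_post -= logsumexp(log_post)
    return support, np.exp(log_post)


@dataclass(frozen=True)
class GridSpec:
    """Finite evaluation grids for the full-posterior quadrature."""

    beta11: np.ndarray
    beta21: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    cp: np.ndarray

    @property
    def total_points(self) -> int:
        return (
            len(self.beta11) * len(self.beta21) * len(self.sigma)
            * len(self.rho) * len(self.cp)
        )

    @classmethod
    def default_for(
        cls,
        series: ABSeries,
        priors: BucpPriors,
        n_beta: int = 81,
        n_sigma: int = 48,
        rho_values: tuple[float, ...] = (0.0,),
        min_per_phase: int = MIN_PER_PHASE,
    ) -> "GridSpec":
        y = series.values
        sd = float(np.std(y, ddof=1)) or 1.0
        beta = np.linspace(y.min() - 3.0 * sd, y.max() + 3.0 * sd, n_beta)
        sigma = np.linspace(sd / 20.0, min(priors.sigma_upper, 4.0 * sd), n_sigma)
        return cls(
            beta11=beta,
            beta21=beta.copy(),
            sigma=sigma,
            rho=np.asarray(rho_values, dtype=float),
            cp=cp_support(series.n, min_per_phase),
        )


def grid_posterior(
    series: ABSeries,
    priors: BucpPriors,
    grid: GridSpec,
    stationary: bool = True,
) -> dict:
    """Dense-grid quadrature of the joint BUCP posterior.

    Returns a dict with posterior ``means`` and ``sds`` per parameter and
    the marginal change-point pmf ``cp_pmf`` over ``grid.cp``.  Raises on
    grids above ``MAX_GRID_POINTS`` evaluations.
    """
    if grid.total_points > MAX_GRID_POINTS:
        raise ValidationError(
            f"grid of {grid.total_points} points exceeds {MAX_GRID_POINTS}"
        )
    y = series.values
    n = len(y)
    b1 = grid.beta11[:, None, None]   # (B1, 1, 1)
    b2 = grid.beta21[None, :, None]   # (1, B2, 1)
    sig = grid.sigma[None, None, :]   # (1, 1, S)
    sig2 = sig**2
    # normal log-priors for the intercepts; flat terms cancel on normalization
    lp_b = (
        -0.5 * ((grid.beta11 - priors.beta_mean) / priors.beta_sd) ** 2
    )
    lp_b2 = (
        -0.5 * ((grid.beta21 - priors.beta_mean) / priors.beta_sd) ** 2
    )
    shape = (len(grid.cp), len(grid.rho), len(grid.beta11), len(grid.beta21), len(grid.sigma))
    log_post = np.empty(shape)
    t = np.arange(n)
    for ic, cp in enumerate(grid.cp):
        xa = (t < cp).astype(float)
        xb = 1.0 - xa
        for ir, rho in enumerate(grid.rho):
            s1mr2 = np.sqrt(1.0 - rho**2)
            def whiten(v: np.ndarray) -> np.ndarray:
                w = np.empty(n)
                w[0] = (s1mr2 if stationary else 0.0) * v[0]
                w[1:] = v[1:] - rho * v[:-1]
                return w
            xaw, xbw, yw = whiten(xa), whiten(xb), whiten(y)
            c_yy = yw @ yw
            a1, b1p = xaw @ yw, xbw @ yw
            a2, b2p, ab = xaw @ xaw, xbw @ xbw, xaw @ xbw
            ss = (
                c_yy
                - 2.0 * b1 * a1 - 2.0 * b2 * b1p
                + b1**2 * a2 + b2**2 * b2p
                + 2.0 * b1 * b2 * ab
            )  # (B1, B2, 1)
            n_eff = n if stationary else n - 1
            ll = -n_eff * np.log(sig) - ss / (2.0 * sig2)
            if stationary:
                ll = ll + 0.5 * np.log1p(-rho**2)
            ll = ll + priors.log_prior_rho(float(rho))
            log_post[ic, ir] = ll + lp_b[:, None, None] + lp_b2[None, :, None]
    flat = log_post.reshape(-1)
    w = np.exp(flat - flat.max())
    w /= w.sum()
    w = w.reshape(shape)

    def _marg(axis: int, values: np.ndarray) -> tuple[float, float]:
        axes = tuple(i for i in range(5) if i != axis)
        pmf = w.sum(axis=axes)
        mean = float(pmf @ values)
        var = float(pmf @ (values - mean) ** 2)
        return mean, np.sqrt(var)

    names = ("cp", "rho", "beta11", "beta21", "sigma")
    value_grids = (grid.cp.astype(float), grid.rho, grid.beta11, grid.beta21, grid.sigma)
    means, sds = {}, {}
    for axis, (name, vals) in enumerate(zip(names, value_grids)):
        means[name], sds[name] = _marg(axis, vals)
    cp_pmf = w.sum(axis=(1, 2, 3, 4))
    return {"means": means, "sds": sds, "cp_pmf": cp_pmf, "support": grid.cp}


def grid_posterior_mean(
    series: ABSeries,
    priors: BucpPriors,
    grid: GridSpec | None = None,
    stationary: bool = True,
) -> dict[str, float]:
    """Approximate posterior means of all parameters by grid quadrature."""
    if grid is None:
        grid = GridSpec.default_for(series, priors)
    return grid_posterior(series, priors, grid, stationary=stationary)["means"]
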