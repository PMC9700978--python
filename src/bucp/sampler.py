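"""Multi-chain MCMC for the BUCP model.

One Gibbs-style sweep updates, in order:

1. **CP** by an exact draw from its full conditional: the support is
   enumerated, the conditional (likelihood x uniform prior) normalized, and
   a categorical sample taken.  This makes the change point mix in one step.
2. **(beta11, beta21)** jointly by a conjugate bivariate-normal draw.  The
   AR(1) model is whitened (first row scaled by sqrt(1-rho^2), later rows
   differenced with lag weight rho), after which the intercepts form an
   ordinary normal-normal conjugate regression.
3. **sigma** by random-walk Metropolis on the log scale (Uniform(0, upper)
   prior, with the log-scale Jacobian in the acceptance ratio).
4. **rho** by random-walk Metropolis on the atanh scale (Uniform(-1, 1)
   prior; the transform's Jacobian contributes log(1 - rho^2)).

Proposal step sizes adapt toward a 0.44 acceptance rate during burn-in only
and are frozen afterwards, preserving detailed balance for the retained
draws.  Chains start overdispersed: intercepts at phase sample means plus
jitter, sigma at the sample SD times a cycling dispersion factor, rho
cycling over {-0.5, 0, 0.5, 0.25}, and the change point spread across its
support.  The master seed expands into independent per-chain substreams
through SeedSequence spawn keys.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .abcds import ABSeries, MIN_PER_PHASE
from .errors import ValidationError
from .model import BucpParams, BucpPriors, cp_support

logger = logging.getLogger(__name__)

_SQ2PI = math.log(2.0 * math.pi)

#: acceptance-rate window outside which a tuning warning is logged
ACCEPT_WINDOW = (0.15, 0.6)


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run configuration.

    ``iterations`` counts post-burn-in draws per chain; with the defaults
    (4 chains x 30,000 draws) a run retains 120,000 draws in total.
    ``fix_rho`` pins the autocorrelation at a known value (used by the
    rho=0 oracle comparisons); ``stationary`` selects the exact stationary
    AR(1) likelihood versus conditioning on the first observation.
    """

    chains: int = 4
    iterations: int = 30_000
    burn_in: int = 5_000
    seed: int = 0
    sigma_step: float = 0.5
    rho_step: float = 0.5
    fix_rho: Optional[float] = None
    stationary: bool = True
    adapt: bool = True
    min_per_phase: int = MIN_PER_PHASE

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError("chains must be >= 2 (PSRF needs multiple chains)")
        if self.iterations < 1000:
            raise ValidationError("iterations must be >= 1000")
        if self.burn_in < 0:
            raise ValidationError("burn_in must be >= 0")


@dataclass
class PosteriorDraws:
    """Per-chain post-burn-in draws of the BUCP parameters.

    Arrays have shape (chains, iterations).  ``es`` is the derived
    standardized-mean-difference draw (beta21 - beta11) / sigma, so a
    positive value means the intervention phase sits above baseline.
    """

    beta11: np.ndarray
    beta21: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    cp: np.ndarray
    support: np.ndarray
    accept_rates: list[dict[str, float]] = field(default_factory=list)

    PARAM_NAMES = ("cp", "beta11", "beta21", "sigma", "rho", "es")

    @property
    def n_chains(self) -> int:
        return self.beta11.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.beta11.shape[1]

    @property
    def es(self) -> np.ndarray:
        return (self.beta21 - self.beta11) / self.sigma

    def chains_of(self, name: str) -> np.ndarray:
        """(chains, iterations) array for one parameter (cp as float)."""
        arr = getattr(self, name)
        return arr.astype(float) if name == "cp" else arr

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated into one 1-D draw array."""
        return self.chains_of(name).reshape(-1)

    def cp_posterior(self) -> np.ndarray:
        """Empirical posterior pmf of CP over its support."""
        counts = np.array([(self.cp == c).sum() for c in self.support], dtype=float)
        return counts / counts.sum()

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws (one row per draw) for CSV export."""
        m, n = self.beta11.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(m), n),
                "iter": np.tile(np.arange(n), m),
                "beta11": self.beta11.reshape(-1),
                "beta21": self.beta21.reshape(-1),
                "sigma": self.sigma.reshape(-1),
                "rho": self.rho.reshape(-1),
                "cp": self.cp.reshape(-1),
            }
        )


def initialize_chains(
    series: ABSeries,
    priors: BucpPriors,
    mcmc: McmcConfig,
) -> list[BucpParams]:
    """Overdispersed, deterministic per-chain starting points."""
    y = series.values
    support = cp_support(series.n, mcmc.min_per_phase)
    sd = float(np.std(y, ddof=1)) or 1.0
    mean_a = float(np.mean(series.phase_a))
    mean_b = float(np.mean(series.phase_b))
    sigma_factors = (1.0, 0.5, 2.0, 1.5)
    rho_cycle = (0.0, -0.5, 0.5, 0.25)
    starts = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed, spawn_key=(c, 0)))
        jit = rng.standard_normal(2) * 0.5 * sd
        sigma0 = min(
            max(sd * sigma_factors[c % 4], 1e-3), 0.95 * priors.sigma_upper
        )
        rho0 = mcmc.fix_rho if mcmc.fix_rho is not None else rho_cycle[c % 4]
        cp0 = int(support[round(c * (len(support) - 1) / max(mcmc.chains - 1, 1))])
        starts.append(
            BucpParams(
                beta11=mean_a + jit[0],
                beta21=mean_b + jit[1],
                sigma=sigma0,
                rho=float(rho0),
                cp=cp0,
            )
        )
    return starts


def _run_chain(
    y: np.ndarray,
    support: np.ndarray,
    priors: BucpPriors,
    mcmc: McmcConfig,
    start: BucpParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """Run one chain; returns post-burn-in draw arrays and acceptance rates."""
    n = len(y)
    k = len(support)
    stationary = mcmc.stationary
    # per-candidate phase masks, shape (k, n)
    mask_a = (np.arange(n)[None, :] < support[:, None]).astype(float)
    mask_b = 1.0 - mask_a
    cp_index = {int(c): i for i, c in enumerate(support)}

    b11, b21 = start.beta11, start.beta21
    sigma, rho = start.sigma, start.rho
    cp = int(start.cp)
    fix_rho = mcmc.fix_rho is not None

    bm, bs2 = priors.beta_mean, priors.beta_sd**2
    sig_up = priors.sigma_upper
    # truncated-normal rho prior enters the MH ratio through -rho^2/(2 sd^2);
    # the truncation constant cancels
    inv_rho_var = 0.0 if priors.rho_sd is None else 1.0 / priors.rho_sd**2

    total = mcmc.burn_in + mcmc.iterations
    out_b11 = np.empty(mcmc.iterations)
    out_b21 = np.empty(mcmc.iterations)
    out_sig = np.empty(mcmc.iterations)
    out_rho = np.empty(mcmc.iterations)
    out_cp = np.empty(mcmc.iterations, dtype=np.int64)

    sigma_step = mcmc.sigma_step
    rho_step = mcmc.rho_step
    acc_sigma = acc_rho = 0
    batch_acc_sigma = batch_acc_rho = 0
    post_acc_sigma = post_acc_rho = 0
    batch = 50

    def whitened_ss_all(b11: float, b21: float, rho: float) -> np.ndarray:
        """Whitened residual sum of squares for every candidate cp."""
        e = y[None, :] - (b11 * mask_a + b21 * mask_b)
        u = e[:, 1:] - rho * e[:, :-1]
        ss = np.einsum("ij,ij->i", u, u)
        if stationary:
            ss = ss + (1.0 - rho * rho) * e[:, 0] ** 2
        else:
            ss = ss.copy()
        return ss

    # initialization sanity: the starting state must have finite density
    ss0 = whitened_ss_all(b11, b21, rho)[cp_index[cp]]
    if not math.isfinite(ss0) or not (0 < sigma < sig_up):
        raise ValidationError(
            "non-finite likelihood at initialization; start="
            f"{start}, whitened SS={ss0}, sigma_upper={sig_up}"
        )

    for it in range(total):
        # --- CP: exact draw from its full conditional --------------------
        ss = whitened_ss_all(b11, b21, rho)
        loglik = -ss / (2.0 * sigma * sigma)
        loglik -= loglik.max()
        w = np.exp(loglik)
        csum = np.cumsum(w)
        cp_i = int(np.searchsorted(csum, rng.random() * csum[-1], side="right"))
        cp_i = min(cp_i, k - 1)
        cp = int(support[cp_i])

        # --- (beta11, beta21): conjugate bivariate-normal draw -----------
        xa = mask_a[cp_i]
        xb = mask_b[cp_i]
        s1mr2 = math.sqrt(1.0 - rho * rho) if stationary else 0.0
        xa_w = np.empty(n); xb_w = np.empty(n); y_w = np.empty(n)
        xa_w[0] = s1mr2 * xa[0]; xb_w[0] = s1mr2 * xb[0]; y_w[0] = s1mr2 * y[0]
        xa_w[1:] = xa[1:] - rho * xa[:-1]
        xb_w[1:] = xb[1:] - rho * xb[:-1]
        y_w[1:] = y[1:] - rho * y[:-1]
        inv_s2 = 1.0 / (sigma * sigma)
        paa = float(xa_w @ xa_w) * inv_s2 + 1.0 / bs2
        pbb = float(xb_w @ xb_w) * inv_s2 + 1.0 / bs2
        pab = float(xa_w @ xb_w) * inv_s2
        ha = float(xa_w @ y_w) * inv_s2 + bm / bs2
        hb = float(xb_w @ y_w) * inv_s2 + bm / bs2
        det = paa * pbb - pab * pab
        mu_a = (pbb * ha - pab * hb) / det
        mu_b = (paa * hb - pab * ha) / det
        # covariance = P^{-1}; lower Cholesky of the 2x2 inverse
        caa = pbb / det; cbb = paa / det; cab = -pab / det
        l11 = math.sqrt(caa)
        l21 = cab / l11
        l22 = math.sqrt(max(cbb - l21 * l21, 0.0))
        z1, z2 = rng.standard_normal(2)
        b11 = mu_a + l11 * z1
        b21 = mu_b + l21 * z1 + l22 * z2

        # residual cross-products for the scalar sigma/rho updates
        e = y - np.where(np.arange(n) < cp, b11, b21)
        e0sq = e[0] * e[0]
        s11 = float(e[1:] @ e[1:])
        s10 = float(e[1:] @ e[:-1])
        s00 = float(e[:-1] @ e[:-1])

        def neg_half_ss(rho_: float) -> float:
            ss_ = s11 - 2.0 * rho_ * s10 + rho_ * rho_ * s00
            if stationary:
                ss_ += (1.0 - rho_ * rho_) * e0sq
            return ss_

        # --- sigma: random-walk Metropolis on log scale ------------------
        n_eff = n if stationary else n - 1
        ss_cur = neg_half_ss(rho)
        sigma_prop = sigma * math.exp(sigma_step * rng.standard_normal())
        if 0.0 < sigma_prop < sig_up:
            # log target in log-sigma space: -n_eff*log(sigma) - ss/(2 sigma^2) + log(sigma)
            cur = -n_eff * math.log(sigma) - ss_cur / (2.0 * sigma * sigma) + math.log(sigma)
            prop = -n_eff * math.log(sigma_prop) - ss_cur / (2.0 * sigma_prop * sigma_prop) + math.log(sigma_prop)
            if math.log(rng.random()) < prop - cur:
                sigma = sigma_prop
                batch_acc_sigma += 1
                if it >= mcmc.burn_in:
                    post_acc_sigma += 1

        # --- rho: random-walk Metropolis on atanh scale ------------------
        if not fix_rho:
            z = math.atanh(rho)
            z_prop = z + rho_step * rng.standard_normal()
            rho_prop = math.tanh(z_prop)
            inv2s2 = 1.0 / (2.0 * sigma * sigma)

            def log_target_z(r: float) -> float:
                lt = -neg_half_ss(r) * inv2s2 + math.log1p(-r * r)  # Jacobian
                lt -= 0.5 * r * r * inv_rho_var  # shrinkage prior
                if stationary:
                    lt += 0.5 * math.log1p(-r * r)  # stationary variance factor
                return lt

            if math.log(rng.random()) < log_target_z(rho_prop) - log_target_z(rho):
                rho = rho_prop
                batch_acc_rho += 1
                if it >= mcmc.burn_in:
                    post_acc_rho += 1

        # --- step-size adaptation (burn-in only) -------------------------
        if mcmc.adapt and it < mcmc.burn_in and (it + 1) % batch == 0:
            delta = min(0.25, 2.0 / math.sqrt((it + 1) / batch))
            sigma_step *= math.exp(delta * (batch_acc_sigma / batch - 0.44))
            rho_step *= math.exp(delta * (batch_acc_rho / batch - 0.44))
            batch_acc_sigma = batch_acc_rho = 0

        if it >= mcmc.burn_in:
            j = it - mcmc.burn_in
            out_b11[j] = b11
            out_b21[j] = b21
            out_sig[j] = sigma
            out_rho[j] = rho
            out_cp[j] = cp

    rates = {
        "sigma": post_acc_sigma / mcmc.iterations,
        "rho": (post_acc_rho / mcmc.iterations) if not fix_rho else float("nan"),
    }
    return out_b11, out_b21, out_sig, out_rho, out_cp, rates


def sample_posterior(
    series: ABSeries,
    priors: Optional[BucpPriors] = None,
    mcmc: Optional[McmcConfig] = None,
) -> PosteriorDraws:
    """Run the multi-chain Gibbs/Metropolis sampler on one AB series.

    Deterministic given ``mcmc.seed``.  Logs a tuning warning when a
    Metropolis acceptance rate falls outside ``ACCEPT_WINDOW``.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    if priors is None:
        priors = BucpPriors.default_for(series, mcmc.min_per_phase)
    support = cp_support(series.n, mcmc.min_per_phase)
    starts = initialize_chains(series, priors, mcmc)
    y = series.values.astype(float)

    chains_out = []
    rates_out = []
    for c, start in enumerate(starts):
        rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed, spawn_key=(c, 1)))
        *arrays, rates = _run_chain(y, support, priors, mcmc, start, rng)
        chains_out.append(arrays)
        rates_out.append(rates)
        for pname, rate in rates.items():
            if not math.isnan(rate) and not (ACCEPT_WINDOW[0] <= rate <= ACCEPT_WINDOW[1]):
                logger.warning(
                    "chain %d: %s Metropolis acceptance rate %.3f outside %s; "
                    "consider retuning step sizes",
                    c, pname, rate, ACCEPT_WINDOW,
                )

    stack = [np.stack([ch[i] for ch in chains_out]) for i in range(5)]
    return PosteriorDraws(
        beta11=stack[0],
        beta21=stack[1],
        sigma=stack[2],
        rho=stack[3],
        cp=stack[4],
        support=support,
        accept_rates=rates_out,
    )
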