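"""Convergence diagnostics, posterior summaries and significance rules.

The potential scale reduction factor (PSRF) is the classic Gelman-Rubin
statistic.  With m chains of n draws each, W the mean within-chain variance
and B = n * Var(chain means) the between-chain variance,

    PSRF = sqrt( ((n - 1)/n * W + B/n) / W ).

Convergence is declared when every monitored parameter's PSRF falls below a
threshold (default 1.05).  A split-chain variant (each chain halved before
the computation) is available and is more sensitive to within-chain trends.

Two significance rules are applied to a fitted AB series:

1. the 95% credible intervals of the phase-A and phase-B intercepts must
   not overlap (closed intervals: touching counts as overlap), and
2. the 95% credible interval of the standardized mean difference
   es = (beta21 - beta11) / sigma must exclude zero.

The intervention effect is judged significant only when both hold.  Note on
the sign convention: the effect size is often written (beta11 - beta21) /
sigma_beta, but reported positive when the intervention phase exceeds
baseline; this package computes es = (beta21 - beta11) / sigma per draw so
that positive values always mean improvement, and each report carries this
footnote.  sigma_beta is taken as the residual-SD draw, which makes es a
genuine posterior distribution (mean-of-ratios) rather than a ratio of
posterior means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sampler import PosteriorDraws

PSRF_THRESHOLD = 1.05

ES_SIGN_FOOTNOTE = (
    "es computed per draw as (beta21 - beta11) / sigma (residual-SD draw): "
    "positive = intervention phase above baseline. The conventional printed "
    "equation (beta11 - beta21)/sigma_beta has the opposite sign; reported "
    "effect sizes follow the positive-equals-improvement convention."
)


def psrf(chains: np.ndarray, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor.

    Parameters
    ----------
    chains
        Array of shape (m, n): m >= 2 chains of n >= 2 draws each.
    split
        Halve each chain first (split-chain variant).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValidationError("psrf needs >= 2 chains of equal length")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half: 2 * half]])
    m, n = chains.shape
    if n < 2:
        raise ValidationError("psrf needs >= 2 draws per chain")
    means = chains.mean(axis=1)
    w = float(chains.var(axis=1, ddof=1).mean())
    b = n * float(means.var(ddof=1))
    if w == 0.0:
        # all chains constant: identical chains give the degenerate limit
        return 1.0 if b == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ci95(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval (2.5th/97.5th percentile by default).

    Uses linear interpolation between order statistics; requires >= 100
    draws so the tails are estimable.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValidationError(f"ci95 needs >= 100 draws, got {draws.size}")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def effect_size_draws(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw standardized mean difference, pooled across chains.

    es = (beta21 - beta11) / sigma for every retained draw; positive values
    mean the intervention-phase intercept exceeds baseline.
    """
    if draws.beta11.size == 0:
        raise ValidationError("empty draws")
    return draws.pooled("es")


def decide_significance(
    ci_a: tuple[float, float],
    ci_b: tuple[float, float],
    ci_es: tuple[float, float],
) -> tuple[bool, bool, bool]:
    """Apply both significance rules to three 95% credible intervals.

    Returns (ci_overlap, es_excludes_zero, significant):
    ``ci_overlap`` is True iff the closed phase intervals intersect;
    ``es_excludes_zero`` is True iff 0 lies outside the closed es interval;
    ``significant`` requires no overlap AND es excluding zero.
    """
    for name, (lo, hi) in (("A", ci_a), ("B", ci_b), ("es", ci_es)):
        if lo > hi:
            raise ValidationError(f"malformed {name} interval: lower {lo} > upper {hi}")
    ci_overlap = (ci_a[0] <= ci_b[1]) and (ci_b[0] <= ci_a[1])
    es_excludes_zero = not (ci_es[0] <= 0.0 <= ci_es[1])
    return ci_overlap, es_excludes_zero, (not ci_overlap) and es_excludes_zero


def mcse(draws: np.ndarray, n_batches: int = 30) -> float:
    """Monte-Carlo standard error of the mean by non-overlapping batch means."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    b = max(len(draws) // n_batches, 1)
    k = len(draws) // b
    if k < 2:
        raise ValidationError("too few draws for batch-means MCSE")
    means = draws[: k * b].reshape(k, b).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(k))


@dataclass(frozen=True)
class ParamSummary:
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    psrf: float

    def __post_init__(self) -> None:
        if self.ci_lower > self.ci_upper:
            raise ValidationError("interval lower > upper")


@dataclass
class FitReport:
    """Posterior summary of one BUCP fit, shaped like a results table row.

    One :class:`ParamSummary` per parameter (cp, beta11, beta21, sigma,
    rho, es); the convergence flag requires every PSRF below
    ``psrf_threshold``; the significance flag applies both credible-interval
    rules.  ``config`` echoes the priors and MCMC settings for audit.
    """

    params: dict[str, ParamSummary]
    psrf_threshold: float
    converged: bool
    ci_overlap: bool
    es_excludes_zero: bool
    significant: bool
    label: str = "score"
    config: dict = field(default_factory=dict)
    footnote: str = ES_SIGN_FOOTNOTE

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "psrf_threshold": self.psrf_threshold,
            "converged": self.converged,
            "ci_overlap": self.ci_overlap,
            "es_excludes_zero": self.es_excludes_zero,
            "significant": self.significant,
            "parameters": {
                name: {
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci95": [s.ci_lower, s.ci_upper],
                    "psrf": s.psrf,
                }
                for name, s in self.params.items()
            },
            "config": self.config,
            "footnote": self.footnote,
        }
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Summary grid (one row per parameter) for CSV export."""
        rows = [
            {
                "parameter": name,
                "mean": s.mean,
                "sd": s.sd,
                "ci_lower": s.ci_lower,
                "ci_upper": s.ci_upper,
                "psrf": s.psrf,
            }
            for name, s in self.params.items()
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Human-readable layout: Mean (SD) [95% CI] per parameter."""
        lines = [f"BUCP fit report — outcome: {self.label}", ""]
        lines.append(f"{'parameter':<8} {'Mean (SD)':>18}  {'95% Bayesian CI':>22}  {'PSRF':>6}")
        for name, s in self.params.items():
            lines.append(
                f"{name:<8} {s.mean:>10.2f} ({s.sd:.2f})  "
                f"[{s.ci_lower:>8.2f}, {s.ci_upper:>8.2f}]  {s.psrf:>6.3f}"
            )
        lines.append("")
        lines.append(f"converged (all PSRF < {self.psrf_threshold}): {self.converged}")
        lines.append(f"phase CIs overlap: {self.ci_overlap}")
        lines.append(f"es CI excludes zero: {self.es_excludes_zero}")
        lines.append(f"significant: {self.significant}")
        lines.append("")
        lines.append(f"note: {self.footnote}")
        return "\n".join(lines)


def summarize(
    draws: PosteriorDraws,
    psrf_threshold: float = PSRF_THRESHOLD,
    split_psrf: bool = False,
    label: str = "score",
    config: Optional[dict] = None,
) -> FitReport:
    """Build the full fit report from posterior draws.

    Means, SDs and credible intervals pool all chains; PSRF compares
    chains.  The significance flags apply :func:`decide_significance` to
    the phase-intercept and effect-size intervals.
    """
    params: dict[str, ParamSummary] = {}
    for name in PosteriorDraws.PARAM_NAMES:
        per_chain = draws.chains_of(name)
        pooled = per_chain.reshape(-1)
        lo, hi = ci95(pooled)
        params[name] = ParamSummary(
            mean=float(pooled.mean()),
            sd=float(pooled.std(ddof=1)),
            ci_lower=lo,
            ci_upper=hi,
            psrf=psrf(per_chain, split=split_psrf),
        )
    max_psrf = max(s.psrf for s in params.values())
    ci_a = (params["beta11"].ci_lower, params["beta11"].ci_upper)
    ci_b = (params["beta21"].ci_lower, params["beta21"].ci_upper)
    ci_es = (params["es"].ci_lower, params["es"].ci_upper)
    overlap, excludes, significant = decide_significance(ci_a, ci_b, ci_es)
    return FitReport(
        params=params,
        psrf_threshold=psrf_threshold,
        converged=max_psrf < psrf_threshold,
        ci_overlap=overlap,
        es_excludes_zero=excludes,
        significant=significant,
        label=label,
        config=config or {},
    )
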