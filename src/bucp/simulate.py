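"""Synthetic AB-design series with AR(1) errors and a known change point.

The generator produces exactly the data-generating process the change-point
model assumes: a step change in level at a known onset,

    y_t = mu_t + e_t,      mu_t = beta11 for t < cp else beta21,
    e_t = rho * e_{t-1} + eps_t,   eps_t ~ Normal(0, sigma^2),

with the initial error drawn from the stationary distribution
Normal(0, sigma^2 / (1 - rho^2)) so early observations are not artificially
precise.  Because the fitted model treats the outcome as continuous and
normal, rounding to the integer score scale is OFF by default; it is turned
on only for fixtures that must look like real integer-valued scale scores.

Three named scenarios mirror the qualitative patterns of a small AB-design
dementia study on the ABC-DS total-score scale (18 weekly points, onset at
week 10): a clear responder with a large standardized level shift, a stable
null with no shift and larger week-to-week noise, and a drifting null whose
noise is autocorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .abcds import ABSeries, SUBSCALE_RANGES, MIN_PER_PHASE
from .errors import ValidationError


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth parameters of one simulated AB series.

    ``beta11``/``beta21`` are the phase-A/phase-B levels in score units,
    ``sigma`` the innovation SD (> 0), ``rho`` the lag-1 autocorrelation
    in (-1, 1), ``cp`` the index of the first phase-B observation, and
    ``n`` the series length.
    """

    beta11: float
    beta21: float
    sigma: float
    rho: float
    cp: int
    n: int = 18

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if not (-1.0 < self.rho < 1.0):
            raise ValidationError(f"rho must be in (-1, 1), got {self.rho}")
        if self.cp < MIN_PER_PHASE or self.n - self.cp < MIN_PER_PHASE:
            raise ValidationError(
                f"cp={self.cp} leaves fewer than {MIN_PER_PHASE} points in a phase (n={self.n})"
            )


def _child_rng(seed: int, *path: int) -> np.random.Generator:
    """Deterministic substream: master seed -> spawn-key path.

    Replicate r of scenario runs uses ``_child_rng(seed, r)``; the splitting
    rule is SeedSequence spawn keys, so substreams are independent and the
    mapping from (seed, path) to stream is stable across runs.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=path))


def _draw_series(params: TrueParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n
    mu = np.where(np.arange(n) < params.cp, params.beta11, params.beta21)
    e = np.empty(n)
    innov = rng.standard_normal(n)
    # stationary start, so the first point has the marginal AR(1) variance
    e[0] = innov[0] * params.sigma / np.sqrt(1.0 - params.rho**2)
    for t in range(1, n):
        e[t] = params.rho * e[t - 1] + params.sigma * innov[t]
    return mu + e


def simulate_series(
    params: TrueParams,
    seed: int,
    round_to_scale: bool = False,
    score_range: tuple[float, float] = SUBSCALE_RANGES["total"],
    label: str = "score",
    replicate: int = 0,
) -> ABSeries:
    """Simulate one AB series from the stated AR(1) step-change process.

    Deterministic given ``seed``, ``replicate`` and ``params``.  With
    ``round_to_scale`` the values are rounded to integers and clipped to
    ``score_range`` (default: the 13-117 total-score range).
    """
    y = _draw_series(params, _child_rng(seed, replicate))
    if round_to_scale:
        y = np.clip(np.round(y), *score_range)
    return ABSeries(
        timepoints=np.arange(params.n),
        values=y,
        intervention_onset=params.cp,
        label=label,
    )


#: named study-condition scenarios (18 points, onset at index 10, on the
#: ABC-DS total-score scale)
SCENARIOS: dict[str, TrueParams] = {
    # clear responder: level shift of 4.5 points on sigma 1.2 noise, a
    # standardized phase difference of 3.75
    "responder": TrueParams(beta11=78.0, beta21=82.5, sigma=1.2, rho=0.0, cp=10, n=18),
    # stable null: no shift, week-to-week SD ~3.5 score points
    "stable_null": TrueParams(beta11=67.0, beta21=67.0, sigma=3.5, rho=0.0, cp=10, n=18),
    # drifting null: no shift, autocorrelated noise
    "drifting_null": TrueParams(beta11=85.0, beta21=85.0, sigma=3.8, rho=0.3, cp=10, n=18),
}


def scenario(
    name: str,
    seed: int,
    onset: int | None = None,
    replicate: int = 0,
) -> tuple[TrueParams, ABSeries]:
    """Generate a named scenario series; returns (truth, series).

    ``onset`` overrides the default intervention onset (index 10);
    ``replicate`` selects an independent substream of the same master seed.
    """
    if name not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    params = SCENARIOS[name]
    if onset is not None:
        params = replace(params, cp=onset)
    series = simulate_series(params, seed, replicate=replicate)
    return params, series
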