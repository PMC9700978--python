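import numpy as np
import pytest

import bucp


@pytest.fixture(scope="session")
def responder():
    """One responder-scenario draw: (truth, series)."""
    return bucp.scenario("responder", seed=11)


@pytest.fixture(scope="session")
def stable_null():
    """One stable-null-scenario draw: (truth, series)."""
    return bucp.scenario("stable_null", seed=11)


@pytest.fixture()
def small_series():
    """A tiny deterministic AB series for exact likelihood checks."""
    return bucp.ABSeries(
        timepoints=np.arange(6),
        values=np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
        intervention_onset=3,
    )


def fast_mcmc(seed: int = 0, **kwargs) -> bucp.McmcConfig:
    """Small-but-valid MCMC budget for unit tests."""
    kwargs.setdefault("chains", 4)
    kwargs.setdefault("iterations", 2000)
    kwargs.setdefault("burn_in", 500)
    return bucp.McmcConfig(seed=seed, **kwargs)
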