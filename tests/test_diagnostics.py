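"""PSRF, credible intervals, effect size, decision rules, and fit reports."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bucp
from bucp.diagnostics import (
    ES_SIGN_FOOTNOTE,
    ci95,
    decide_significance,
    effect_size_draws,
    mcse,
    psrf,
    summarize,
)
from bucp.sampler import PosteriorDraws, sample_posterior
from conftest import fast_mcmc


def make_draws(b11, b21, sigma, rho=None, cp=None):
    b11 = np.atleast_2d(np.asarray(b11, dtype=float))
    shape = b11.shape
    b21 = np.broadcast_to(np.asarray(b21, dtype=float), shape).copy()
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), shape).copy()
    rho = np.zeros(shape) if rho is None else np.broadcast_to(rho, shape).copy()
    cp = np.full(shape, 10, dtype=int) if cp is None else cp
    return PosteriorDraws(
        beta11=b11, beta21=b21, sigma=sigma, rho=rho, cp=cp,
        support=np.arange(3, 16),
    )


class TestPsrf:
    def test_identical_chains_degenerate_value(self):
        chain = np.sin(np.arange(200.0))
        chains = np.stack([chain, chain])
        n = chains.shape[1]
        # B = 0: statistic reduces to sqrt((n-1)/n)
        assert psrf(chains) == pytest.approx(math.sqrt((n - 1) / n), abs=1e-12)

    def test_separated_constant_chains_explode(self):
        chains = np.array([[0.0, 0.0, 0.0, 0.0], [10.0, 10.0, 10.0, 10.0]])
        assert psrf(chains) == math.inf
        jittered = chains + np.tile([0.01, -0.01], 2)
        assert psrf(jittered) > 3.0

    def test_direct_formula_evaluation(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 500)) + np.array([[0.0], [0.1], [0.2], [0.3]])
        m, n = chains.shape
        w = chains.var(axis=1, ddof=1).mean()
        b = n * chains.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((n - 1) / n * w + b / n) / w)
        assert psrf(chains) == pytest.approx(expected, rel=1e-12)

    def test_matches_arviz_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 1000)).cumsum(axis=1) * 0.01 + rng.normal(size=(4, 1000))
        assert psrf(chains) == pytest.approx(float(az.rhat(chains, method="identity")), rel=1e-9)
        # the split variant halves chains first and is more conservative here
        half = chains.shape[1] // 2
        split = np.concatenate([chains[:, :half], chains[:, half:]])
        assert psrf(chains, split=True) == pytest.approx(psrf(split), rel=1e-12)
        assert psrf(chains, split=True) >= psrf(chains)

    def test_single_chain_rejected(self):
        with pytest.raises(bucp.ValidationError):
            psrf(np.zeros((1, 100)))

    def test_converged_sampler_run(self, stable_null):
        _, series = stable_null
        d = sample_posterior(series, mcmc=fast_mcmc(seed=10, iterations=8000, burn_in=1000))
        for name in PosteriorDraws.PARAM_NAMES:
            assert psrf(d.chains_of(name)) < 1.05


class TestCi95:
    def test_percentile_rule_on_integers(self):
        draws = np.random.default_rng(0).permutation(np.arange(1, 1001))
        assert ci95(draws) == pytest.approx((25.975, 975.025))

    def test_constant_draws(self):
        lo, hi = ci95(np.full(500, 3.25))
        assert lo == hi == 3.25

    def test_standard_normal_large_sample(self):
        z = np.random.default_rng(42).standard_normal(100_000)
        lo, hi = ci95(z)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_too_few_draws(self):
        with pytest.raises(bucp.ValidationError, match="100"):
            ci95(np.arange(50))


class TestEffectSize:
    def test_null_identity(self):
        d = make_draws(np.full((2, 200), 70.0), 70.0, 2.0)
        assert np.all(effect_size_draws(d) == 0.0)

    def test_unit_standardization(self):
        d = make_draws([[10.0]], [[12.0]], [[2.0]])
        assert effect_size_draws(d) == pytest.approx([1.0])

    def test_posterior_mean_plug_in_scale(self):
        # ratio of posterior means at (38.91, 38.04, 2.35) ~ -0.37: the
        # per-draw posterior mean differs only by the mean-of-ratios gap
        assert (38.04 - 38.91) / 2.35 == pytest.approx(-0.37, abs=0.005)
        rng = np.random.default_rng(0)
        b11 = rng.normal(38.91, 0.83, (2, 20_000))
        b21 = rng.normal(38.04, 0.69, (2, 20_000))
        sig = rng.normal(2.35, 0.3, (2, 20_000)).clip(0.5)
        es = effect_size_draws(make_draws(b11, b21, sig))
        assert es.mean() == pytest.approx(-0.40, abs=0.08)

    def test_sign_antisymmetry_under_phase_swap(self, responder):
        _, series = responder
        d = sample_posterior(series, mcmc=fast_mcmc(seed=2))
        swapped = make_draws(d.beta21, d.beta11, d.sigma, d.rho, d.cp)
        np.testing.assert_allclose(
            effect_size_draws(swapped), -effect_size_draws(d)
        )
        lo, hi = ci95(effect_size_draws(d))
        slo, shi = ci95(effect_size_draws(swapped))
        assert (hi - lo) == pytest.approx(shi - slo, rel=1e-9)


class TestDecideSignificance:
    @pytest.mark.parametrize(
        "ci_a, ci_b, ci_es, expected",
        [
            # clear separation and es excluding zero -> significant
            ((77.52, 79.00), (81.38, 83.49), (1.47, 5.91), (False, True, True)),
            # overlapping phases and es straddling zero -> not significant
            ((64.52, 68.70), (64.88, 68.73), (-0.83, 0.95), (True, False, False)),
            # touching intervals count as overlap (closed intervals)
            ((0.0, 1.0), (1.0, 2.0), (1.0, 2.0), (True, True, False)),
            # es boundary exactly at zero counts as including zero
            ((0.0, 1.0), (2.0, 3.0), (0.0, 1.0), (False, False, False)),
        ],
    )
    def test_rule_table(self, ci_a, ci_b, ci_es, expected):
        assert decide_significance(ci_a, ci_b, ci_es) == expected

    def test_malformed_interval(self):
        with pytest.raises(bucp.ValidationError, match="malformed"):
            decide_significance((1.0, 0.0), (0.0, 1.0), (0.0, 1.0))

    @settings(max_examples=100, derandomize=True)
    @given(
        lo=st.floats(-10, 10), width=st.floats(0, 5),
        gap=st.floats(-5, 5), widen=st.floats(0, 5),
    )
    def test_widening_monotone(self, lo, width, gap, widen):
        ci_a = (lo, lo + width)
        ci_b = (lo + width + gap, lo + 2 * width + gap)
        ci_es = (1.0, 2.0)
        _, _, sig = decide_significance(ci_a, ci_b, ci_es)
        wide_a = (ci_a[0] - widen, ci_a[1] + widen)
        _, _, sig_wide = decide_significance(wide_a, ci_b, ci_es)
        assert sig or not sig_wide  # widening can only kill significance


class TestSummarize:
    def test_report_invariants(self, responder):
        _, series = responder
        d = sample_posterior(series, mcmc=fast_mcmc(seed=4))
        rep = summarize(d)
        assert set(rep.params) == set(PosteriorDraws.PARAM_NAMES)
        for name, s in rep.params.items():
            assert s.ci_lower <= s.ci_upper
            assert s.sd >= 0
            if name != "cp":  # discrete cp quantiles may exclude the mean
                assert s.ci_lower <= s.mean <= s.ci_upper
        assert rep.converged == (max(s.psrf for s in rep.params.values()) < 1.05)
        assert rep.significant == ((not rep.ci_overlap) and rep.es_excludes_zero)

    def test_es_summary_consistent_with_draws(self, responder):
        _, series = responder
        d = sample_posterior(series, mcmc=fast_mcmc(seed=4))
        rep = summarize(d)
        assert rep.params["es"].mean == pytest.approx(effect_size_draws(d).mean())

    def test_serialization_round_trip(self, responder):
        _, series = responder
        d = sample_posterior(series, mcmc=fast_mcmc(seed=4))
        rep = summarize(d, config={"mcmc": {"seed": 4}})
        parsed = json.loads(rep.to_json())
        assert parsed["significant"] == rep.significant
        assert parsed["footnote"] == ES_SIGN_FOOTNOTE
        assert parsed["config"] == {"mcmc": {"seed": 4}}
        frame = rep.to_frame()
        assert list(frame["parameter"]) == list(rep.params)
        text = rep.to_text()
        assert "95% Bayesian CI" in text and "significant" in text


class TestMcse:
    def test_iid_draws_match_analytic_se(self):
        draws = np.random.default_rng(3).standard_normal(30_000)
        assert mcse(draws) == pytest.approx(1 / math.sqrt(30_000), rel=0.35)
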