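"""Metric layer: HDI vs exhaustive search, analytic normal masses,
g-computation closed forms, and the convergence diagnostics gate."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

import krtbayes as kb
from krtbayes.samples import PosteriorDraws


def exhaustive_hdi(draws, mass):
    """Brute-force shortest window over all valid starts."""
    a = np.sort(np.asarray(draws, float))
    n = a.size
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = a[i + m - 1] - a[i]
        if best is None or w < best[0]:
            best = (w, a[i], a[i + m - 1])
    return best[1], best[2]


def make_binary_draws(theta, beta_0, covariates=(), extra=None, meta=None):
    """Assemble a PosteriorDraws object shaped like a logistic fit."""
    theta = np.asarray(theta, float)
    n = theta.size
    half = n // 2
    params = {"theta": theta[: 2 * half].reshape(2, half),
              "beta_0": np.asarray(beta_0, float)[: 2 * half].reshape(2, half)}
    if extra:
        for k, v in extra.items():
            params[k] = np.asarray(v, float)[: 2 * half].reshape(2, half)
    base_meta = {"outcome": "death90", "covariates": list(covariates)}
    if meta:
        base_meta.update(meta)
    return PosteriorDraws(params=params, meta=base_meta)


def tiny_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    death = rng.integers(0, 2, n).astype(float)
    df = pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "site_id": ["S001"] * n,
        "arm": rng.integers(0, 2, n),
        "sepsis": rng.integers(0, 2, n),
        "surgical": rng.integers(0, 2, n),
        "ckd": rng.integers(0, 2, n),
        "death90": death,
        "krt_free_days": np.zeros(n),
        "hosp_free_days": np.zeros(n),
        "survivor": 1 - death.astype(int),
        "krt_dep90": np.where(death == 0, 0.0, np.nan),
        "rehosp90": np.where(death == 0, 0.0, np.nan),
    })
    return kb.TrialDataset(df)


class TestHdi:
    def test_integer_ladder(self):
        lo, hi = kb.hdi(np.arange(100, dtype=float), 0.95)
        assert (lo, hi) == (0.0, 94.0)

    def test_point_mass(self):
        lo, hi = kb.hdi(np.full(200, 3.7), 0.95)
        assert lo == hi == 3.7

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("dist", ["normal", "lognormal", "uniform"])
    def test_matches_exhaustive_search(self, seed, dist):
        rng = np.random.default_rng(seed)
        draws = getattr(rng, dist)(size=801)
        assert kb.hdi(draws, 0.95) == exhaustive_hdi(draws, 0.95)
        assert kb.hdi(draws, 0.5) == exhaustive_hdi(draws, 0.5)

    def test_ties_resolved_to_lowest_start(self):
        draws = np.tile(np.arange(10, dtype=float), 20)  # many equal windows
        assert kb.hdi(draws, 0.9) == exhaustive_hdi(draws, 0.9)

    def test_skewed_sample_shorter_than_equal_tailed(self):
        rng = np.random.default_rng(5)
        draws = rng.lognormal(size=20_000)
        lo, hi = kb.hdi(draws, 0.95)
        eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < eq_hi - eq_lo

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            kb.hdi(np.arange(50, dtype=float), 0.95)


class TestProbDirection:
    def test_direct_count(self):
        draws = np.tile([-3.0, -2.0, -1.0, 1.0], 50)
        assert kb.prob_direction(draws) == 0.75

    def test_symmetric_sample_near_half(self, rng):
        draws = rng.normal(0, 1, 100_000)
        assert kb.prob_direction(draws) == pytest.approx(0.5, abs=0.01)

    def test_analytic_normal_mass(self, rng):
        n = 200_000
        draws = rng.normal(-0.257, 0.249, n)
        expected = norm.cdf(0.257 / 0.249)  # 0.8490
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(kb.prob_direction(draws) - expected) < 3 * se


class TestRopeFraction:
    def test_null_posterior(self, thresholds):
        assert kb.rope_fraction(np.zeros(500), thresholds) == 1.0

    def test_direct_count(self, thresholds):
        ors = np.tile([0.5, 0.9, 1.0, 1.1, 2.0], 40)
        assert kb.rope_fraction(np.log(ors), thresholds) == 0.6

    def test_analytic_normal_mass(self, thresholds, rng):
        n = 200_000
        draws = rng.normal(0.0, 0.07, n)
        expected = norm.cdf(0.18138 / 0.07) - norm.cdf(-0.18138 / 0.07)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(kb.rope_fraction(draws, thresholds) - expected) < 3 * se


class TestMarginalRiskDifference:
    def test_null_effect_exact_zero(self):
        draws = make_binary_draws(np.zeros(400), np.full(400, -0.5))
        rd = kb.marginal_risk_difference(draws, tiny_data())
        assert (rd == 0.0).all()

    def test_no_covariate_closed_form(self, rng):
        theta = rng.normal(0, 0.2, 400)
        beta0 = rng.normal(-0.3, 0.1, 400)
        draws = make_binary_draws(theta, beta0)
        rd = kb.marginal_risk_difference(draws, tiny_data())
        t2, b2 = draws.flat("theta"), draws.flat("beta_0")
        np.testing.assert_allclose(rd, expit(b2 + t2) - expit(b2), atol=1e-12)

    def test_design_effect_magnitude(self):
        draws = make_binary_draws(np.full(400, -0.257),
                                  np.full(400, logit(0.40)))
        rd = kb.marginal_risk_difference(draws, tiny_data())
        assert rd[0] == pytest.approx(-0.0598, abs=2e-4)  # 40% -> 34.0%

    def test_covariate_mismatch_rejected(self):
        draws = make_binary_draws(np.zeros(400), np.zeros(400),
                                  covariates=("frailty",))
        with pytest.raises(ValueError, match="frailty"):
            kb.marginal_risk_difference(draws, tiny_data())


class TestSummarizeEffect:
    def test_prior_only_mcid_probability(self, thresholds, rng):
        n = 200_000
        theta = rng.normal(0.0, 0.355, n)
        draws = make_binary_draws(theta, np.zeros(n))
        s = kb.summarize_effect(draws, tiny_data(), thresholds)
        expected = norm.cdf(np.log(0.84) / 0.355)  # 0.3117
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(s.p_or_below_mcid - expected) < 3 * se
        assert round(s.p_or_below_mcid, 2) == 0.31

    def test_degenerate_null_draws(self, thresholds):
        draws = make_binary_draws(np.zeros(200), np.zeros(200))
        s = kb.summarize_effect(draws, tiny_data(), thresholds)
        assert s.median_or == 1.0
        assert s.pct_in_rope == 1.0
        assert s.p_not_large == 1.0
        assert s.rope_decision == "practically_null"

    def test_benefit_complementarity(self, thresholds, rng):
        theta = rng.normal(0.05, 0.3, 4000)
        draws = make_binary_draws(theta, np.zeros(4000))
        s = kb.summarize_effect(draws, tiny_data(), thresholds)
        p_ge = np.mean(np.exp(draws.flat("theta")) >= 1.0)
        assert s.p_benefit + p_ge == pytest.approx(1.0)

    def test_chain_concatenation_invariance(self, thresholds, rng):
        theta = rng.normal(0, 0.3, 4000)
        beta0 = rng.normal(-0.2, 0.1, 4000)
        a = make_binary_draws(theta, beta0)
        # same pooled draws, different chain split order
        flipped = {k: v[::-1].copy() for k, v in a.params.items()}
        b = PosteriorDraws(params=flipped, meta=a.meta)
        sa = kb.summarize_effect(a, tiny_data(), thresholds)
        sb = kb.summarize_effect(b, tiny_data(), thresholds)
        assert sa.median_or == sb.median_or
        assert sa.hdi95_or == sb.hdi95_or
        assert sa.pct_in_rope == sb.pct_in_rope

    def test_refuses_nonconverged_without_force(self, thresholds):
        from krtbayes.samples import Diagnostics
        draws = make_binary_draws(np.zeros(200), np.zeros(200))
        draws.diagnostics = Diagnostics(
            rhat={"theta": 2.0}, ess={"theta": 10.0}, converged=False)
        with pytest.raises(RuntimeError):
            kb.summarize_effect(draws, tiny_data(), thresholds)
        kb.summarize_effect(draws, tiny_data(), thresholds, force=True)


class TestRopeDecision:
    def test_tight_null_posterior_is_practically_null(self, thresholds, rng):
        assert kb.rope_decision(rng.normal(0, 0.01, 5000), thresholds) == \
            "practically_null"

    def test_large_shifted_posterior_is_non_null(self, thresholds, rng):
        assert kb.rope_decision(rng.normal(-1.0, 0.05, 5000), thresholds) == \
            "non_null"

    def test_wide_posterior_undecided(self, thresholds, rng):
        assert kb.rope_decision(rng.normal(0, 1.0, 5000), thresholds) == \
            "undecided"


class TestDiagnostics:
    def test_iid_chains_pass_gate(self, rng):
        draws = PosteriorDraws(params={"theta": rng.normal(size=(4, 1000))})
        d = kb.compute_diagnostics(draws)
        assert d.max_rhat < 1.01
        assert d.min_ess > 3000
        assert d.converged

    def test_separated_chains_fail_gate(self):
        arr = np.stack([np.full(1000, 0.0), np.full(1000, 5.0)])
        d = kb.compute_diagnostics(PosteriorDraws(params={"theta": arr}))
        assert not d.converged
        assert d.messages  # zero-variance chains flagged, not crashed

    def test_drifting_chains_fail_rhat(self, rng):
        base = rng.normal(size=(4, 1000))
        base[0] += 3.0  # one chain in a different mode
        d = kb.compute_diagnostics(PosteriorDraws(params={"theta": base}))
        assert d.max_rhat > 1.01
        assert not d.converged

    def test_duplicating_chains_preserves_rhat(self, rng):
        arr = rng.normal(size=(2, 800))
        d1 = kb.compute_diagnostics(PosteriorDraws(params={"theta": arr}))
        d2 = kb.compute_diagnostics(PosteriorDraws(
            params={"theta": np.vstack([arr, arr])}))
        assert d1.rhat["theta"] == pytest.approx(d2.rhat["theta"], abs=1e-3)

    def test_single_chain_rejected(self, rng):
        draws = PosteriorDraws(params={"theta": rng.normal(size=(1, 1000))})
        with pytest.raises(ValueError):
            kb.compute_diagnostics(draws)

    def test_vector_parameters_expanded(self, rng):
        draws = PosteriorDraws(params={
            "theta": rng.normal(size=(2, 500)),
            "u_site": rng.normal(size=(2, 500, 3))})
        d = kb.compute_diagnostics(draws)
        assert {"theta", "u_site[0]", "u_site[1]", "u_site[2]"} == set(d.rhat)


class TestLongFormatExport:
    def test_round_trip_shape(self, rng):
        draws = PosteriorDraws(params={"theta": rng.normal(size=(2, 50)),
                                       "u_site": rng.normal(size=(2, 50, 2))})
        long = draws.to_long_frame()
        assert set(long.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(long) == 2 * 50 * 3
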