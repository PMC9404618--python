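"""Hierarchical logistic model: oracle agreement, symmetry, prior behaviour.

MCMC-based tests use short chains (structural checks) and a module-scoped
cache of fits; tolerances reflect Monte-Carlo error at those sizes.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import ks_1samp

import krtbayes as kb

pytestmark = pytest.mark.filterwarnings(
    "ignore::krtbayes.hierarchical_logistic.ConvergenceWarning")

NEUTRAL = kb.NormalPrior("neutral", 0.0, 0.355)


def one_site_bernoulli_data(n=120, seed=6):
    """Single-site, two-arm binary data for the exact-posterior oracle."""
    rng = np.random.default_rng(seed)
    arm = np.tile([0, 1], n // 2)
    death = (rng.random(n) < expit(-0.3 + 0.2 * arm)).astype(float)
    df = pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "site_id": ["S001"] * n,
        "arm": arm,
        "sepsis": 0, "surgical": 0, "ckd": 0,
        "death90": death,
        "krt_free_days": 0.0, "hosp_free_days": 0.0,
        "survivor": 1 - death.astype(int),
        "krt_dep90": np.where(death == 0, 0.0, np.nan),
        "rehosp90": np.where(death == 0, 0.0, np.nan),
    })
    return kb.TrialDataset(df)


def exact_theta_cdf(data, prior, grid_half_width=2.5):
    """Dense 2-parameter grid posterior for the one-site no-covariate model.

    Integrates the exact unnormalized posterior over the intercept to get
    the marginal CDF of theta; independent of the MCMC path.
    """
    df = data.df
    y = df["death90"].to_numpy(float)
    arm = df["arm"].to_numpy(float)
    b0 = np.linspace(-grid_half_width, grid_half_width, 601)
    th = np.linspace(-grid_half_width, grid_half_width, 1201)
    B0, TH = np.meshgrid(b0, th, indexing="ij")
    eta1 = B0 + TH  # arm 1
    eta0 = B0
    n1, d1 = arm.sum(), y[arm == 1].sum()
    n0, d0 = (1 - arm).sum(), y[arm == 0].sum()
    ll = (d1 * eta1 - n1 * np.logaddexp(0, eta1)
          + d0 * eta0 - n0 * np.logaddexp(0, eta0))
    lp = ll - 0.5 * ((TH - prior.mean) / prior.sd) ** 2 \
        - 2.0 * np.log1p(B0**2 / 18.75)  # Student-t(3, 0, 2.5) intercept
    lp -= lp.max()
    marg = np.exp(lp).sum(axis=0)
    cdf = np.cumsum(marg)
    cdf /= cdf[-1]
    return lambda x: np.interp(x, th, cdf, left=0.0, right=1.0)


@pytest.fixture(scope="module")
def small_fits(small_trial):
    """One fit per theoretical prior on the same 600-patient dataset."""
    sampler = kb.SamplerConfig(chains=2, warmup_draws=300,
                               kept_draws_per_chain=400, seed=11)
    priors = kb.build_theoretical_priors()
    return {
        label: kb.fit_binary_model(
            small_trial,
            kb.BinaryModelSpec("death90", priors[label]), sampler)
        for label in priors.labels()
    }


class TestOracleAgreement:
    def test_posterior_matches_dense_integration(self):
        """KS distance between NUTS draws and the exact grid posterior."""
        data = one_site_bernoulli_data()
        spec = kb.BinaryModelSpec("death90", NEUTRAL, covariates=(),
                                  include_sites=False)
        draws = kb.fit_binary_model(
            data, spec, kb.SamplerConfig(chains=4, warmup_draws=400,
                                         kept_draws_per_chain=1000, seed=9))
        cdf = exact_theta_cdf(data, NEUTRAL)
        ks = ks_1samp(draws.flat("theta"), cdf)
        assert ks.statistic < 0.05

    def test_reconstructed_margins_near_analytic_posterior(self, margins_data):
        """Collapsed 643/1465 vs 639/1462 margins: the neutral-prior
        posterior median OR should sit near the precision-weighted value
        ~1.007."""
        spec = kb.BinaryModelSpec("death90", NEUTRAL)
        draws = kb.fit_binary_model(
            margins_data, spec,
            kb.SamplerConfig(chains=2, warmup_draws=400,
                             kept_draws_per_chain=500, seed=13))
        med = float(np.median(np.exp(draws.flat("theta"))))
        assert med == pytest.approx(1.007, abs=0.015)


class TestSymmetryAndMonotonicity:
    def test_arm_relabelling_flips_theta(self, small_trial):
        sampler = kb.SamplerConfig(chains=2, warmup_draws=300,
                                   kept_draws_per_chain=400, seed=21)
        spec = kb.BinaryModelSpec("death90", NEUTRAL)
        a = kb.fit_binary_model(small_trial, spec, sampler)
        flipped_df = small_trial.df.copy()
        flipped_df["arm"] = 1 - flipped_df["arm"]
        b = kb.fit_binary_model(kb.TrialDataset(flipped_df), spec, sampler)
        m_a = float(np.median(a.flat("theta")))
        m_b = float(np.median(b.flat("theta")))
        assert m_a == pytest.approx(-m_b, abs=0.04)

    def test_posterior_ordering_across_priors(self, small_fits):
        med = {k: float(np.median(v.flat("theta")))
               for k, v in small_fits.items()}
        slack = 0.01  # MCMC error at these sizes
        assert med["optimistic"] <= med["neutral"] + slack
        assert med["neutral"] <= med["pessimistic"] + slack

    def test_site_effects_track_observed_site_rates(self):
        """With strong heterogeneity, posterior site intercept means should
        correlate with the sites' observed death-rate logits."""
        data = kb.generate_trial(kb.SimulationConfig(
            n_patients=2000, n_sites=8, tau_site=1.0, seed=23))
        draws = kb.fit_binary_model(
            data, kb.BinaryModelSpec("death90", NEUTRAL),
            kb.SamplerConfig(chains=2, warmup_draws=300,
                             kept_draws_per_chain=300, seed=3))
        u_mean = draws.params["u_site"].mean(axis=(0, 1))
        df = data.df
        obs = df.groupby("site_id")["death90"].mean().reindex(
            draws.meta["site_labels"])
        obs_logit = np.log(obs / (1 - obs))
        assert np.corrcoef(u_mean, obs_logit)[0, 1] > 0.7

    def test_site_label_permutation_is_immaterial(self, small_trial):
        """Relabelling sites permutes nothing the treatment posterior sees."""
        sampler = kb.SamplerConfig(chains=2, warmup_draws=250,
                                   kept_draws_per_chain=300, seed=29)
        spec = kb.BinaryModelSpec("death90", NEUTRAL)
        a = kb.fit_binary_model(small_trial, spec, sampler)
        df = small_trial.df.copy()
        labels = sorted(df["site_id"].unique())
        rng = np.random.default_rng(1)
        mapping = dict(zip(labels, rng.permutation(labels)))
        df["site_id"] = df["site_id"].map(mapping)
        b = kb.fit_binary_model(kb.TrialDataset(df), spec, sampler)
        assert float(np.median(a.flat("theta"))) == pytest.approx(
            float(np.median(b.flat("theta"))), abs=0.04)


class TestPriorPredictive:
    @pytest.mark.parametrize("label, mean, sd", [
        ("neutral", 0.0, 0.355),
        ("optimistic", -0.257, 0.249),
    ])
    def test_posterior_returns_prior(self, label, mean, sd):
        prior = kb.NormalPrior(label, mean, sd)
        draws = kb.prior_predictive_check(
            kb.BinaryModelSpec("death90", prior),
            kb.SamplerConfig(chains=2, warmup_draws=300,
                             kept_draws_per_chain=700, seed=17))
        theta = draws.flat("theta")
        ess = max(draws.diagnostics.ess["theta"], 100.0)
        assert abs(theta.mean() - mean) < 3 * sd / np.sqrt(ess)
        assert abs(theta.std() - sd) < 3 * sd / np.sqrt(2 * ess) + 0.01

    def test_degenerate_prior_pins_theta(self):
        prior = kb.NormalPrior("point", -0.257, 1e-3)
        draws = kb.prior_predictive_check(
            kb.BinaryModelSpec("death90", prior),
            kb.SamplerConfig(chains=2, warmup_draws=300,
                             kept_draws_per_chain=300, seed=19))
        assert np.allclose(draws.flat("theta"), -0.257, atol=0.02)


class TestValidation:
    def test_single_arm_rejected(self, small_trial):
        df = small_trial.df[small_trial.df.arm == 1].reset_index(drop=True)
        with pytest.raises(ValueError, match="one arm"):
            kb.fit_binary_model(kb.TrialDataset(df),
                                kb.BinaryModelSpec("death90", NEUTRAL),
                                kb.SamplerConfig(seed=1))

    def test_empty_data_rejected(self, small_trial):
        df = small_trial.df.copy()
        df["death90"] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            kb.fit_binary_model(kb.TrialDataset(df),
                                kb.BinaryModelSpec("death90", NEUTRAL),
                                kb.SamplerConfig(seed=1))

    def test_non_binary_outcome_rejected(self, small_trial):
        with pytest.raises(ValueError, match="binary"):
            kb.fit_binary_model(small_trial,
                                kb.BinaryModelSpec("krt_free_days", NEUTRAL),
                                kb.SamplerConfig(seed=1))

    def test_single_site_needs_flag(self):
        data = one_site_bernoulli_data()
        with pytest.raises(ValueError, match="site"):
            kb.fit_binary_model(data,
                                kb.BinaryModelSpec("death90", NEUTRAL),
                                kb.SamplerConfig(seed=1))

    def test_determinism_same_seed(self, small_trial):
        sampler = kb.SamplerConfig(chains=2, warmup_draws=200,
                                   kept_draws_per_chain=200, seed=77)
        spec = kb.BinaryModelSpec("death90", NEUTRAL)
        a = kb.fit_binary_model(small_trial, spec, sampler)
        b = kb.fit_binary_model(small_trial, spec, sampler)
        np.testing.assert_array_equal(a.params["theta"], b.params["theta"])
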