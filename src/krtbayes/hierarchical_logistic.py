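"""Bayesian hierarchical logistic regression for binary trial endpoints.

The model for an endpoint y (90-day mortality, or a secondary binary
endpoint) is

    logit P(y_i = 1) = beta_0 + theta * arm_i + sum_k beta_k x_ik + u_s(i)
    u_s ~ Normal(0, tau_site)

with the treatment log-odds-ratio theta carrying the elicited prior,
Normal(0, 1) regularizing priors on the binary adjusters, a weakly
informative Student-t(3, 0, 2.5) on the intercept, and a half-Student-t(3,
0, 2.5) on the site random-intercept scale tau_site.  The random intercepts
use a non-centered parameterization (u_s = tau_site * z_s, z_s ~ N(0, 1)),
the standard remedy for funnel geometry when tau_site is small.

Posterior sampling is NUTS over the joint parameter vector with analytic
gradients; diagnostics (rank-normalized split R-hat, bulk ESS) are attached
to the returned draws and a warning is emitted — not a silent success —
when the convergence gate fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._nuts import sample_nuts
from .prior_elicitation import NormalPrior
from .samples import Diagnostics, PosteriorDraws, SamplerConfig, compute_diagnostics
from .synthetic_trial import TrialDataset, complete_cases

__all__ = ["BinaryModelSpec", "fit_binary_model", "prior_predictive_check",
           "ConvergenceWarning"]

DEFAULT_COVARIATES = ("sepsis", "surgical", "ckd")

# Student-t(3, 0, 2.5): weakly informative default for logit-scale
# intercepts and for the positive half prior on tau_site
_T_NU = 3.0
_T_SCALE = 2.5


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class BinaryModelSpec:
    outcome: str
    treatment_prior: NormalPrior
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    covariate_prior_sd: float = 1.0
    include_sites: bool = True
    subset: str | None = None  # pandas query, e.g. "survivor == 1"

    def __post_init__(self) -> None:
        if self.covariate_prior_sd <= 0:
            raise ValueError("covariate_prior_sd must be positive")


def _t_logpdf_grad(x: np.ndarray | float):
    """Unnormalized Student-t(3, 0, 2.5) log density and its gradient."""
    denom = _T_NU * _T_SCALE**2 + np.square(x)
    logp = -0.5 * (_T_NU + 1) * np.log1p(np.square(x) / (_T_NU * _T_SCALE**2))
    grad = -(_T_NU + 1) * x / denom
    return np.sum(logp), grad


def _make_logp(y, arm, X, site_idx, n_sites, spec: BinaryModelSpec):
    """Joint log posterior and gradient over the flat parameter vector.

    Layout: [beta_0, theta, beta_cov..., log_tau, z_1..z_S] with the tail
    present only when sites are included.
    """
    k = X.shape[1]
    pm, ps = spec.treatment_prior.mean, spec.treatment_prior.sd
    cov_sd = spec.covariate_prior_sd
    use_sites = spec.include_sites

    def logp_grad(q):
        beta0 = q[0]
        theta = q[1]
        beta = q[2:2 + k]
        eta = beta0 + theta * arm + (X @ beta if k else 0.0)
        if use_sites:
            log_tau = q[2 + k]
            z = q[3 + k:]
            tau = np.exp(log_tau)
            eta = eta + tau * z[site_idx]
        # Bernoulli log likelihood and residual
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        r = y - expit(eta)
        grad = np.empty_like(q)
        grad[0] = np.sum(r)
        grad[1] = r @ arm
        if k:
            grad[2:2 + k] = X.T @ r
        # priors
        lp0, g0 = _t_logpdf_grad(beta0)
        ll += lp0
        grad[0] += g0
        ll += -0.5 * ((theta - pm) / ps) ** 2
        grad[1] += -(theta - pm) / ps**2
        if k:
            ll += float(-0.5 * np.sum((beta / cov_sd) ** 2))
            grad[2:2 + k] += -beta / cov_sd**2
        if use_sites:
            site_r = np.bincount(site_idx, weights=r, minlength=n_sites)
            grad[3 + k:] = tau * site_r - z
            # half-t(3, 0, 2.5) on tau with log transform Jacobian
            grad[2 + k] = (tau * float(z @ site_r)
                           - (_T_NU + 1) * tau**2 / (_T_NU * _T_SCALE**2 + tau**2)
                           + 1.0)
            ll += float(-0.5 * np.sum(z**2))
            ll += -0.5 * (_T_NU + 1) * np.log1p(tau**2 / (_T_NU * _T_SCALE**2))
            ll += log_tau
        return ll, grad

    return logp_grad


def _prepare(data: TrialDataset, spec: BinaryModelSpec):
    df = data.df
    if spec.subset is not None:
        df = df.query(spec.subset)
    needed = [spec.outcome, "arm", "site_id", *spec.covariates]
    df = TrialDataset(df.reset_index(drop=True))
    df = complete_cases(df, needed).df
    if len(df) == 0:
        raise ValueError("no complete-case rows for this endpoint")
    y = df[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError(f"outcome {spec.outcome!r} is not binary after filtering")
    arm = df["arm"].to_numpy(dtype=float)
    if len(np.unique(arm)) < 2:
        raise ValueError("treatment effect unidentifiable: only one arm present")
    X = df[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates \
        else np.empty((len(df), 0))
    sites = pd.Categorical(df["site_id"])
    site_idx = sites.codes.astype(int)
    n_sites = len(sites.categories)
    if spec.include_sites and n_sites < 2:
        raise ValueError("site random intercepts need at least 2 sites "
                         "(set include_sites=False to drop them)")
    return df, y, arm, X, site_idx, n_sites, list(sites.categories)


def _package_draws(raw, spec, n_sites, site_labels, sampler, n_obs):
    k = len(spec.covariates)
    params: dict[str, np.ndarray] = {
        "beta_0": raw[:, :, 0],
        "theta": raw[:, :, 1],
    }
    for j, cov in enumerate(spec.covariates):
        params[f"beta_{cov}"] = raw[:, :, 2 + j]
    if spec.include_sites:
        tau = np.exp(raw[:, :, 2 + k])
        params["tau_site"] = tau
        params["u_site"] = tau[:, :, None] * raw[:, :, 3 + k:]
    draws = PosteriorDraws(params=params, meta={
        "outcome": spec.outcome,
        "covariates": list(spec.covariates),
        "prior": spec.treatment_prior.to_dict(),
        "include_sites": spec.include_sites,
        "site_labels": site_labels,
        "n_obs": n_obs,
        "seed": sampler.seed,
    })
    diag = compute_diagnostics(draws)
    draws.diagnostics = diag
    if not diag.converged:
        warnings.warn(
            f"fit for {spec.outcome!r} failed the convergence gate "
            f"(max R-hat {diag.max_rhat:.4f}, min ESS {diag.min_ess:.0f})",
            ConvergenceWarning, stacklevel=3)
    return draws


def fit_binary_model(
    data: TrialDataset,
    spec: BinaryModelSpec,
    sampler: SamplerConfig,
) -> PosteriorDraws:
    """Sample the posterior of the hierarchical logistic model."""
    _, y, arm, X, site_idx, n_sites, site_labels = _prepare(data, spec)
    logp = _make_logp(y, arm, X, site_idx, n_sites, spec)
    k = X.shape[1]
    dim = 2 + k + (1 + n_sites if spec.include_sites else 0)
    q0 = np.zeros(dim)
    p_bar = float(np.clip(y.mean(), 0.01, 0.99))
    q0[0] = logit(p_bar)
    if spec.include_sites:
        q0[2 + k] = np.log(0.1)
    raw, _ = sample_nuts(
        logp, q0,
        chains=sampler.chains,
        warmup=sampler.warmup_draws,
        draws=sampler.kept_draws_per_chain,
        seed=sampler.seed,
        target_accept=sampler.target_accept,
        init_jitter=0.2,
    )
    return _package_draws(raw, spec, n_sites, site_labels, sampler, len(y))


def prior_predictive_check(
    spec: BinaryModelSpec,
    sampler: SamplerConfig,
) -> PosteriorDraws:
    """Sample with the treatment column held constant at zero.

    With every patient in the reference arm the likelihood carries no
    information about theta, so its posterior must return the prior —
    a direct check that priors flow through the sampler unchanged.
    """
    n = 64
    rng = np.random.default_rng(20_040)
    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "site_id": [f"S{1 + i % 4:03d}" for i in range(n)],
        "arm": np.zeros(n, dtype=int),
        "sepsis": rng.integers(0, 2, n),
        "surgical": rng.integers(0, 2, n),
        "ckd": rng.integers(0, 2, n),
        "death90": rng.integers(0, 2, n).astype(float),
        "krt_free_days": np.zeros(n),
        "hosp_free_days": np.zeros(n),
        "survivor": np.ones(n, dtype=int),
        "krt_dep90": np.zeros(n),
        "rehosp90": np.zeros(n),
    })
    df["survivor"] = 1 - df["death90"].astype(int)
    df.loc[df["survivor"] == 0, ["krt_dep90", "rehosp90"]] = np.nan
    check_spec = BinaryModelSpec(
        outcome="death90",
        treatment_prior=spec.treatment_prior,
        covariates=spec.covariates,
        include_sites=spec.include_sites,
    )
    data = TrialDataset(df)
    # bypass the single-arm identifiability guard: constant arm is the point
    _, y, _, X, site_idx, n_sites, site_labels = _prepare_unchecked(
        data, check_spec)
    logp = _make_logp(y, np.zeros_like(y), X, site_idx, n_sites, check_spec)
    k = X.shape[1]
    dim = 2 + k + (1 + n_sites if check_spec.include_sites else 0)
    q0 = np.zeros(dim)
    if check_spec.include_sites:
        q0[2 + k] = np.log(0.1)
    raw, _ = sample_nuts(
        logp, q0,
        chains=sampler.chains,
        warmup=sampler.warmup_draws,
        draws=sampler.kept_draws_per_chain,
        seed=sampler.seed,
        target_accept=sampler.target_accept,
        init_jitter=0.2,
    )
    return _package_draws(raw, check_spec, n_sites, site_labels, sampler, len(y))


def _prepare_unchecked(data: TrialDataset, spec: BinaryModelSpec):
    """_prepare without the two-arm guard (prior predictive only)."""
    df = complete_cases(data, [spec.outcome, "arm", "site_id",
                               *spec.covariates]).df
    y = df[spec.outcome].to_numpy(dtype=float)
    X = df[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates \
        else np.empty((len(df), 0))
    sites = pd.Categorical(df["site_id"])
    return (df, y, df["arm"].to_numpy(dtype=float), X,
            sites.codes.astype(int), len(sites.categories),
            list(sites.categories))
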