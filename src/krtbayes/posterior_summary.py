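"""Posterior effect metrics: HDI, probability of direction, ROPE, MCID.

Implements the full reporting surface for one endpoint/prior combination:
posterior median odds ratio, 95% highest density interval, probability of
benefit P(OR < 1), probability of direction, fraction of the posterior
inside the region of practical equivalence, probability the effect is not
large, MCID probabilities on both the OR and the absolute-risk scales, and
the covariate-marginalized (g-computation) absolute risk difference.

The HDI is the shortest contiguous window over the sorted draws containing
ceil(mass * N) draws, ties broken by the lowest start — a fixed convention,
since sample-based HDIs are not unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .samples import Diagnostics, PosteriorDraws, compute_diagnostics  # noqa: F401
from .prior_elicitation import ThresholdSet
from .synthetic_trial import TrialDataset

__all__ = [
    "EffectSummary", "hdi", "prob_direction", "rope_fraction",
    "rope_decision", "marginal_risk_difference", "summarize_effect",
    "compute_diagnostics", "Diagnostics",
]

_MIN_DRAWS = 100


@dataclass(frozen=True)
class EffectSummary:
    """The metric bundle reported for one endpoint under one prior."""

    median_or: float
    hdi95_or: tuple[float, float]
    p_benefit: float          # P(OR < 1)
    prob_direction: float
    pct_in_rope: float
    p_not_large: float        # P(OR inside the large-effect margin)
    p_or_below_mcid: float    # P(OR < mcid_or)
    p_absdiff_beyond_mcid: float  # P(risk difference < -mcid_abs)
    absdiff_median: float     # percentage points
    absdiff_hdi95: tuple[float, float]  # percentage points
    rope_decision: str = "undecided"

    def __post_init__(self) -> None:
        lo, hi = self.hdi95_or
        if not lo <= self.median_or <= hi:
            raise ValueError("median OR must lie inside its HDI")
        for name in ("p_benefit", "prob_direction", "pct_in_rope",
                     "p_not_large", "p_or_below_mcid", "p_absdiff_beyond_mcid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return {
            "median_or": self.median_or,
            "hdi95_or": list(self.hdi95_or),
            "p_benefit": self.p_benefit,
            "prob_direction": self.prob_direction,
            "pct_in_rope": self.pct_in_rope,
            "p_not_large": self.p_not_large,
            "p_or_below_mcid": self.p_or_below_mcid,
            "p_absdiff_beyond_mcid": self.p_absdiff_beyond_mcid,
            "absdiff_median": self.absdiff_median,
            "absdiff_hdi95": list(self.absdiff_hdi95),
            "rope_decision": self.rope_decision,
        }


def hdi(draws: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(mass * N)`` sorted draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    n = draws.size
    if n < _MIN_DRAWS:
        raise ValueError(f"hdi requires at least {_MIN_DRAWS} draws, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    m = math.ceil(mass * n)
    a = np.sort(draws)
    widths = a[m - 1:] - a[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the earliest minimum
    return float(a[i]), float(a[i + m - 1])


def prob_direction(draws: np.ndarray) -> float:
    """Posterior mass on the side of zero where the sample median lies.

    The median convention: if the median is exactly zero the positive side
    is reported (degenerate for continuous posteriors).
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < _MIN_DRAWS:
        raise ValueError(f"prob_direction requires at least {_MIN_DRAWS} draws")
    med = np.median(draws)
    if med < 0:
        return float(np.mean(draws < 0))
    return float(np.mean(draws > 0))


def rope_fraction(draws: np.ndarray, thresholds: ThresholdSet) -> float:
    """Fraction of log-OR draws strictly inside the ROPE on the OR scale."""
    draws = np.asarray(draws, dtype=float).ravel()
    lo, hi = np.log(thresholds.rope_or[0]), np.log(thresholds.rope_or[1])
    return float(np.mean((draws > lo) & (draws < hi)))


def rope_decision(draws: np.ndarray, thresholds: ThresholdSet,
                  mass: float = 0.95) -> str:
    """Optional HDI-vs-ROPE decision rule.

    'practically_null' when the HDI lies fully inside the ROPE, 'non_null'
    when fully outside, 'undecided' otherwise.
    """
    lo, hi = hdi(np.asarray(draws, dtype=float).ravel(), mass)
    r_lo, r_hi = np.log(thresholds.rope_or[0]), np.log(thresholds.rope_or[1])
    if r_lo < lo and hi < r_hi:
        return "practically_null"
    if hi < r_lo or lo > r_hi:
        return "non_null"
    return "undecided"


def marginal_risk_difference(
    draws: PosteriorDraws, data: TrialDataset
) -> np.ndarray:
    """Posterior sample of the marginal absolute risk difference.

    Per draw, averages inverse-logit predictions over every observed
    covariate row with the arm set to 1 and to 0 (random effects excluded)
    and returns the difference in event probability — marginal
    standardization / g-computation.
    """
    covs = draws.meta.get("covariates")
    if covs is None:
        raise ValueError("draws lack covariate metadata; fit with fit_binary_model")
    missing = [c for c in covs if c not in data.df.columns]
    if missing:
        raise ValueError(f"data lacks covariates {missing} used in the fit")
    needed = [draws.meta["outcome"], "arm", "site_id", *covs]
    df = data.df.loc[data.df[needed].notna().all(axis=1)]
    X = df[list(covs)].to_numpy(dtype=float) if covs else np.empty((len(df), 0))
    beta0 = draws.flat("beta_0")
    theta = draws.flat("theta")
    if covs:
        B = np.column_stack([draws.flat(f"beta_{c}") for c in covs])
        lin = X @ B.T  # rows x draws
    else:
        lin = np.zeros((max(len(df), 1), beta0.size))
    out = np.empty(beta0.size)
    chunk = 500
    for start in range(0, beta0.size, chunk):
        end = min(start + chunk, beta0.size)
        base = beta0[start:end] + lin[:, start:end]
        out[start:end] = (expit(base + theta[start:end])
                          - expit(base)).mean(axis=0)
    return out


def summarize_effect(
    draws: PosteriorDraws,
    data: TrialDataset,
    thresholds: ThresholdSet,
    force: bool = False,
) -> EffectSummary:
    """Assemble the full metric bundle from treatment log-OR draws."""
    if draws.diagnostics is not None and not draws.diagnostics.converged \
            and not force:
        raise RuntimeError(
            "draws failed the convergence gate; pass force=True to override")
    theta = draws.flat("theta")
    or_draws = np.exp(theta)
    lo, hi = hdi(or_draws, 0.95)
    rd = marginal_risk_difference(draws, data)
    rd_lo, rd_hi = hdi(rd, 0.95)
    large_lo = np.log(thresholds.large_or[0])
    large_hi = np.log(thresholds.large_or[1])
    return EffectSummary(
        median_or=float(np.median(or_draws)),
        hdi95_or=(lo, hi),
        p_benefit=float(np.mean(or_draws < 1.0)),
        prob_direction=prob_direction(theta),
        pct_in_rope=rope_fraction(theta, thresholds),
        p_not_large=float(np.mean((theta > large_lo) & (theta < large_hi))),
        p_or_below_mcid=float(
            np.mean(or_draws < thresholds.mcid_or_reporting)),
        p_absdiff_beyond_mcid=float(np.mean(rd < -thresholds.mcid_abs_diff)),
        absdiff_median=float(np.median(rd) * 100.0),
        absdiff_hdi95=(rd_lo * 100.0, rd_hi * 100.0),
        rope_decision=rope_decision(theta, thresholds),
    )
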