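"""Posterior draw containers, sampler settings and convergence diagnostics.

Convergence is gated exactly as the reanalysis prescribes: rank-normalized
split R-hat below 1.01 and bulk effective sample size above 1000, per
parameter.  Diagnostics are computed with ArviZ, whose defaults implement
those modern variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

__all__ = ["SamplerConfig", "Diagnostics", "PosteriorDraws",
           "compute_diagnostics", "RHAT_GATE", "ESS_GATE"]

RHAT_GATE = 1.01
ESS_GATE = 1000.0


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup_draws: int = 1000
    kept_draws_per_chain: int = 1000
    seed: int = 0
    target_accept: float = 0.9

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError(f"chains must be >= 2, got {self.chains}")
        if self.warmup_draws <= 0 or self.kept_draws_per_chain <= 0:
            raise ValueError("warmup_draws and kept_draws_per_chain must be positive")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError(f"target_accept must be in (0, 1), got {self.target_accept}")


@dataclass(frozen=True)
class Diagnostics:
    """Per-parameter R-hat and bulk ESS with the convergence gate applied."""

    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    messages: tuple[str, ...] = ()

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(self.ess.values())


@dataclass
class PosteriorDraws:
    """Named posterior samples indexed by chain x iteration.

    ``params`` maps a parameter name to an array of shape (chains, draws)
    for scalars or (chains, draws, k) for vector-valued parameters (site
    intercepts).  Diagnostics are attached after sampling.
    """

    params: dict[str, np.ndarray]
    diagnostics: Diagnostics | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {k: v.shape[:2] for k, v in self.params.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"inconsistent chain/draw shapes: {shapes}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of a scalar parameter pooled across chains."""
        arr = self.params[name]
        if arr.ndim != 2:
            raise ValueError(f"{name!r} is vector-valued; index it explicitly")
        return arr.reshape(-1)

    def scalar_items(self) -> dict[str, np.ndarray]:
        """Expand vector parameters into per-element named (chains, draws)."""
        out: dict[str, np.ndarray] = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                for j in range(arr.shape[2]):
                    out[f"{name}[{j}]"] = arr[:, :, j]
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: chain, iteration, parameter, value."""
        rows = []
        for name, arr in self.scalar_items().items():
            c, d = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), d),
                "iteration": np.tile(np.arange(d), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(rows, ignore_index=True)


def compute_diagnostics(draws: PosteriorDraws) -> Diagnostics:
    """Rank-normalized split R-hat and bulk ESS per scalar parameter.

    Zero-variance (stuck) chains yield undefined diagnostics; these are
    reported as non-converged with a message rather than raising.
    """
    if draws.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    messages: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in draws.scalar_items().items():
            if np.allclose(arr.var(axis=1), 0.0):
                rhat[name] = float("inf")
                ess[name] = 0.0
                messages.append(f"{name}: zero-variance chains")
                continue
            r = float(az.rhat(arr))
            e = float(az.ess(arr))
            rhat[name] = r if np.isfinite(r) else float("inf")
            ess[name] = e if np.isfinite(e) else 0.0
    converged = (max(rhat.values()) < RHAT_GATE
                 and min(ess.values()) > ESS_GATE)
    return Diagnostics(rhat=rhat, ess=ess, converged=converged,
                       messages=tuple(messages))
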