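"""Gradient-based MCMC engine: No-U-Turn sampler with windowed adaptation.

Implements multinomial NUTS over a user-supplied log-density-and-gradient
callable, with dual-averaging step-size adaptation and Stan-style windowed
estimation of a diagonal mass matrix.  All model-specific structure (data,
priors, link functions) lives in the callable; this module only integrates
Hamiltonian trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsStats", "sample_nuts"]

_MAX_DELTA_H = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class NutsStats:
    """Per-chain sampler statistics gathered during the kept draws."""

    accept_stat: np.ndarray  # (chains, draws) mean leapfrog acceptance
    treedepth: np.ndarray  # (chains, draws)
    divergent: np.ndarray  # (chains, draws) bool
    step_size: np.ndarray  # (chains,) final adapted step size
    inv_mass: np.ndarray  # (chains, dim) final diagonal inverse mass


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "lp_prop", "g_prop", "log_w", "sum_accept", "n_steps",
        "divergent", "turning",
    )


def _leapfrog(logp_grad, q, p, g, eps, inv_mass):
    p = p + 0.5 * eps * g
    q = q + eps * inv_mass * p
    lp, g = logp_grad(q)
    if not np.isfinite(lp):
        lp, g = -np.inf, np.zeros_like(g)
    p = p + 0.5 * eps * g
    return q, p, lp, g


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _build_tree(logp_grad, q, p, g, direction, depth, eps, inv_mass, h0, rng):
    """Recursively double the trajectory; multinomial sampling over leaves."""
    if depth == 0:
        q1, p1, lp1, g1 = _leapfrog(logp_grad, q, p, g, direction * eps, inv_mass)
        h1 = -lp1 + _kinetic(p1, inv_mass)
        delta = h0 - h1 if np.isfinite(h1) else -np.inf
        t = _Tree()
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.log_w = delta  # log weight relative to initial energy
        t.sum_accept = min(1.0, float(np.exp(min(delta, 0.0))))
        t.n_steps = 1
        t.divergent = delta < -_MAX_DELTA_H
        t.turning = False
        return t

    first = _build_tree(logp_grad, q, p, g, direction, depth - 1, eps, inv_mass, h0, rng)
    if first.divergent or first.turning:
        return first
    if direction == 1:
        second = _build_tree(
            logp_grad, first.q_plus, first.p_plus, first.g_plus,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
        first.q_plus, first.p_plus, first.g_plus = (
            second.q_plus, second.p_plus, second.g_plus,
        )
    else:
        second = _build_tree(
            logp_grad, first.q_minus, first.p_minus, first.g_minus,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
        first.q_minus, first.p_minus, first.g_minus = (
            second.q_minus, second.p_minus, second.g_minus,
        )

    total = np.logaddexp(first.log_w, second.log_w)
    if np.log(rng.random()) < second.log_w - total:
        first.q_prop, first.lp_prop, first.g_prop = (
            second.q_prop, second.lp_prop, second.g_prop,
        )
    first.log_w = total
    first.sum_accept += second.sum_accept
    first.n_steps += second.n_steps
    first.divergent = second.divergent
    dq = first.q_plus - first.q_minus
    first.turning = (
        second.turning
        or np.dot(dq, inv_mass * first.p_minus) < 0
        or np.dot(dq, inv_mass * first.p_plus) < 0
    )
    return first


def _nuts_step(logp_grad, q, lp, g, eps, inv_mass, max_treedepth, rng):
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = -lp + _kinetic(p, inv_mass)
    t = _Tree()
    t.q_minus = t.q_plus = t.q_prop = q
    t.p_minus = t.p_plus = p
    t.g_minus = t.g_plus = t.g_prop = g
    t.lp_prop = lp
    t.log_w = 0.0
    sum_accept = 0.0
    n_steps = 0
    divergent = False
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(
                logp_grad, t.q_plus, t.p_plus, t.g_plus,
                1, depth, eps, inv_mass, h0, rng,
            )
        else:
            sub = _build_tree(
                logp_grad, t.q_minus, t.p_minus, t.g_minus,
                -1, depth, eps, inv_mass, h0, rng,
            )
        sum_accept += sub.sum_accept
        n_steps += sub.n_steps
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.random()) < sub.log_w - t.log_w:
            t.q_prop, t.lp_prop, t.g_prop = sub.q_prop, sub.lp_prop, sub.g_prop
        t.log_w = np.logaddexp(t.log_w, sub.log_w)
        if direction == 1:
            t.q_plus, t.p_plus, t.g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        else:
            t.q_minus, t.p_minus, t.g_minus = sub.q_minus, sub.p_minus, sub.g_minus
        dq = t.q_plus - t.q_minus
        if (np.dot(dq, inv_mass * t.p_minus) < 0
                or np.dot(dq, inv_mass * t.p_plus) < 0):
            depth += 1
            break
        depth += 1
    accept_stat = sum_accept / max(n_steps, 1)
    return t.q_prop, t.lp_prop, t.g_prop, accept_stat, depth, divergent


def _find_initial_step(logp_grad, q, lp, g, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = -lp + _kinetic(p, inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, q, p, g, eps, inv_mass)
    h1 = -lp1 + _kinetic(p1, inv_mass) if np.isfinite(lp1) else np.inf
    delta = h0 - h1
    direction = 1 if delta > np.log(0.8) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, lp1, _ = _leapfrog(logp_grad, q, p, g, eps, inv_mass)
        h1 = -lp1 + _kinetic(p1, inv_mass) if np.isfinite(lp1) else np.inf
        delta = h0 - h1
        if (direction == 1 and delta <= np.log(0.8)) or (
                direction == -1 and delta >= np.log(0.8)):
            break
    return eps


def _adaptation_windows(n_warmup):
    """Stan-style schedule: step-size buffer, doubling mass windows, buffer."""
    init_buf, term_buf, base = 75, 50, 25
    if n_warmup < init_buf + term_buf + base:
        init_buf = max(1, int(0.15 * n_warmup))
        term_buf = max(1, int(0.1 * n_warmup))
        base = max(1, n_warmup - init_buf - term_buf)
    boundaries = []
    start = init_buf
    size = base
    while start + size < n_warmup - term_buf:
        next_size = 2 * size
        if start + size + next_size > n_warmup - term_buf:
            size = n_warmup - term_buf - start
        boundaries.append(start + size)
        start += size
        size *= 2
    if not boundaries:
        boundaries = [n_warmup - term_buf]
    return init_buf, boundaries, n_warmup - term_buf


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    *,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
    init_jitter: float = 0.5,
) -> tuple[np.ndarray, NutsStats]:
    """Run independent NUTS chains; return (chains, draws, dim) positions.

    ``q0`` may be a single point (jittered per chain) or one point per chain.
    Determinism: the same seed yields the same draws, bit for bit.
    """
    q0 = np.atleast_2d(np.asarray(q0, dtype=float))
    dim = q0.shape[-1]
    seeds = np.random.SeedSequence(seed).spawn(chains)
    out = np.empty((chains, draws, dim))
    accept = np.empty((chains, draws))
    depth_arr = np.empty((chains, draws), dtype=int)
    div_arr = np.zeros((chains, draws), dtype=bool)
    final_eps = np.empty(chains)
    final_inv_mass = np.empty((chains, dim))

    # NaN/overflow inside a trajectory is normal: it marks a divergent leaf,
    # which the tree-building logic already discards
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        for c in range(chains):
            _run_chain(logp_grad, q0, c, seeds[c], dim, warmup, draws,
                       target_accept, max_treedepth, init_jitter,
                       out, accept, depth_arr, div_arr, final_eps,
                       final_inv_mass)

    stats = NutsStats(accept, depth_arr, div_arr, final_eps, final_inv_mass)
    return out, stats


def _run_chain(logp_grad, q0, c, seed_seq, dim, warmup, draws, target_accept,
               max_treedepth, init_jitter, out, accept, depth_arr, div_arr,
               final_eps, final_inv_mass):
    """One chain: warmup with windowed adaptation, then kept draws,
    written into the caller's output arrays."""
    rng = np.random.default_rng(seed_seq)
    q = q0[c % q0.shape[0]].copy()
    if q0.shape[0] == 1 and init_jitter > 0:
        q = q + init_jitter * rng.uniform(-1, 1, size=dim)
    lp, g = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, q, lp, g, inv_mass, rng)

    # dual averaging state
    mu = np.log(10 * eps)
    log_eps_bar, h_bar, t0, gamma, kappa = 0.0, 0.0, 10.0, 0.05, 0.75
    da_iter = 0

    init_buf, mass_bounds, adapt_end = _adaptation_windows(warmup)
    window_samples: list[np.ndarray] = []
    bound_idx = 0

    for it in range(warmup + draws):
        adapting = it < warmup
        # short trajectories while the step size is still wild
        depth_cap = min(max_treedepth, 6) if it < init_buf else max_treedepth
        q, lp, g, a_stat, depth, div = _nuts_step(
            logp_grad, q, lp, g, eps, inv_mass, depth_cap, rng)
        if adapting:
            da_iter += 1
            eta = 1.0 / (da_iter + t0)
            h_bar = (1 - eta) * h_bar + eta * (target_accept - a_stat)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if init_buf <= it < adapt_end:
                window_samples.append(q.copy())
            if (bound_idx < len(mass_bounds)
                    and it + 1 == mass_bounds[bound_idx]):
                arr = np.asarray(window_samples)
                n = arr.shape[0]
                if n >= 10:
                    var = arr.var(axis=0, ddof=1)
                    inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                    eps = _find_initial_step(logp_grad, q, lp, g, inv_mass, rng)
                    mu = np.log(10 * eps)
                    log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
                window_samples = []
                bound_idx += 1
            if it + 1 == warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            k = it - warmup
            out[c, k] = q
            accept[c, k] = a_stat
            depth_arr[c, k] = depth
            div_arr[c, k] = div
    final_eps[c] = eps
    final_inv_mass[c] = inv_mass

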