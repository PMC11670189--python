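"""Hamiltonian Monte Carlo with dual-averaging step-size adaptation and
diagonal mass-matrix estimation.

A deliberately compact sampler for smooth, moderately high-dimensional
posteriors supplied as ``logp_and_grad(q) -> (logp, grad)``.  Warmup runs in
three phases (step-size search on the identity metric; metric estimation
from the running variance of the draws; step-size re-adaptation on the new
metric), after which trajectories use a fixed step size with a jittered
number of leapfrog steps.  Trajectories whose energy error exceeds a large
threshold are counted as divergent and rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]

DIVERGENCE_ENERGY = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_samples, dim)
    logp: np.ndarray           # (n_samples,)
    accept_rate: float
    divergences: int
    step_size: float
    inv_mass: np.ndarray       # (dim,)


class InitializationError(RuntimeError):
    pass


def _leapfrog(logp_and_grad: LogpGrad, q, p, grad, step, inv_mass, n_steps):
    """Standard leapfrog integrator; returns (q, p, logp, grad)."""
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        q = q + step * inv_mass * p
        lp, grad = logp_and_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf, grad
        if i < n_steps - 1:
            p = p + step * grad
    p = p + 0.5 * step * grad
    return q, p, lp, grad


def _find_initial_step(logp_and_grad, q0, lp0, grad0, inv_mass, rng):
    """Double/halve until the one-step acceptance probability crosses 0.5."""
    step = 0.1
    p0 = rng.standard_normal(q0.shape) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, lp1, _ = _leapfrog(logp_and_grad, q0, p0, grad0, step, inv_mass, 1)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
    direction = 1 if (h1 - h0) > np.log(0.5) else -1
    for _ in range(50):
        step *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_and_grad, q0, p0, grad0, step, inv_mass, 1)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
        if direction == 1 and (h1 - h0) <= np.log(0.5):
            break
        if direction == -1 and (h1 - h0) >= np.log(0.5):
            break
    return step


class _DualAveraging:
    """Nesterov dual averaging targeting a given acceptance statistic."""

    def __init__(self, step0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.h_bar = 0.0
        self.log_step_bar = np.log(step0)
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_step = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_step_bar = w * log_step + (1 - w) * self.log_step_bar
        return float(np.exp(log_step))

    @property
    def adapted_step(self) -> float:
        return float(np.exp(self.log_step_bar))


def sample_chain(
    logp_and_grad: LogpGrad,
    q0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_leapfrog: int = 24,
) -> ChainResult:
    """Run one HMC chain; q0 must give a finite log-density."""
    dim = q0.size
    q = np.asarray(q0, dtype=float).copy()
    lp, grad = logp_and_grad(q)
    if not np.isfinite(lp):
        raise InitializationError(
            f"non-finite initial log-density {lp} at |q|={np.abs(q).max():.3g}"
        )
    inv_mass = np.ones(dim)

    phase2_start = int(0.15 * n_warmup)
    phase3_start = int(0.85 * n_warmup)
    step = _find_initial_step(logp_and_grad, q, lp, grad, inv_mass, rng)
    da = _DualAveraging(step, target=target_accept)
    # Welford accumulators for the diagonal metric
    w_n, w_mean, w_m2 = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    n_accept = 0
    n_div = 0
    total = n_warmup + n_samples

    for it in range(total):
        warm = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        q1, p1, lp1, grad1 = _leapfrog(
            logp_and_grad, q, p0, grad, step, inv_mass, n_steps
        )
        with np.errstate(over="ignore", invalid="ignore"):
            h1 = (
                lp1 - 0.5 * np.sum(inv_mass * p1**2)
                if np.isfinite(lp1)
                else -np.inf
            )
        delta = h1 - h0
        if not np.isfinite(delta) or delta < -DIVERGENCE_ENERGY:
            accept_prob, accepted = 0.0, False
            if not warm:
                n_div += 1
        else:
            accept_prob = min(1.0, float(np.exp(min(delta, 0.0))))
            accepted = np.log(rng.uniform()) < delta
        if accepted:
            q, lp, grad = q1, lp1, grad1

        if warm:
            step = da.update(accept_prob)
            if phase2_start <= it < phase3_start:
                w_n += 1
                d = q - w_mean
                w_mean += d / w_n
                w_m2 += d * (q - w_mean)
            if it == phase3_start - 1 and w_n > 4:
                var = w_m2 / (w_n - 1)
                shrink = w_n / (w_n + 5.0)
                inv_mass = shrink * var + (1 - shrink) * 1e-3 + 1e-10
                step = _find_initial_step(logp_and_grad, q, lp, grad, inv_mass, rng)
                da = _DualAveraging(step, target=target_accept)
            if it == n_warmup - 1:
                step = da.adapted_step
        else:
            if accepted:
                n_accept += 1
            i = it - n_warmup
            draws[i] = q
            logps[i] = lp

    return ChainResult(
        draws=draws,
        logp=logps,
        accept_rate=n_accept / max(n_samples, 1),
        divergences=n_div,
        step_size=step,
        inv_mass=inv_mass,
    )
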