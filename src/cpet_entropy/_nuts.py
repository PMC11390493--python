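"""A compact No-U-Turn sampler with dual-averaging step-size adaptation.

Implements the recursive tree-doubling NUTS variant with a slice variable,
a diagonal mass matrix estimated during warm-up, and deterministic seeding
(one integer seed fully determines every chain).  The target supplies the
log density and its gradient on an unconstrained parameter space.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "sample_nuts"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log density


@dataclasses.dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim), post-warm-up
    accept_stat: float  # mean acceptance statistic over sampling
    divergences: int
    step_size: float
    inv_mass: np.ndarray  # diagonal of the inverse mass matrix


def _leapfrog(logp_grad, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, logp, grad


def _joint(logp, p, inv_mass):
    return logp - 0.5 * float(np.dot(p * inv_mass, p))


def _find_reasonable_epsilon(logp_grad, theta, rng, inv_mass):
    eps = 1.0
    logp, grad = logp_grad(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = _joint(logp, p, inv_mass)
    theta1, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
    h1 = _joint(logp1, p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        theta1, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
        h1 = _joint(logp1, p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    """Recursive NUTS tree build (Hoffman & Gelman, Algorithm 6)."""

    def __init__(self, logp_grad, rng, inv_mass, eps, log_u, h0):
        self.logp_grad = logp_grad
        self.rng = rng
        self.inv_mass = inv_mass
        self.eps = eps
        self.log_u = log_u
        self.h0 = h0
        self.diverged = False
        self.alpha_sum = 0.0
        self.n_alpha = 0

    def build(self, theta, p, grad, direction, depth):
        if depth == 0:
            theta1, p1, logp1, grad1 = _leapfrog(
                self.logp_grad, theta, p, grad, direction * self.eps, self.inv_mass
            )
            h1 = _joint(logp1, p1, self.inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            n_valid = int(self.log_u <= h1)
            keep_going = self.log_u < _DELTA_MAX + h1
            if not keep_going:
                self.diverged = True
            self.alpha_sum += min(1.0, np.exp(h1 - self.h0))
            self.n_alpha += 1
            return theta1, p1, grad1, theta1, p1, grad1, theta1, n_valid, keep_going
        # Build left and right subtrees.
        (tm, pm, gm, tp, pp, gp, sample, n_valid, keep_going) = self.build(
            theta, p, grad, direction, depth - 1
        )
        if keep_going:
            if direction == -1:
                (tm, pm, gm, _, _, _, sample2, n2, keep2) = self.build(
                    tm, pm, gm, direction, depth - 1
                )
            else:
                (_, _, _, tp, pp, gp, sample2, n2, keep2) = self.build(
                    tp, pp, gp, direction, depth - 1
                )
            if n2 > 0 and self.rng.random() < n2 / max(n_valid + n2, 1):
                sample = sample2
            n_valid += n2
            keep_going = keep2 and _no_u_turn(tm, tp, pm, pp, self.inv_mass)
        return tm, pm, gm, tp, pp, gp, sample, n_valid, keep_going


def _no_u_turn(theta_minus, theta_plus, p_minus, p_plus, inv_mass):
    dt = theta_plus - theta_minus
    return (np.dot(dt, inv_mass * p_minus) >= 0) and (np.dot(dt, inv_mass * p_plus) >= 0)


def _nuts_iteration(logp_grad, theta, logp, grad, eps, inv_mass, rng, max_depth):
    p0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = _joint(logp, p0, inv_mass)
    log_u = h0 + np.log(rng.random())
    tm = tp = theta
    pm = pp = p0
    gm = gp = grad
    sample = theta
    n_valid, depth = 1, 0
    tree = _Tree(logp_grad, rng, inv_mass, eps, log_u, h0)
    keep_going = True
    while keep_going and depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            tm, pm, gm, _, _, _, sample2, n2, keep2 = tree.build(tm, pm, gm, -1, depth)
        else:
            _, _, _, tp, pp, gp, sample2, n2, keep2 = tree.build(tp, pp, gp, 1, depth)
        if keep2 and n2 > 0 and rng.random() < min(1.0, n2 / n_valid):
            sample = sample2
        n_valid += n2
        keep_going = keep2 and _no_u_turn(tm, tp, pm, pp, inv_mass)
        depth += 1
    logp_new, grad_new = logp_grad(sample)
    accept = tree.alpha_sum / max(tree.n_alpha, 1)
    return sample, logp_new, grad_new, accept, tree.diverged


class _DualAveraging:
    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.h_bar = 0.0
        self.log_eps_bar = 0.0
        self.count = 0
        self.log_eps = np.log(eps0)

    def update(self, accept):
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.8,
    max_depth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warm-up draws.

    Warm-up runs in two halves: the first adapts the step size under a unit
    metric, then the diagonal inverse mass is set from the regularized
    sample variance of the second quarter's draws and the step size is
    re-adapted under the new metric.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    half = max(n_warmup // 2, 1)
    windows = [(0, half, True), (half, n_warmup, False)]
    divergences = 0
    for start, stop, first in windows:
        if stop <= start:
            continue
        eps0 = _find_reasonable_epsilon(logp_grad, theta, rng, inv_mass)
        da = _DualAveraging(eps0, target=target_accept)
        window_draws = []
        for i in range(start, stop):
            theta, logp, grad, accept, diverged = _nuts_iteration(
                logp_grad, theta, logp, grad, da.eps, inv_mass, rng, max_depth
            )
            da.update(accept)
            if first and i >= start + (stop - start) // 2:
                window_draws.append(theta.copy())
        if first and len(window_draws) >= 10:
            var = np.var(np.asarray(window_draws), axis=0)
            n = len(window_draws)
            # Stan-style shrinkage toward a small diagonal.
            inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
            inv_mass = np.maximum(inv_mass, 1e-10)
        eps = da.eps_final

    draws = np.empty((n_draws, dim))
    accept_sum = 0.0
    for i in range(n_draws):
        theta, logp, grad, accept, diverged = _nuts_iteration(
            logp_grad, theta, logp, grad, eps, inv_mass, rng, max_depth
        )
        accept_sum += accept
        divergences += int(diverged)
        draws[i] = theta
    return NutsResult(
        draws=draws,
        accept_stat=accept_sum / max(n_draws, 1),
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
    )
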