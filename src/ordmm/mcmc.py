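"""No-U-Turn sampler with dual-averaging step size and diagonal metric.

A compact, dependency-free NUTS implementation (slice variant) for
differentiable log densities on R^d.  Warm-up runs in three phases: an
initial step-size buffer, a metric window that estimates per-coordinate
posterior variances, and a terminal step-size buffer; the metric and step
size are frozen for sampling.  Divergent transitions (energy error > 1000)
are counted and the doubling procedure stops at ``max_treedepth``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_MAX_ENERGY_ERROR = 1000.0


@dataclass
class SampleResult:
    draws: np.ndarray          # (n_draws, dim)
    step_size: float
    metric: np.ndarray         # diagonal of the inverse mass matrix
    accept_rate: float
    n_divergent: int


def _leapfrog(logp_grad: LogpGrad, x, r, g, eps, inv_mass):
    r = r + 0.5 * eps * g
    x = x + eps * inv_mass * r
    logp, g = logp_grad(x)
    r = r + 0.5 * eps * g
    return x, r, g, logp


def _kinetic(r, inv_mass):
    return 0.5 * float(np.dot(r * inv_mass, r))


def find_reasonable_epsilon(logp_grad: LogpGrad, x, rng, inv_mass) -> float:
    """Double/halve the step size until the one-step acceptance crosses 1/2."""
    eps = 1.0
    logp, g = logp_grad(x)
    r = rng.standard_normal(x.shape) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r, inv_mass)
    x1, r1, _, logp1 = _leapfrog(logp_grad, x, r, g, eps, inv_mass)
    h1 = logp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        x1, r1, _, logp1 = _leapfrog(logp_grad, x, r, g, eps, inv_mass)
        h1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


class _Tree:
    """State carried through the recursive doubling of one NUTS transition."""

    __slots__ = ("logp_grad", "inv_mass", "logu", "h0", "rng", "n_divergent")

    def __init__(self, logp_grad, inv_mass, logu, h0, rng):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.logu = logu
        self.h0 = h0
        self.rng = rng
        self.n_divergent = 0

    def build(self, x, r, g, direction, depth, eps):
        if depth == 0:
            x1, r1, g1, logp1 = _leapfrog(self.logp_grad, x, r * direction, g, eps,
                                          self.inv_mass)
            r1 = r1 * direction
            h1 = logp1 - _kinetic(r1, self.inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            n_valid = int(self.logu <= h1)
            diverged = (self.logu - _MAX_ENERGY_ERROR) >= h1
            if diverged:
                self.n_divergent += 1
            alpha = min(1.0, np.exp(min(h1 - self.h0, 0.0)))
            return (x1, r1, g1), (x1, r1, g1), x1, n_valid, not diverged, alpha, 1
        # inner subtree then outer, in the chosen direction
        minus, plus, xprop, n_valid, keep, alpha, n_alpha = self.build(
            x, r, g, direction, depth - 1, eps)
        if keep:
            if direction == 1:
                edge = plus
            else:
                edge = minus
            minus2, plus2, xprop2, n2, keep2, alpha2, n_alpha2 = self.build(
                edge[0], edge[1], edge[2], direction, depth - 1, eps)
            if direction == 1:
                plus = plus2
            else:
                minus = minus2
            if keep2 and n2 > 0 and self.rng.random() < n2 / max(n_valid + n2, 1):
                xprop = xprop2
            alpha += alpha2
            n_alpha += n_alpha2
            n_valid += n2
            keep = keep2 and self._no_uturn(minus, plus)
        return minus, plus, xprop, n_valid, keep, alpha, n_alpha

    def _no_uturn(self, minus, plus):
        dx = plus[0] - minus[0]
        return (np.dot(dx, self.inv_mass * minus[1]) >= 0) and (
            np.dot(dx, self.inv_mass * plus[1]) >= 0)


def _nuts_step(logp_grad, x, logp, g, eps, inv_mass, rng, max_treedepth):
    r0 = rng.standard_normal(x.shape) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r0, inv_mass)
    logu = h0 - rng.exponential()
    tree = _Tree(logp_grad, inv_mass, logu, h0, rng)
    minus = plus = (x, r0, g)
    xcur, logpcur, gcur = x, logp, g
    n_valid, keep, depth = 1, True, 0
    alpha_sum, n_alpha = 0.0, 0
    while keep and depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        edge = plus if direction == 1 else minus
        m2, p2, xprop, n2, keep2, a, na = tree.build(
            edge[0], edge[1], edge[2], direction, depth, eps)
        if direction == 1:
            plus = p2
        else:
            minus = m2
        if keep2 and n2 > 0 and rng.random() < min(1.0, n2 / n_valid):
            xcur = xprop
            logpcur, gcur = logp_grad(xcur)
        alpha_sum += a
        n_alpha += na
        n_valid += n2
        keep = keep2 and tree._no_uturn(minus, plus)
        depth += 1
    accept_stat = alpha_sum / max(n_alpha, 1)
    return xcur, logpcur, gcur, accept_stat, tree.n_divergent


def nuts_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> SampleResult:
    """Run one NUTS chain; returns post-warm-up draws and adaptation state."""
    x = np.array(x0, dtype=float)
    dim = x.size
    logp, g = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")
    inv_mass = np.ones(dim)

    eps = find_reasonable_epsilon(logp_grad, x, rng, inv_mass)
    # dual-averaging state (Hoffman-Gelman defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    b_init = max(25, int(0.15 * n_warmup))
    b_term = max(25, int(0.10 * n_warmup))
    window_start, window_end = b_init, max(b_init, n_warmup - b_term)
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    accept_accum, n_divergent = 0.0, 0

    for it in range(n_warmup + n_draws):
        x, logp, g, accept_stat, div = _nuts_step(
            logp_grad, x, logp, g, eps, inv_mass, rng, max_treedepth)
        if it < n_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            w = adapt_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if window_start <= it < window_end:
                window.append(x.copy())
            if it == window_end - 1 and len(window) >= 10:
                samp = np.asarray(window)
                n = samp.shape[0]
                var = samp.var(axis=0, ddof=1)
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                eps = find_reasonable_epsilon(logp_grad, x, rng, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x
            accept_accum += accept_stat
            n_divergent += div

    return SampleResult(
        draws=draws,
        step_size=eps,
        metric=inv_mass,
        accept_rate=accept_accum / max(n_draws, 1),
        n_divergent=n_divergent,
    )
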