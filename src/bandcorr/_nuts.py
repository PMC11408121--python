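"""Dynamic Hamiltonian Monte Carlo (No-U-Turn) with adaptive tuning.

A compact, dependency-free implementation of the dynamic-trajectory sampler
used by modern Bayesian toolchains: multinomial sampling over the trajectory,
generalized no-U-turn termination, dual-averaging step-size adaptation toward
a target acceptance statistic, and windowed estimation of a diagonal metric
(inverse mass matrix) during warmup.  The target density is supplied as a
callable returning the log density and its gradient at a point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsStats", "nuts_chain"]

_DIVERGENCE_THRESHOLD = 1000.0  # drop in joint log density marking a divergence


@dataclass
class NutsStats:
    """Per-chain sampler diagnostics."""

    divergences: int
    step_size: float
    mean_accept: float
    max_treedepth_hits: int
    inv_mass: np.ndarray


class _Node:
    """Boundary/sample state of a sub-trajectory."""

    __slots__ = ("q", "p", "grad", "logp")

    def __init__(self, q, p, grad, logp):
        self.q = q
        self.p = p
        self.grad = grad
        self.logp = logp


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p, inv_mass * p))


def _warmup_schedule(n_warmup: int) -> tuple[int, int, list[int]]:
    """(init_buffer, term_buffer, metric-window end iterations)."""
    init_buffer, term_buffer, base_window = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.10 * n_warmup))
        return init_buffer, term_buffer, [n_warmup - term_buffer]
    ends = []
    start, size = init_buffer, base_window
    while True:
        end = start + size
        # absorb a final stub window into the last full one
        if end + 2 * size > n_warmup - term_buffer:
            end = n_warmup - term_buffer
            ends.append(end)
            break
        ends.append(end)
        start, size = end, 2 * size
    return init_buffer, term_buffer, ends


class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance delta)."""

    def __init__(self, eps0: float, delta: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.delta = delta
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0

    def update(self, accept_stat: float) -> float:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.delta - accept_stat)
        self.log_eps = self.mu - math.sqrt(self.m) / self.gamma * self.h_bar
        eta = self.m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return math.exp(self.log_eps)

    def restart(self, eps: float) -> None:
        self.mu = math.log(10.0 * eps)
        self.log_eps = math.log(eps)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0


def _find_initial_step(logp_grad, node: _Node, inv_mass, rng) -> float:
    """Double/halve until the one-step acceptance probability crosses 1/2."""
    eps = 1.0
    p0 = rng.standard_normal(len(node.q)) / np.sqrt(inv_mass)
    h0 = node.logp - _kinetic(p0, inv_mass)

    def one_step(eps):
        p = p0 + 0.5 * eps * node.grad
        q = node.q + eps * inv_mass * p
        logp, grad = logp_grad(q)
        p = p + 0.5 * eps * grad
        return (logp - _kinetic(p, inv_mass)) - h0

    dh = one_step(eps)
    if not math.isfinite(dh):
        dh = -math.inf
    direction = 1.0 if dh > math.log(0.5) else -1.0
    for _ in range(60):
        eps_new = eps * (2.0 ** direction)
        dh = one_step(eps_new)
        if not math.isfinite(dh):
            dh = -math.inf
        if direction > 0 and dh <= math.log(0.5):
            break
        if direction < 0 and dh >= math.log(0.5):
            eps = eps_new
            break
        eps = eps_new
    return max(eps, 1e-10)


class _TrajectorySampler:
    def __init__(self, logp_grad: Callable, inv_mass: np.ndarray,
                 eps: float, max_depth: int, rng: np.random.Generator):
        self.f = logp_grad
        self.inv_mass = inv_mass
        self.eps = eps
        self.max_depth = max_depth
        self.rng = rng
        self.n_evals = 0

    def _leapfrog(self, node: _Node, direction: int) -> _Node:
        eps = direction * self.eps
        p = node.p + 0.5 * eps * node.grad
        q = node.q + eps * self.inv_mass * p
        logp, grad = self.f(q)
        self.n_evals += 1
        p = p + 0.5 * eps * grad
        return _Node(q, p, grad, logp)

    def _turning(self, node_minus: _Node, node_plus: _Node, rho: np.ndarray) -> bool:
        return (
            np.dot(self.inv_mass * node_minus.p, rho) <= 0.0
            or np.dot(self.inv_mass * node_plus.p, rho) <= 0.0
        )

    def _build_tree(self, node: _Node, depth: int, direction: int, h0: float):
        """Returns (valid, minus, plus, sample, logw, rho, sum_acc, n_acc, div)."""
        if depth == 0:
            new = self._leapfrog(node, direction)
            dh = (new.logp - _kinetic(new.p, self.inv_mass)) - h0
            if not math.isfinite(dh):
                dh = -math.inf
            divergent = dh < -_DIVERGENCE_THRESHOLD
            accept = math.exp(min(0.0, dh))
            return (not divergent, new, new, new, dh, new.p.copy(), accept, 1, divergent)
        valid1, minus, plus, sample1, logw1, rho, acc, n_acc, div = self._build_tree(
            node, depth - 1, direction, h0
        )
        if not valid1:
            return valid1, minus, plus, sample1, logw1, rho, acc, n_acc, div
        inner = plus if direction == 1 else minus
        valid2, minus2, plus2, sample2, logw2, rho2, acc2, n_acc2, div2 = (
            self._build_tree(inner, depth - 1, direction, h0)
        )
        if direction == 1:
            plus = plus2
        else:
            minus = minus2
        acc += acc2
        n_acc += n_acc2
        div = div or div2
        if not valid2:
            return False, minus, plus, sample1, logw1, rho, acc, n_acc, div
        logw_tot = np.logaddexp(logw1, logw2)
        sample = sample2 if math.log(self.rng.random() + 1e-300) < logw2 - logw_tot else sample1
        rho = rho + rho2
        valid = not self._turning(minus, plus, rho)
        return valid, minus, plus, sample, logw_tot, rho, acc, n_acc, div

    def draw(self, current: _Node) -> tuple[_Node, float, bool, bool]:
        """One transition; returns (new node, accept stat, divergent, maxdepth hit)."""
        dim = len(current.q)
        p0 = self.rng.standard_normal(dim) / np.sqrt(self.inv_mass)
        start = _Node(current.q, p0, current.grad, current.logp)
        h0 = start.logp - _kinetic(p0, self.inv_mass)
        minus = plus = start
        sample = start
        logw_tot = 0.0  # weight of the initial point relative to itself
        rho = p0.copy()
        sum_acc, n_acc = 0.0, 0
        divergent = False
        depth = 0
        while depth < self.max_depth:
            direction = 1 if self.rng.random() < 0.5 else -1
            edge = plus if direction == 1 else minus
            valid, m2, p2, sub_sample, logw_sub, rho_sub, acc, n, div = (
                self._build_tree(edge, depth, direction, h0)
            )
            if direction == 1:
                plus = p2
            else:
                minus = m2
            sum_acc += acc
            n_acc += n
            divergent = divergent or div
            if not valid:
                break
            # biased progressive sampling favors the new subtree
            if math.log(self.rng.random() + 1e-300) < logw_sub - logw_tot:
                sample = sub_sample
            logw_tot = np.logaddexp(logw_tot, logw_sub)
            rho = rho + rho_sub
            if self._turning(minus, plus, rho):
                depth += 1
                break
            depth += 1
        accept_stat = sum_acc / max(n_acc, 1)
        return sample, accept_stat, divergent, depth >= self.max_depth


def nuts_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    *,
    thin: int = 1,
    max_depth: int = 10,
    target_accept: float = 0.8,
) -> tuple[np.ndarray, NutsStats]:
    """Run one chain; returns retained draws (n_samples // thin kept) and stats.

    ``n_samples`` counts post-warmup transitions; every ``thin``-th is stored.
    """
    dim = len(q0)
    logp0, grad0 = logp_grad(q0)
    if not math.isfinite(logp0):
        raise ValueError("initial point has non-finite log density")
    current = _Node(np.asarray(q0, dtype=float).copy(), np.zeros(dim), grad0, logp0)
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, current, inv_mass, rng)
    da = _DualAveraging(eps, delta=target_accept)
    sampler = _TrajectorySampler(logp_grad, inv_mass, eps, max_depth, rng)

    init_buffer, term_buffer, window_ends = _warmup_schedule(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    for it in range(1, n_warmup + 1):
        current, accept_stat, _, _ = sampler.draw(current)
        sampler.eps = da.update(accept_stat)
        in_metric_phase = init_buffer < it <= (n_warmup - term_buffer)
        if in_metric_phase:
            welford_n += 1
            delta = current.q - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += delta * (current.q - welford_mean)
        if it in window_ends and welford_n > 1:
            var = welford_m2 / (welford_n - 1)
            # regularize toward unit scale as Stan does
            n = welford_n
            inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
            inv_mass = np.maximum(inv_mass, 1e-10)
            sampler.inv_mass = inv_mass
            eps = _find_initial_step(logp_grad, current, inv_mass, rng)
            sampler.eps = eps
            da.restart(eps)
            welford_n = 0
            welford_mean[:] = 0.0
            welford_m2[:] = 0.0
    sampler.eps = math.exp(da.log_eps_bar) if n_warmup > 0 else sampler.eps

    n_keep = n_samples // thin
    draws = np.empty((n_keep, dim))
    divergences = 0
    maxdepth_hits = 0
    acc_sum = 0.0
    kept = 0
    for it in range(n_samples):
        current, accept_stat, divergent, hit = sampler.draw(current)
        acc_sum += accept_stat
        divergences += int(divergent)
        maxdepth_hits += int(hit)
        if (it + 1) % thin == 0 and kept < n_keep:
            draws[kept] = current.q
            kept += 1
    stats = NutsStats(
        divergences=divergences,
        step_size=sampler.eps,
        mean_accept=acc_sum / max(n_samples, 1),
        max_treedepth_hits=maxdepth_hits,
        inv_mass=inv_mass,
    )
    return draws, stats
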