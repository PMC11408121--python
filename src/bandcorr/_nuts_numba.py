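"""Compiled dynamic-HMC chain specialized to the m-array posterior kernel.

Same algorithm as :mod:`bandcorr._nuts` (multinomial No-U-Turn sampling,
dual-averaging step size, windowed diagonal-metric warmup) but written as a
single numba-compiled routine with the log-posterior gradient inlined, which
removes the per-leapfrog interpreter overhead.  The recursive tree doubling
is expressed iteratively with a binary-counter merge stack, which performs
the same bottom-up no-U-turn checks and the same progressive multinomial
sample selection as the recursion.

The pure-Python sampler remains the readable reference; a statistical
equivalence test keeps the two engines honest against each other.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._posterior import logp_grad

_DIVERGENCE_THRESHOLD = 1000.0


@njit(cache=True, fastmath=False)
def _logaddexp(a: float, b: float) -> float:
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + np.log1p(np.exp(-abs(a - b)))


@njit(cache=True, fastmath=False)
def _kinetic(p, inv_mass) -> float:
    s = 0.0
    for i in range(p.shape[0]):
        s += inv_mass[i] * p[i] * p[i]
    return 0.5 * s


@njit(cache=True, fastmath=False)
def _find_initial_step(
    q, grad, logp, inv_mass, rng, M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered
):
    dim = q.shape[0]
    eps = 1.0
    p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)
    qn = np.empty(dim)
    gn = np.empty(dim)
    pn = np.empty(dim)

    def step(eps_try):
        for i in range(dim):
            pn[i] = p0[i] + 0.5 * eps_try * grad[i]
            qn[i] = q[i] + eps_try * inv_mass[i] * pn[i]
        lp = logp_grad(qn, M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered, gn)
        for i in range(dim):
            pn[i] = pn[i] + 0.5 * eps_try * gn[i]
        return (lp - _kinetic(pn, inv_mass)) - h0

    dh = step(eps)
    if not np.isfinite(dh):
        dh = -np.inf
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(60):
        eps_new = eps * (2.0**direction)
        dh = step(eps_new)
        if not np.isfinite(dh):
            dh = -np.inf
        if direction > 0.0 and dh <= np.log(0.5):
            break
        if direction < 0.0 and dh >= np.log(0.5):
            eps = eps_new
            break
        eps = eps_new
    return max(eps, 1e-10)


@njit(cache=True, fastmath=False)
def _transition(
    q, grad, logp, eps, inv_mass, max_depth, rng,
    M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered,
    # preallocated merge-stack work arrays, shape (max_depth + 1, dim) / scalars
    st_minus_q, st_minus_p, st_plus_q, st_plus_p,
    st_sample_q, st_rho, st_logw, st_depth,
    # boundary/gradient work arrays, shape (dim,)
    g_buf,
):
    """One sampler transition in place; returns (logp, accept_stat, divergent,
    hit_max_depth) with q and grad updated to the selected draw."""
    dim = q.shape[0]
    p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)

    q_minus = q.copy()
    p_minus = p0.copy()
    g_minus = grad.copy()
    q_plus = q.copy()
    p_plus = p0.copy()
    g_plus = grad.copy()
    q_sample = q.copy()
    logw_tot = 0.0
    rho = p0.copy()
    sum_acc = 0.0
    n_acc = 0
    divergent = False
    depth = 0
    hit_max = False

    cur_q = np.empty(dim)
    cur_p = np.empty(dim)
    cur_g = np.empty(dim)

    while depth < max_depth:
        go_forward = rng.random() < 0.5
        direction = 1.0 if go_forward else -1.0
        if go_forward:
            cur_q[:] = q_plus
            cur_p[:] = p_plus
            cur_g[:] = g_plus
        else:
            cur_q[:] = q_minus
            cur_p[:] = p_minus
            cur_g[:] = g_minus

        n_leaves = 1 << depth
        top = -1  # merge-stack pointer
        valid = True
        for _leaf in range(n_leaves):
            # leapfrog one step in direction
            e = direction * eps
            for i in range(dim):
                cur_p[i] += 0.5 * e * cur_g[i]
                cur_q[i] += e * inv_mass[i] * cur_p[i]
            lp = logp_grad(
                cur_q, M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered, g_buf
            )
            cur_g[:] = g_buf
            for i in range(dim):
                cur_p[i] += 0.5 * e * cur_g[i]
            dh = (lp - _kinetic(cur_p, inv_mass)) - h0
            if not np.isfinite(dh):
                dh = -np.inf
            n_acc += 1
            if dh < 0.0:
                sum_acc += np.exp(dh)
            else:
                sum_acc += 1.0
            if dh < -_DIVERGENCE_THRESHOLD:
                divergent = True
                valid = False
                break
            # push leaf as a depth-0 subtree
            top += 1
            st_minus_q[top] = cur_q
            st_minus_p[top] = cur_p
            st_plus_q[top] = cur_q
            st_plus_p[top] = cur_p
            st_sample_q[top] = cur_q
            st_rho[top] = cur_p
            st_logw[top] = dh
            st_depth[top] = 0
            # binary-counter merges of equal-depth neighbours
            while top > 0 and st_depth[top] == st_depth[top - 1]:
                lw = _logaddexp(st_logw[top - 1], st_logw[top])
                if np.log(rng.random() + 1e-300) < st_logw[top] - lw:
                    st_sample_q[top - 1] = st_sample_q[top]
                st_logw[top - 1] = lw
                for i in range(dim):
                    st_rho[top - 1, i] += st_rho[top, i]
                if go_forward:
                    # older subtree is backward-most: keep its minus, take new plus
                    st_plus_q[top - 1] = st_plus_q[top]
                    st_plus_p[top - 1] = st_plus_p[top]
                else:
                    st_minus_q[top - 1] = st_minus_q[top]
                    st_minus_p[top - 1] = st_minus_p[top]
                st_depth[top - 1] += 1
                top -= 1
                dm = 0.0
                dp = 0.0
                for i in range(dim):
                    dm += inv_mass[i] * st_minus_p[top, i] * st_rho[top, i]
                    dp += inv_mass[i] * st_plus_p[top, i] * st_rho[top, i]
                if dm <= 0.0 or dp <= 0.0:
                    valid = False
                    break
            if not valid:
                break
        if valid and top != 0:
            valid = False  # incomplete merge (cannot happen for power-of-two leaves)
        # update overall boundaries to the farthest state reached
        if go_forward:
            q_plus[:] = cur_q
            p_plus[:] = cur_p
            g_plus[:] = cur_g
        else:
            q_minus[:] = cur_q
            p_minus[:] = cur_p
            g_minus[:] = cur_g
        if not valid:
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.random() + 1e-300) < st_logw[0] - logw_tot:
            q_sample[:] = st_sample_q[0]
        logw_tot = _logaddexp(logw_tot, st_logw[0])
        for i in range(dim):
            rho[i] += st_rho[0, i]
        dm = 0.0
        dp = 0.0
        for i in range(dim):
            dm += inv_mass[i] * p_minus[i] * rho[i]
            dp += inv_mass[i] * p_plus[i] * rho[i]
        depth += 1
        if dm <= 0.0 or dp <= 0.0:
            break
    if depth >= max_depth:
        hit_max = True

    q[:] = q_sample
    lp_new = logp_grad(q, M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered, g_buf)
    grad[:] = g_buf
    accept_stat = sum_acc / max(n_acc, 1)
    return lp_new, accept_stat, divergent, hit_max


@njit(cache=True, fastmath=False)
def run_chain(
    q0, n_warmup, n_samples, thin, max_depth, target_accept, rng,
    M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered,
    init_buffer, term_buffer, window_ends,
):
    """Full warmup + sampling for one chain; returns (draws, divergences,
    step_size, mean_accept, max_depth_hits)."""
    dim = q0.shape[0]
    q = q0.copy()
    grad = np.empty(dim)
    logp = logp_grad(q, M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered, grad)
    inv_mass = np.ones(dim)

    st_minus_q = np.empty((max_depth + 1, dim))
    st_minus_p = np.empty((max_depth + 1, dim))
    st_plus_q = np.empty((max_depth + 1, dim))
    st_plus_p = np.empty((max_depth + 1, dim))
    st_sample_q = np.empty((max_depth + 1, dim))
    st_rho = np.empty((max_depth + 1, dim))
    st_logw = np.empty(max_depth + 1)
    st_depth = np.empty(max_depth + 1, dtype=np.int64)
    g_buf = np.empty(dim)

    eps = _find_initial_step(
        q, grad, logp, inv_mass, rng, M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered
    )
    # dual averaging state
    da_mu = np.log(10.0 * eps)
    da_log_eps = np.log(eps)
    da_log_eps_bar = 0.0
    da_h_bar = 0.0
    da_m = 0
    gamma = 0.05
    t0 = 10.0
    kappa = 0.75

    wf_n = 0
    wf_mean = np.zeros(dim)
    wf_m2 = np.zeros(dim)
    w_idx = 0

    for it in range(1, n_warmup + 1):
        logp, acc, _, _ = _transition(
            q, grad, logp, eps, inv_mass, max_depth, rng,
            M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered,
            st_minus_q, st_minus_p, st_plus_q, st_plus_p,
            st_sample_q, st_rho, st_logw, st_depth, g_buf,
        )
        da_m += 1
        frac = 1.0 / (da_m + t0)
        da_h_bar = (1.0 - frac) * da_h_bar + frac * (target_accept - acc)
        da_log_eps = da_mu - np.sqrt(da_m) / gamma * da_h_bar
        eta = da_m ** (-kappa)
        da_log_eps_bar = eta * da_log_eps + (1.0 - eta) * da_log_eps_bar
        eps = np.exp(da_log_eps)

        if init_buffer < it <= (n_warmup - term_buffer):
            wf_n += 1
            for i in range(dim):
                d = q[i] - wf_mean[i]
                wf_mean[i] += d / wf_n
                wf_m2[i] += d * (q[i] - wf_mean[i])
        if w_idx < len(window_ends) and it == window_ends[w_idx] and wf_n > 1:
            for i in range(dim):
                var = wf_m2[i] / (wf_n - 1)
                inv_mass[i] = max(
                    (wf_n / (wf_n + 5.0)) * var + 1e-3 * (5.0 / (wf_n + 5.0)),
                    1e-10,
                )
            eps = _find_initial_step(
                q, grad, logp, inv_mass, rng,
                M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered,
            )
            da_mu = np.log(10.0 * eps)
            da_log_eps = np.log(eps)
            da_log_eps_bar = 0.0
            da_h_bar = 0.0
            da_m = 0
            wf_n = 0
            wf_mean[:] = 0.0
            wf_m2[:] = 0.0
            w_idx += 1
    if n_warmup > 0:
        eps = np.exp(da_log_eps_bar)

    n_keep = n_samples // thin
    draws = np.empty((n_keep, dim))
    divergences = 0
    hits = 0
    acc_sum = 0.0
    kept = 0
    for it in range(n_samples):
        logp, acc, div, hit = _transition(
            q, grad, logp, eps, inv_mass, max_depth, rng,
            M, cprime, kind, p1, p2, mu_mean, mu_sd, like_on, centered,
            st_minus_q, st_minus_p, st_plus_q, st_plus_p,
            st_sample_q, st_rho, st_logw, st_depth, g_buf,
        )
        acc_sum += acc
        if div:
            divergences += 1
        if hit:
            hits += 1
        if (it + 1) % thin == 0 and kept < n_keep:
            draws[kept] = q
            kept += 1
    return draws, divergences, eps, acc_sum / max(n_samples, 1), hits
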