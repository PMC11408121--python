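"""Joint log-posterior and analytic gradient for the hierarchical m-array model.

Unconstrained parameter vector ``q`` of length ``5 + 2T``::

    q[0]      mu_kappa           mean log hunting hazard
    q[1]      mu_eta             mean log natural hazard
    q[2]      u_sigma_kappa      transformed SD of hunting-hazard effects
    q[3]      u_sigma_eta        transformed SD of natural-hazard effects
    q[4]      u_rho              atanh-like transform of the correlation
    q[5:5+T]  z_kappa            standard-normal innovations (non-centered)
    q[5+T:]   z_eta              standard-normal innovations (non-centered)

The latent block supports both hierarchical parameterizations:

* centered (``centered=True``): ``q[5:]`` are the annual log hazards
  ``alpha_t = (ln h_kappa_t, ln h_eta_t)`` themselves, with prior
  ``alpha_t ~ BVN((mu_kappa, mu_eta), Sigma)``.  Preferred when the data are
  strong (many releases): each log hazard is then tightly identified by its
  cohort counts, the means enter only through the prior, and the scale
  parameters mix freely.
* non-centered: ``eps = L(sigma_kappa, sigma_eta, rho) z`` with ``L`` the
  lower Cholesky factor of the 2x2 covariance and ``q[5:]`` the
  standard-normal innovations ``z``.  Preferred for weak data, where the
  centered posterior develops a funnel.

Both express the identical posterior.  Gradients of the multinomial m-array
log-likelihood with respect to ``log S_t`` and ``log f_t`` are accumulated in
O(T^2) via per-cohort suffix sums, then chained through the competing-risks
transform and the chosen latent map.

Sigma transforms: ``kind 0`` = uniform(0, upper) prior, ``sigma = upper *
expit(u)``; ``kind 1`` = gamma(shape, rate) prior, ``sigma = exp(u)``.  Log
densities include the transform Jacobians so the sampler works on an
unconstrained space.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SIGMA_PRIOR_UNIFORM = 0
SIGMA_PRIOR_GAMMA = 1


@njit(cache=True, fastmath=False)
def _softplus(x: float) -> float:
    if x > 0.0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


@njit(cache=True, fastmath=False)
def logp_grad(
    q: np.ndarray,
    M: np.ndarray,  # (T, T+1) float64 m-array counts
    cprime: float,  # (1 - crippling loss) * band reporting
    sigma_kind: int,
    sigma_p1: float,  # uniform: upper bound (lower fixed 0); gamma: shape
    sigma_p2: float,  # uniform: unused; gamma: rate
    mu_mean: float,
    mu_sd: float,
    likelihood_on: bool,
    centered: bool,
    grad: np.ndarray,  # output, same length as q
) -> float:
    T = M.shape[0]
    grad[:] = 0.0
    lp = 0.0

    mu_k = q[0]
    mu_e = q[1]

    # --- sigma transforms, priors and Jacobians -------------------------
    sig = np.empty(2)
    dsig_du = np.empty(2)
    for i in range(2):
        u = q[2 + i]
        if sigma_kind == SIGMA_PRIOR_UNIFORM:
            e = 1.0 / (1.0 + math.exp(-u))
            sig[i] = sigma_p1 * e
            dsig_du[i] = sigma_p1 * e * (1.0 - e)
            # log expit(u) + log expit(-u)  (uniform density constant dropped)
            lp += -_softplus(-u) - _softplus(u)
            grad[2 + i] += 1.0 - 2.0 * e
        else:
            s = math.exp(u)
            sig[i] = s
            dsig_du[i] = s
            # gamma(shape, rate) on sigma plus log-Jacobian exp(u)
            lp += sigma_p1 * u - sigma_p2 * s
            grad[2 + i] += sigma_p1 - sigma_p2 * s
        if sig[i] <= 0.0 or not math.isfinite(sig[i]):
            return -np.inf
    sk = sig[0]
    se = sig[1]

    # --- correlation: rho = tanh(u), uniform(-1, 1) prior ---------------
    u_rho = q[4]
    rho = math.tanh(u_rho)
    # log(1 - rho^2) = 2*(log 2 - u - softplus(-2u))
    lp += 2.0 * (math.log(2.0) - u_rho - _softplus(-2.0 * u_rho))
    grad[4] += -2.0 * rho
    if 1.0 - rho * rho < 1e-15:  # tanh rounded to +/-1; reject outright
        return -np.inf
    w = math.sqrt(1.0 - rho * rho)

    # --- mu priors ------------------------------------------------------
    lp += -0.5 * ((mu_k - mu_mean) / mu_sd) ** 2
    lp += -0.5 * ((mu_e - mu_mean) / mu_sd) ** 2
    grad[0] += -(mu_k - mu_mean) / (mu_sd * mu_sd)
    grad[1] += -(mu_e - mu_mean) / (mu_sd * mu_sd)

    # --- latent effects and linear predictors ---------------------------
    a = np.empty(T)  # log hunting hazard per year
    b = np.empty(T)  # log natural hazard per year
    opr = 1.0 - rho * rho
    if centered:
        # q[5:] hold the log hazards; bivariate-normal prior around the means
        sxx = 0.0
        sxy = 0.0
        syy = 0.0
        for t in range(T):
            a[t] = q[5 + t]
            b[t] = q[5 + T + t]
            if abs(a[t]) > 25.0 or abs(b[t]) > 25.0:
                return -np.inf
            x = a[t] - mu_k
            y = b[t] - mu_e
            sxx += x * x
            sxy += x * y
            syy += y * y
        A = sxx / (sk * sk)
        B = sxy / (sk * se)
        C = syy / (se * se)
        lp += (
            -T * math.log(sk)
            - T * math.log(se)
            - 0.5 * T * math.log(opr)
            - 0.5 * (A - 2.0 * rho * B + C) / opr
        )
        for t in range(T):
            x = a[t] - mu_k
            y = b[t] - mu_e
            gx = -(x / (sk * sk) - rho * y / (sk * se)) / opr
            gy = -(y / (se * se) - rho * x / (sk * se)) / opr
            grad[5 + t] += gx
            grad[5 + T + t] += gy
            grad[0] += -gx  # means enter the prior with opposite sign
            grad[1] += -gy
        grad[2] += (-T / sk + (A - rho * B) / (opr * sk)) * dsig_du[0]
        grad[3] += (-T / se + (C - rho * B) / (opr * se)) * dsig_du[1]
        grad[4] += (
            T * rho / opr
            + (B * opr - rho * (A - 2.0 * rho * B + C)) / (opr * opr)
        ) * opr  # d rho / d u_rho = 1 - rho^2
    else:
        for t in range(T):
            z1 = q[5 + t]
            z2 = q[5 + T + t]
            lp += -0.5 * (z1 * z1 + z2 * z2)
            grad[5 + t] += -z1
            grad[5 + T + t] += -z2
            a[t] = mu_k + sk * z1
            b[t] = mu_e + se * (rho * z1 + w * z2)
            if abs(a[t]) > 25.0 or abs(b[t]) > 25.0:
                return -np.inf

    if not likelihood_on:
        return lp

    # --- demographic transforms -----------------------------------------
    hk = np.empty(T)
    he = np.empty(T)
    S = np.empty(T)
    dead = np.empty(T)
    tot = np.empty(T)
    kap = np.empty(T)
    f = np.empty(T)
    for t in range(T):
        hk[t] = math.exp(a[t])
        he[t] = math.exp(b[t])
        tot[t] = hk[t] + he[t]
        S[t] = math.exp(-tot[t])
        dead[t] = -math.expm1(-tot[t])
        kap[t] = dead[t] * hk[t] / tot[t]
        f[t] = cprime * kap[t]
        if f[t] <= 0.0:
            return -np.inf

    # --- multinomial m-array log-likelihood and d/dlogS, d/dlogf --------
    dlnS = np.zeros(T)
    dlnf = np.zeros(T)
    Prow = np.empty(T)
    Q = np.empty(T)
    for t in range(T):
        surv = 1.0
        rowsum = 0.0
        for j in range(t, T):
            if j > t:
                surv *= S[j - 1]
            p = surv * f[j]
            Prow[j] = p
            rowsum += p
        PT = 1.0 - rowsum
        if PT <= 0.0:
            return -np.inf
        for j in range(t, T):
            m = M[t, j]
            if m > 0.0:
                lp += m * math.log(Prow[j])
        mT = M[t, T]
        if mT > 0.0:
            lp += mT * math.log(PT)
        W = mT / PT
        for j in range(t, T):
            Q[j] = M[t, j] - W * Prow[j]
            dlnf[j] += Q[j]
        acc = 0.0
        for k in range(T - 2, t - 1, -1):
            acc += Q[k + 1]
            dlnS[k] += acc
    if not math.isfinite(lp):
        return -np.inf

    # --- chain rule back to the parameters ------------------------------
    g_mu_k = 0.0
    g_mu_e = 0.0
    g_sk = 0.0
    g_se = 0.0
    g_rho = 0.0
    for t in range(T):
        # d log S / d a = -hk ; d log S / d b = -he
        # kappa = dead * hk / tot:
        dk_dhk = S[t] * hk[t] / tot[t] + dead[t] * he[t] / (tot[t] * tot[t])
        dk_dhe = hk[t] * (S[t] / tot[t] - dead[t] / (tot[t] * tot[t]))
        dlnk_da = hk[t] * dk_dhk / kap[t]
        dlnk_db = he[t] * dk_dhe / kap[t]
        ga = -dlnS[t] * hk[t] + dlnf[t] * dlnk_da
        gb = -dlnS[t] * he[t] + dlnf[t] * dlnk_db
        if centered:
            # likelihood touches the log hazards only, never the means
            grad[5 + t] += ga
            grad[5 + T + t] += gb
        else:
            g_mu_k += ga
            g_mu_e += gb
            z1 = q[5 + t]
            z2 = q[5 + T + t]
            g_sk += ga * z1
            g_se += gb * (rho * z1 + w * z2)
            g_rho += gb * se * (z1 - (rho / w) * z2)
            grad[5 + t] += ga * sk + gb * se * rho
            grad[5 + T + t] += gb * se * w
    grad[0] += g_mu_k
    grad[1] += g_mu_e
    if not centered:
        grad[2] += g_sk * dsig_du[0]
        grad[3] += g_se * dsig_du[1]
        grad[4] += g_rho * (1.0 - rho * rho)
    return lp


def unpack_params(
    q: np.ndarray, T: int, sigma_kind: int, sigma_p1: float
) -> dict[str, float]:
    """Constrained top-level parameters from one unconstrained draw."""
    if sigma_kind == SIGMA_PRIOR_UNIFORM:
        sk = sigma_p1 / (1.0 + math.exp(-q[2]))
        se = sigma_p1 / (1.0 + math.exp(-q[3]))
    else:
        sk = math.exp(q[2])
        se = math.exp(q[3])
    return {
        "mu_kappa": float(q[0]),
        "mu_eta": float(q[1]),
        "sigma_kappa": sk,
        "sigma_eta": se,
        "rho": math.tanh(q[4]),
    }
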