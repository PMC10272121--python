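"""Numba-compiled likelihood recursions and a Nelder-Mead optimizer.

These kernels carry the per-edge cost of a seed-to-whole-brain dynamic
connectivity map (hundreds of quasi-ML fits per subject), so they are kept
free of Python-level allocation inside the hot loops.

Parameter transforms keep every iterate strictly inside the admissible
region: omega = exp(p), and the persistence pair (alpha, beta) — or the
correlation-stage pair (theta1, theta2) — is written as s*r and s*(1-r)
with s = S_MAX * sigmoid(.) and r = sigmoid(.), so alpha, beta >= 0 and
alpha + beta <= S_MAX = 0.999 by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

S_MAX = 0.999  # stationarity cap for alpha+beta and theta1+theta2
LOG_2PI = 1.8378770664093453

MODE_GARCH = 0
MODE_DCC = 1


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _logit(p):
    return np.log(p / (1.0 - p))


@njit(cache=True)
def garch_untransform(p):
    """Transformed 3-vector -> (omega, alpha, beta)."""
    q = p[0]
    if q > 50.0:
        q = 50.0
    elif q < -50.0:
        q = -50.0
    omega = np.exp(q)
    s = S_MAX * _sigmoid(p[1])
    r = _sigmoid(p[2])
    return omega, s * r, s * (1.0 - r)


@njit(cache=True)
def garch_transform(omega, alpha, beta):
    s = (alpha + beta) / S_MAX
    r = alpha / (alpha + beta)
    out = np.empty(3)
    out[0] = np.log(omega)
    out[1] = _logit(s)
    out[2] = _logit(r)
    return out


@njit(cache=True)
def pair_untransform(p):
    """Transformed 2-vector -> (theta1, theta2) with theta1+theta2 <= S_MAX."""
    s = S_MAX * _sigmoid(p[0])
    r = _sigmoid(p[1])
    return s * r, s * (1.0 - r)


@njit(cache=True)
def pair_transform(theta1, theta2):
    s = (theta1 + theta2) / S_MAX
    r = theta1 / (theta1 + theta2)
    out = np.empty(2)
    out[0] = _logit(s)
    out[1] = _logit(r)
    return out


@njit(cache=True)
def garch_filter(x, omega, alpha, beta, var0):
    """Conditional variance recursion; x is the demeaned series."""
    T = x.shape[0]
    s2 = np.empty(T)
    s2[0] = var0
    for t in range(1, T):
        s2[t] = omega + alpha * x[t - 1] * x[t - 1] + beta * s2[t - 1]
    return s2

@njit(cache=True)
def garch_nll(p, x, var0):
    """Gaussian quasi negative log-likelihood at transformed parameters."""
    omega, alpha, beta = garch_untransform(p)
    T = x.shape[0]
    s2 = var0
    nll = 0.5 * (LOG_2PI + np.log(s2) + x[0] * x[0] / s2)
    for t in range(1, T):
        s2 = omega + alpha * x[t - 1] * x[t - 1] + beta * s2
        if s2 < 1e-300:
            s2 = 1e-300
        nll += 0.5 * (LOG_2PI + np.log(s2) + x[t] * x[t] / s2)
    return nll


@njit(cache=True)
def dcc_rho(z1, z2, a, b, sbar):
    """Correlation path from the DCC recursion.

    Q_t = (1-a-b)*Sbar + a*z_{t-1} z_{t-1}' + b*Q_{t-1}, Q_1 = Sbar;
    rho_t = q12 / sqrt(q11*q22). rho_1 equals sbar.
    """
    T = z1.shape[0]
    rho = np.empty(T)
    q11 = 1.0
    q22 = 1.0
    q12 = sbar
    rho[0] = sbar
    c = 1.0 - a - b
    for t in range(1, T):
        q11 = c + a * z1[t - 1] * z1[t - 1] + b * q11
        q22 = c + a * z2[t - 1] * z2[t - 1] + b * q22
        q12 = c * sbar + a * z1[t - 1] * z2[t - 1] + b * q12
        rho[t] = q12 / np.sqrt(q11 * q22)
    return rho


@njit(cache=True)
def dcc_nll(p, z1, z2, sbar):
    """Correlation-stage quasi negative log-likelihood (transformed params).

    l_c = -1/2 sum_t [ log|R_t| + z_t' R_t^-1 z_t - z_t' z_t ]  with the
    2x2 R_t having off-diagonal rho_t; rho is clipped away from +-1 so the
    degenerate perfectly-correlated case stays finite.
    """
    a, b = pair_untransform(p)
    T = z1.shape[0]
    q11 = 1.0
    q22 = 1.0
    q12 = sbar
    c = 1.0 - a - b
    nll = 0.0
    rho = sbar
    for t in range(T):
        if t > 0:
            q11 = c + a * z1[t - 1] * z1[t - 1] + b * q11
            q22 = c + a * z2[t - 1] * z2[t - 1] + b * q22
            q12 = c * sbar + a * z1[t - 1] * z2[t - 1] + b * q12
            rho = q12 / np.sqrt(q11 * q22)
        r = rho
        if r > 0.9999:
            r = 0.9999
        elif r < -0.9999:
            r = -0.9999
        one_m = 1.0 - r * r
        zz = z1[t] * z1[t] + z2[t] * z2[t]
        quad = (zz - 2.0 * r * z1[t] * z2[t]) / one_m
        nll += 0.5 * (np.log(one_m) + quad - zz)
    return nll


@njit(cache=True)
def _objective(mode, p, d1, d2, aux):
    if mode == MODE_GARCH:
        return garch_nll(p, d1, aux)
    return dcc_nll(p, d1, d2, aux)


@njit(cache=True)
def nelder_mead(mode, x0, d1, d2, aux, ftol, maxiter, step):
    """Deterministic Nelder-Mead in the transformed parameter space.

    Returns (x_best, f_best, converged). The best vertex is monotonically
    non-increasing, so f_best <= f(x0) always holds.
    """
    n = x0.shape[0]
    m = n + 1
    sim = np.empty((m, n))
    fx = np.empty(m)
    for j in range(n):
        sim[0, j] = x0[j]
    fx[0] = _objective(mode, sim[0], d1, d2, aux)
    for i in range(n):
        for j in range(n):
            sim[i + 1, j] = x0[j]
        sim[i + 1, i] = x0[i] + step
        fx[i + 1] = _objective(mode, sim[i + 1], d1, d2, aux)

    alpha_r = 1.0
    gamma_e = 2.0
    rho_c = 0.5
    sigma_s = 0.5
    converged = False
    for _it in range(maxiter):
        # insertion sort of simplex by objective value
        for i in range(1, m):
            fi = fx[i]
            xi = sim[i].copy()
            k = i - 1
            while k >= 0 and fx[k] > fi:
                fx[k + 1] = fx[k]
                sim[k + 1] = sim[k]
                k -= 1
            fx[k + 1] = fi
            sim[k + 1] = xi

        # convergence on the objective span, relative to its magnitude:
        # quasi-likelihoods here can be flat in unidentified directions
        # (e.g. beta when alpha -> 0) or crawl along a boundary in the
        # unbounded transformed space, so requiring the simplex itself to
        # collapse would flag sound fits
        fspan = np.abs(fx[m - 1] - fx[0])
        if fspan <= ftol * (1.0 + np.abs(fx[0])):
            converged = True
            break

        cen = np.zeros(n)
        for i in range(m - 1):
            for j in range(n):
                cen[j] += sim[i, j]
        for j in range(n):
            cen[j] /= m - 1

        xr = cen + alpha_r * (cen - sim[m - 1])
        fr = _objective(mode, xr, d1, d2, aux)
        if fr < fx[0]:
            xe = cen + gamma_e * (xr - cen)
            fe = _objective(mode, xe, d1, d2, aux)
            if fe < fr:
                sim[m - 1] = xe
                fx[m - 1] = fe
            else:
                sim[m - 1] = xr
                fx[m - 1] = fr
        elif fr < fx[m - 2]:
            sim[m - 1] = xr
            fx[m - 1] = fr
        else:
            if fr < fx[m - 1]:
                xc = cen + rho_c * (xr - cen)
            else:
                xc = cen + rho_c * (sim[m - 1] - cen)
            fc = _objective(mode, xc, d1, d2, aux)
            if fc < min(fr, fx[m - 1]):
                sim[m - 1] = xc
                fx[m - 1] = fc
            else:
                for i in range(1, m):
                    sim[i] = sim[0] + sigma_s * (sim[i] - sim[0])
                    fx[i] = _objective(mode, sim[i], d1, d2, aux)

    best = 0
    for i in range(1, m):
        if fx[i] < fx[best]:
            best = i
    return sim[best].copy(), fx[best], converged


@njit(cache=True)
def garch_sim(n, omega, alpha, beta, z):
    """Generate a GARCH(1,1) series from standard-normal innovations z."""
    x = np.empty(n)
    s2 = omega / (1.0 - alpha - beta)
    x[0] = np.sqrt(s2) * z[0]
    for t in range(1, n):
        s2 = omega + alpha * x[t - 1] * x[t - 1] + beta * s2
        x[t] = np.sqrt(s2) * z[t]
    return x
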