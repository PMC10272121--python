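"""Two-stage GARCH(1,1)/DCC estimation of time-varying seed-target correlation.

The dynamic conditional correlation (DCC) estimator runs in two stages:

1. each series gets a univariate GARCH(1,1) fit by Gaussian quasi maximum
   likelihood (constant mean, i.e. the series is demeaned only), yielding
   standardized residuals z_t = (x_t - mu) / sigma_t;
2. the pair of residual series drives an EWMA-like recursion
   Q_t = (1 - theta1 - theta2) * Sbar + theta1 * z_{t-1} z_{t-1}' + theta2 * Q_{t-1}
   whose normalized off-diagonal rho_t = q12 / sqrt(q11 q22) is the
   conditional correlation path; (theta1, theta2) maximize the
   correlation-stage quasi-likelihood.

The temporal mean of rho_t plays the role of static connectivity; its
temporal variance is the dynamic-connectivity feature used for trait
prediction.

Estimation is pairwise per (seed, target) edge; stage-1 fits are shared
across all edges that involve the same series.  All optimizers use fixed
starting values and a deterministic Nelder-Mead, so identical input gives
identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels as K

#: fixed quasi-ML starting values (omega is scaled by the sample variance)
GARCH_START = (0.1, 0.05, 0.90)
DCC_START = (0.05, 0.90)
OPT_TOL = 1e-6
OPT_MAXITER = 500
_NM_STEP = 0.25

MIN_LENGTH = 100
_CONST_TOL = 1e-10


@dataclass
class GarchFit:
    """Univariate GARCH(1,1) quasi-ML fit (constant-mean model)."""

    mu: float
    omega: float
    alpha: float
    beta: float
    sigma_series: np.ndarray
    z_series: np.ndarray
    loglik: float
    converged: bool

    @property
    def unconditional_variance(self) -> float:
        return self.omega / (1.0 - self.alpha - self.beta)


@dataclass
class DccFit:
    """Correlation-stage fit for one pair of standardized residual series."""

    theta1: float
    theta2: float
    sbar: float
    rho_series: np.ndarray
    loglik: float
    converged: bool


@dataclass
class EdgeDynamics:
    """Estimated dynamic-correlation path for one (seed, target) edge."""

    seed_id: str
    target_id: str
    rho_series: np.ndarray = field(repr=False)
    dcc_mean: float
    dcc_variance: float
    converged: bool = True


def _validate_series(x: np.ndarray, name: str = "series") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < MIN_LENGTH:
        raise ValueError(f"{name} must have length >= {MIN_LENGTH}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    if x.std() <= _CONST_TOL:
        raise ValueError(f"{name} is (numerically) constant")
    return x


def fit_garch11(series: np.ndarray) -> GarchFit:
    """Fit GARCH(1,1) by Gaussian quasi maximum likelihood.

    The conditional variance follows
    sigma^2_t = omega + alpha * eps^2_{t-1} + beta * sigma^2_{t-1}
    with eps_t = x_t - mu, mu the sample mean, and sigma^2_1 initialized to
    the sample variance.  Constraints (omega > 0, alpha, beta >= 0,
    alpha + beta <= 0.999) are enforced by smooth reparameterization, so the
    returned log-likelihood is never below its value at the starting point
    (omega, alpha, beta) = (0.1 * var(x), 0.05, 0.90).
    """
    x = _validate_series(series)
    mu = float(x.mean())
    xc = x - mu
    var0 = float(xc.var())  # population (1/T) convention
    # optimize on the variance-standardized series: the objective is then
    # scale-free, making the fit exactly invariant to positive rescaling
    sd0 = np.sqrt(var0)
    xs = xc / sd0
    p0 = K.garch_transform(GARCH_START[0], GARCH_START[1], GARCH_START[2])
    p, nll, conv = K.nelder_mead(
        K.MODE_GARCH, p0, xs, xs, 1.0, OPT_TOL, OPT_MAXITER, _NM_STEP
    )
    omega_s, alpha, beta = K.garch_untransform(p)
    sigma = np.sqrt(K.garch_filter(xs, omega_s, alpha, beta, 1.0))
    z = xs / sigma
    return GarchFit(
        mu=mu,
        omega=float(omega_s * var0),
        alpha=float(alpha),
        beta=float(beta),
        sigma_series=sigma * sd0,
        z_series=z,
        loglik=float(-nll - xs.size * np.log(sd0)),
        converged=bool(conv),
    )


def fit_dcc_bivariate(z_seed: np.ndarray, z_target: np.ndarray) -> DccFit:
    """Fit the DCC correlation stage for one pair of residual series.

    Sbar is the sample correlation of the residual pair, Q_1 = Sbar-matrix,
    and (theta1, theta2) maximize the correlation-stage quasi-likelihood
    under theta1, theta2 >= 0, theta1 + theta2 <= 0.999.  rho_1 equals the
    off-diagonal of Sbar.  A numerically perfectly correlated pair
    (1 - sbar^2 below 1e-8) short-circuits the optimizer: the recursion then
    preserves equal matrix entries and rho_t is identically +-1.
    """
    z1 = np.asarray(z_seed, dtype=float).ravel()
    z2 = np.asarray(z_target, dtype=float).ravel()
    if z1.size != z2.size:
        raise ValueError(f"residual length mismatch: {z1.size} vs {z2.size}")
    if z1.size < MIN_LENGTH:
        raise ValueError(f"residual series must have length >= {MIN_LENGTH}")
    if not (np.all(np.isfinite(z1)) and np.all(np.isfinite(z2))):
        raise ValueError("residuals contain non-finite values")
    sbar = float(np.corrcoef(z1, z2)[0, 1])

    if 1.0 - sbar * sbar < 1e-8:
        # snap to exactly +-1 so the recursion preserves equal entries and
        # the returned path is identically +-1
        sbar = 1.0 if sbar > 0 else -1.0
        a, b = DCC_START
        rho = K.dcc_rho(z1, z2, a, b, sbar)
        nll = K.dcc_nll(K.pair_transform(a, b), z1, z2, sbar)
        return DccFit(a, b, sbar, rho, float(-nll), True)

    p0 = K.pair_transform(*DCC_START)
    p, nll, conv = K.nelder_mead(
        K.MODE_DCC, p0, z1, z2, sbar, OPT_TOL, OPT_MAXITER, _NM_STEP
    )
    a, b = K.pair_untransform(p)
    rho = K.dcc_rho(z1, z2, a, b, sbar)
    return DccFit(float(a), float(b), sbar, rho, float(-nll), bool(conv))


def _summaries(rho: np.ndarray, fisher_z: bool) -> tuple[float, float]:
    if fisher_z:
        v = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        return float(np.tanh(v.mean())), float(v.var())
    return float(rho.mean()), float(rho.var())


def edge_dynamics(
    seed_series: np.ndarray,
    target_series: np.ndarray,
    seed_id: str = "seed",
    target_id: str = "target",
    *,
    garch_seed: GarchFit | None = None,
    garch_target: GarchFit | None = None,
    fisher_z: bool = False,
) -> EdgeDynamics:
    """Estimate the dynamic-correlation path for one (seed, target) pair.

    Composes the two estimation stages; precomputed stage-1 fits may be
    passed to share them across edges.  Temporal mean and variance use the
    population (1/T) convention over the full path; with ``fisher_z`` the
    variance is taken on arctanh-transformed correlations (off by default).
    """
    gs = garch_seed if garch_seed is not None else fit_garch11(seed_series)
    gt = garch_target if garch_target is not None else fit_garch11(target_series)
    dcc = fit_dcc_bivariate(gs.z_series, gt.z_series)
    mean, var = _summaries(dcc.rho_series, fisher_z)
    return EdgeDynamics(
        seed_id=seed_id,
        target_id=target_id,
        rho_series=dcc.rho_series,
        dcc_mean=mean,
        dcc_variance=var,
        converged=gs.converged and gt.converged and dcc.converged,
    )


def seed_dcc_map(
    subject,
    seed_ids: Sequence[str],
    target_ids: Sequence[str],
    *,
    fisher_z: bool = False,
) -> list[EdgeDynamics]:
    """Dynamic-connectivity map: every (seed, target) edge of one subject.

    ``subject`` is a :class:`~dynconn.io.ParcellatedSeries`.  Each region's
    GARCH(1,1) fit is computed once and reused across all edges that touch
    it, so the map costs one stage-1 fit per region plus one correlation
    stage per edge.  Output is ordered seed-major, then target order.
    """
    labels = list(subject.labels)
    for rid in list(seed_ids) + list(target_ids):
        if rid not in labels:
            raise KeyError(f"unknown region label: {rid!r}")
    cache: dict[str, GarchFit] = {}

    def garch_of(rid: str) -> GarchFit:
        if rid not in cache:
            cache[rid] = fit_garch11(subject.values[:, labels.index(rid)])
        return cache[rid]

    out = []
    for sid in seed_ids:
        gs = garch_of(sid)
        for tid in target_ids:
            gt = garch_of(tid)
            dcc = fit_dcc_bivariate(gs.z_series, gt.z_series)
            mean, var = _summaries(dcc.rho_series, fisher_z)
            ed = EdgeDynamics(sid, tid, dcc.rho_series, mean, var,
                              gs.converged and gt.converged and dcc.converged)
            if not ed.converged:
                warnings.warn(f"edge ({sid}, {tid}): non-converged fit", stacklevel=2)
            out.append(ed)
    return out
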