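"""Dense REML machinery for small linear mixed models.

The phenotypic analysis needs a mixed-model fitter that supports, at the
same time,

* an arbitrary set of independent random-effect groups with iid effects
  (rows, columns, lines, line-by-trial cells),
* per-observation weights entering the residual covariance as
  ``sigma2_e * diag(1/w)``, and
* an optionally *fixed* residual variance.  Fixing the residual variance
  while weighting by the stage-1 standard errors is what makes the
  line-by-trial interaction variance separable from the residual when
  every line-by-trial cell holds a single adjusted mean.

No installed mixed-model package exposes that combination, so the REML
log-likelihood is evaluated directly on dense matrices (the trial- and
cycle-level problems here have at most a few hundred rows) and maximised
with a derivative-free simplex search over log-variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["LMMFit", "reml_fit", "gls", "ConvergenceWarning"]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceWarning(UserWarning):
    """REML iteration stopped before meeting its tolerance."""


@dataclass
class LMMFit:
    """Result of a REML fit.

    Attributes
    ----------
    beta, beta_cov
        GLS estimates of the fixed effects and their covariance
        ``(X' V^-1 X)^-1`` at the REML variance estimates.
    varcomps
        Estimated variance for each random-effect group, keyed by the
        name given in ``randoms``.  Components that collapsed to the
        lower boundary are reported as ``0.0``.
    sigma2_e
        Residual variance (the supplied constant when it was fixed).
    loglik
        Restricted log-likelihood at the optimum (constants included,
        so values are comparable across models with the same fixed
        part).
    n_vparams
        Number of *estimated* variance parameters; used by ``aic``.
    blups
        Empirical BLUPs of each random-effect vector.
    V
        Marginal covariance matrix at the estimates (handy for a GLS
        refit with a different fixed design).
    """

    beta: np.ndarray
    beta_cov: np.ndarray
    varcomps: dict[str, float]
    sigma2_e: float
    loglik: float
    n_vparams: int
    converged: bool
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    V: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_vparams - 2.0 * self.loglik


def _reml_loglik(y, X, V):
    """Restricted log-likelihood of y ~ N(Xb, V), b profiled out."""
    n, p = X.shape
    try:
        L = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet_V = 2.0 * np.sum(np.log(np.diag(L[0])))
    Vi_y = cho_solve(L, y)
    Vi_X = cho_solve(L, X)
    XtViX = X.T @ Vi_X
    try:
        Lx = cho_factor(XtViX, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet_X = 2.0 * np.sum(np.log(np.diag(Lx[0])))
    beta = cho_solve(Lx, X.T @ Vi_y)
    resid = y - X @ beta
    quad = float(resid @ cho_solve(L, resid))
    ll = -0.5 * (logdet_V + logdet_X + quad + (n - p) * _LOG2PI)
    return ll, beta, cho_solve(Lx, np.eye(p)), L


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    randoms: dict[str, np.ndarray] | None = None,
    weights: np.ndarray | None = None,
    fixed_resid: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> LMMFit:
    """Fit ``y = X b + sum_r Z_r u_r + e`` by REML.

    Parameters
    ----------
    randoms
        Mapping ``name -> Z`` of random-effect design matrices; each
        ``u_r ~ N(0, I sigma2_r)``.
    weights
        Per-observation weights ``w``; the residual covariance is
        ``sigma2_e * diag(1/w)``.
    fixed_resid
        If given, ``sigma2_e`` is held at this value instead of being
        estimated (requires weights or random effects to carry the
        remaining variation).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows must match y length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    randoms = dict(randoms or {})
    names = list(randoms)
    ZZt = {k: np.asarray(Z, dtype=float) @ np.asarray(Z, dtype=float).T for k, Z in randoms.items()}
    R = np.ones(n) if weights is None else 1.0 / np.asarray(weights, dtype=float)
    if np.any(R <= 0) or not np.all(np.isfinite(R)):
        raise ValueError("weights must be positive and finite")

    estimate_resid = fixed_resid is None
    free = names + (["__resid__"] if estimate_resid else [])
    scale = max(float(np.var(y)), 1e-12)

    def build_V(sig2, s2e):
        V = np.diag(s2e * R)
        for k in names:
            V += sig2[k] * ZZt[k]
        return V

    def unpack(theta):
        v = np.exp(np.clip(theta, -40.0, 40.0))
        sig2 = {k: v[i] for i, k in enumerate(names)}
        s2e = v[-1] if estimate_resid else float(fixed_resid)
        return sig2, s2e

    def nll(theta):
        sig2, s2e = unpack(theta)
        out = _reml_loglik(y, X, build_V(sig2, s2e))
        if out is None:
            return 1e12
        return -out[0]

    converged = True
    if free:
        theta0 = np.full(len(free), np.log(scale / (len(free) + 1)))
        res = optimize.minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            bounds=[(-40.0, 40.0)] * len(free),
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        # polish with a short simplex pass; L-BFGS-B with numeric
        # gradients can stall on flat boundary regions
        res2 = optimize.minimize(
            nll,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 100 * len(free)},
        )
        if res2.fun <= res.fun:
            res = res2
        theta = res.x
        converged = bool(res.success) and np.isfinite(res.fun)
        if not converged:
            warnings.warn(
                "REML simplex search did not meet tolerance; returning current state",
                ConvergenceWarning,
                stacklevel=2,
            )
    else:
        theta = np.empty(0)

    sig2, s2e = unpack(theta)
    V = build_V(sig2, s2e)
    out = _reml_loglik(y, X, V)
    if out is None:
        raise np.linalg.LinAlgError("marginal covariance not positive definite at optimum")
    ll, beta, beta_cov, L = out
    resid = y - X @ beta
    Vi_resid = cho_solve(L, resid)
    blups = {k: sig2[k] * (randoms[k].T @ Vi_resid) for k in names}
    # boundary components are genuine zeros for reporting purposes
    floor = 1e-8 * scale
    varcomps = {k: (0.0 if sig2[k] < floor else float(sig2[k])) for k in names}
    return LMMFit(
        beta=beta,
        beta_cov=beta_cov,
        varcomps=varcomps,
        sigma2_e=float(s2e),
        loglik=float(ll),
        n_vparams=len(free),
        converged=converged,
        blups=blups,
        V=V,
    )


def gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Generalised least squares with known covariance.

    Returns ``(beta, beta_cov)`` with ``beta_cov = (X' V^-1 X)^-1``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    L = cho_factor(np.asarray(V, dtype=float), lower=True)
    Vi_X = cho_solve(L, X)
    XtViX = X.T @ Vi_X
    Lx = cho_factor(XtViX, lower=True)
    beta = cho_solve(Lx, X.T @ cho_solve(L, y))
    return beta, cho_solve(Lx, np.eye(X.shape[1]))
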