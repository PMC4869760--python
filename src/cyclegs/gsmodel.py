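"""RR-BLUP and G-BLUP genomic prediction models.

Both models are the same single-kernel linear mixed model seen from two
sides: ridge regression on markers (``y = Xb + Zu + e`` with
``u ~ N(0, I s2_u)``) and a line-effect model with a genomic
relationship matrix (``y = Xb + g + e`` with ``g ~ N(0, K s2_G)``).
Variance components are REML estimates obtained from the spectral
decomposition of the kernel, profiling out the residual variance, so a
single one-dimensional search over the variance ratio gives the exact
restricted-likelihood optimum.  With the kinship built from the same
centered markers the two models yield identical GEBVs.

Estimators follow scikit-learn conventions (``fit``/``predict``,
fitted attributes with a trailing underscore) and compose with sklearn
model-selection utilities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .markers import KinshipMatrix, MarkerMatrix

__all__ = [
    "RRBLUP",
    "GBLUP",
    "fit_rrblup",
    "fit_gblup",
    "predict_gebv",
    "line_accuracy_rpev",
    "NoGeneticSignalWarning",
]

_LOG2PI = np.log(2.0 * np.pi)


class NoGeneticSignalWarning(UserWarning):
    """The genetic variance component collapsed to (near) zero."""


def _as_fixed_design(n: int, fixed) -> np.ndarray:
    """Intercept column plus any user-supplied fixed covariates."""
    if fixed is None:
        return np.ones((n, 1))
    fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
    if fixed.shape[0] != n:
        raise ValueError("fixed design rows must match y")
    X = np.column_stack([np.ones(n), fixed])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    return X


def _kernel_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray, log_ratio_bounds=(-14.0, 14.0), ratio=None):
    """Exact REML for ``y = Xb + g + e``, ``g ~ N(0, K s2_g)``.

    Returns variance components, GLS fixed effects, and
    ``alpha = V^-1 (y - X beta)`` — everything a BLUP needs.  If
    ``ratio`` (``s2_g / s2_e``) is given the 1-D search is skipped and
    only the residual scale is profiled.
    """
    n, p = y.size, X.shape[1]
    d, U = eigh(K)
    d = np.clip(d, 0.0, None)  # PSD up to roundoff; clip instead of ridging
    yt = U.T @ y
    Xt = U.T @ X

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        v = lam * d + 1.0
        Xw = Xt / v[:, None]
        XtX = Xt.T @ Xw
        sign, logdet_x = np.linalg.slogdet(XtX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtX, Xw.T @ yt)
        r = yt - Xt @ beta
        q = float(np.sum(r * r / v))
        if q <= 0:
            return 1e12
        s2e = q / (n - p)
        return 0.5 * ((n - p) * np.log(s2e) + np.sum(np.log(v)) + logdet_x + (n - p) * (1.0 + _LOG2PI))

    if ratio is not None:
        if ratio <= 0:
            raise ValueError("variance ratio must be positive")
        log_lam = float(np.log(ratio))
        res_fun = neg_reml(log_lam)
    else:
        res = minimize_scalar(neg_reml, bounds=log_ratio_bounds, method="bounded", options={"xatol": 1e-10})
        log_lam = float(res.x)
        res_fun = float(res.fun)
    lam = np.exp(log_lam)
    v = lam * d + 1.0
    Xw = Xt / v[:, None]
    XtX = Xt.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yt)
    r = yt - Xt @ beta
    s2e = float(np.sum(r * r / v) / (n - p))
    s2g = lam * s2e
    alpha = U @ (r / (v * s2e))
    if log_lam <= log_ratio_bounds[0] + 1e-6:
        warnings.warn(
            "genetic variance collapsed to zero; returning a no-signal fit",
            NoGeneticSignalWarning,
            stacklevel=3,
        )
    return {
        "sigma2_g": s2g,
        "sigma2_e": s2e,
        "beta": beta,
        "alpha": alpha,
        "loglik": -res_fun,
        "mean_diag": float(np.mean(np.diag(K))),
    }


class RRBLUP(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP of marker effects.

    ``fit(X, y)`` takes a lines-by-markers genotype matrix coded
    ``{-1, 0, +1}`` (heterozygote 0; continuous dosages accepted).
    Marker columns are centered on their training means, so predictions
    for new lines are genetic deviations plus the training fixed-effect
    offset.

    Fitted attributes
    -----------------
    marker_effects_ : (M,) BLUPs of marker effects
    beta_ : fixed-effect estimates (intercept first)
    sigma2_u_, sigma2_e_ : REML variance components
    lambda2_ : ridge penalty ``sigma2_e / sigma2_u``
    gebv_ : genetic values of the training lines (deviations)
    h2_ : genomic heritability referenced to the training population
    """

    def __init__(self, center: bool = True, ratio: float | None = None):
        self.center = center
        self.ratio = ratio

    def fit(self, X, y, fixed=None):
        if isinstance(X, MarkerMatrix):
            self.marker_ids_ = X.marker_ids.copy()
            X = X.codes
        Z = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if np.any(~np.isfinite(Z)):
            raise ValueError("marker matrix contains missing values: impute first")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        n = y.size
        Xf = _as_fixed_design(n, fixed)
        self.col_means_ = Z.mean(axis=0) if self.center else np.zeros(Z.shape[1])
        W = Z - self.col_means_
        # scale the marker kernel exactly like the genomic relationship
        # matrix (2 sum p(1-p)); the ridge profile then coincides with the
        # G-BLUP profile on kinship from the same markers
        p = (Z.mean(axis=0) + 1.0) / 2.0
        c = 2.0 * float(np.sum(np.clip(p * (1.0 - p), 0.0, None)))
        if c <= 0:
            c = max(float(np.sum(W * W)) / max(Z.shape[0], 1), 1e-12)
        K0 = (W @ W.T) / c
        sol = _kernel_reml(y, Xf, K0, ratio=None if self.ratio is None else self.ratio * c)
        sol["sigma2_g"] = sol["sigma2_g"] / c
        sol["mean_diag"] = sol["mean_diag"] * c
        self.sigma2_u_ = sol["sigma2_g"]
        self.sigma2_e_ = sol["sigma2_e"]
        self.lambda2_ = np.inf if self.sigma2_u_ == 0 else self.sigma2_e_ / self.sigma2_u_
        self.beta_ = sol["beta"]
        self.marker_effects_ = self.sigma2_u_ * (W.T @ sol["alpha"])
        self.gebv_ = W @ self.marker_effects_
        self.offset_ = float(np.mean(Xf @ self.beta_))
        self.loglik_ = sol["loglik"]
        gvar = self.sigma2_u_ * sol["mean_diag"]
        self.h2_ = gvar / (gvar + self.sigma2_e_) if gvar + self.sigma2_e_ > 0 else 0.0
        self.n_features_in_ = Z.shape[1]
        return self

    def predict(self, X, include_offset: bool = True):
        if isinstance(X, MarkerMatrix):
            X = X.codes
        Z = np.asarray(X, dtype=float)
        gebv = (Z - self.col_means_) @ self.marker_effects_
        return gebv + (self.offset_ if include_offset else 0.0)


class GBLUP(BaseEstimator, RegressorMixin):
    """G-BLUP of line genetic values from a genomic relationship matrix.

    ``fit(X, y)`` takes the (training) kinship matrix as ``X``; use
    ``predict(K_cross)`` with the validation-by-training kinship block
    to predict unphenotyped lines.  Per-line prediction error variances
    (PEV) and the reliability-type accuracy
    ``r_PEV = sqrt(1 - PEV / (G_ii s2_G))`` are computed on request.
    """

    def __init__(self, compute_pev: bool = True, ratio: float | None = None):
        self.compute_pev = compute_pev
        self.ratio = ratio

    def fit(self, X, y, fixed=None):
        if isinstance(X, KinshipMatrix):
            self.line_ids_ = X.line_ids.copy()
            X = X.K
        K = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if K.shape != (n, n):
            raise ValueError("K must be square and aligned to y")
        Xf = _as_fixed_design(n, fixed)
        sol = _kernel_reml(y, Xf, K, ratio=self.ratio)
        self.sigma2_G_ = sol["sigma2_g"]
        self.sigma2_e_ = sol["sigma2_e"]
        self.beta_ = sol["beta"]
        self._alpha_ = sol["alpha"]
        self.g_ = self.sigma2_G_ * (K @ sol["alpha"])
        self.offset_ = float(np.mean(Xf @ self.beta_))
        self.loglik_ = sol["loglik"]
        gvar = self.sigma2_G_ * sol["mean_diag"]
        self.h2_ = gvar / (gvar + self.sigma2_e_) if gvar + self.sigma2_e_ > 0 else 0.0
        self._K_ = K
        self.n_features_in_ = n
        if self.compute_pev:
            V = self.sigma2_G_ * K + self.sigma2_e_ * np.eye(n)
            L = cho_factor(V, lower=True)
            Vi = cho_solve(L, np.eye(n))
            Vi_X = Vi @ Xf
            P = Vi - Vi_X @ np.linalg.solve(Xf.T @ Vi_X, Vi_X.T)
            self._P_ = P
            KP = K @ P
            self.pev_ = np.clip(
                self.sigma2_G_ * np.diag(K) - self.sigma2_G_**2 * np.einsum("ij,ji->i", KP, K),
                0.0,
                None,
            )
            if self.sigma2_G_ > 0:
                self.r_pev_ = line_accuracy_rpev(self.pev_, np.diag(K), self.sigma2_G_)
        return self

    def predict(self, X, include_offset: bool = True):
        """Predict genetic values from a new-by-training kinship block."""
        K_cross = np.atleast_2d(np.asarray(X, dtype=float))
        gebv = self.sigma2_G_ * (K_cross @ self._alpha_)
        return gebv + (self.offset_ if include_offset else 0.0)

    def predict_with_pev(self, K_cross, k_diag):
        """GEBVs and PEVs for unphenotyped lines.

        ``K_cross`` is the new-by-training kinship block and ``k_diag``
        the self-relationship of each new line.
        """
        if not hasattr(self, "_P_"):
            raise AttributeError("fit with compute_pev=True first")
        K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
        gebv = self.predict(K_cross)
        PK = self._P_ @ K_cross.T
        pev = self.sigma2_G_ * np.asarray(k_diag, dtype=float) - self.sigma2_G_**2 * np.einsum(
            "ij,ji->i", K_cross, PK
        )
        return gebv, np.clip(pev, 0.0, None)


def fit_rrblup(y, fixed_design, Z) -> RRBLUP:
    """Functional wrapper over :class:`RRBLUP`.

    ``Z`` may be a :class:`~cyclegs.markers.MarkerMatrix` or a raw codes
    array; ``fixed_design`` is the covariate block without intercept
    (pass ``None`` for intercept only).
    """
    return RRBLUP().fit(Z, y, fixed=fixed_design)


def fit_gblup(y, fixed_design, K) -> GBLUP:
    """Functional wrapper over :class:`GBLUP`."""
    return GBLUP().fit(K, y, fixed=fixed_design)


def predict_gebv(fit: RRBLUP, newlines: MarkerMatrix) -> pd.Series:
    """GEBVs of new lines from fitted marker effects.

    Marker sets are aligned by id; a mismatch is resolved by taking the
    intersection (with a warning), an empty intersection is an error.
    """
    if not hasattr(fit, "marker_effects_"):
        raise ValueError("fit must be a fitted RR-BLUP model with marker effects")
    if hasattr(fit, "marker_ids_"):
        train_ids = pd.Index(fit.marker_ids_)
        new_ids = pd.Index(newlines.marker_ids)
        common = train_ids.intersection(new_ids)
        if common.empty:
            raise ValueError("no markers shared between fit and new lines")
        if len(common) < len(train_ids) or len(common) < len(new_ids):
            warnings.warn(
                f"marker sets differ; using the {len(common)}-marker intersection",
                UserWarning,
                stacklevel=2,
            )
        ti = train_ids.get_indexer(common)
        ni = new_ids.get_indexer(common)
        gebv = (newlines.codes[:, ni] - fit.col_means_[ti]) @ fit.marker_effects_[ti] + fit.offset_
    else:
        gebv = fit.predict(newlines.codes)
    return pd.Series(gebv, index=newlines.line_ids, name="gebv")


def line_accuracy_rpev(pev, G_ii, sigma2_G):
    """Individual-line accuracy ``sqrt(1 - PEV / (G_ii s2_G))``.

    Values with ``PEV > G_ii s2_G`` are clamped to accuracy 0 with a
    warning; ``sigma2_G = 0`` is an error.
    """
    pev = np.asarray(pev, dtype=float)
    G_ii = np.asarray(G_ii, dtype=float)
    if sigma2_G <= 0:
        raise ValueError("sigma2_G must be positive")
    if np.any(G_ii * sigma2_G <= 0):
        raise ValueError("G_ii * sigma2_G must be positive")
    if np.any(pev < 0):
        raise ValueError("PEV must be non-negative")
    ratio = pev / (G_ii * sigma2_G)
    if np.any(ratio > 1.0):
        warnings.warn("PEV exceeds G_ii * sigma2_G for some lines; accuracy clamped to 0", UserWarning, stacklevel=2)
    out = np.sqrt(np.clip(1.0 - ratio, 0.0, None))
    return float(out) if out.ndim == 0 else out
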