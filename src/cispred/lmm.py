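"""Linear mixed model: REML variance components and BLUP prediction.

The model for a centered expression vector y and n × p cis-genotype matrix X
is

    y = Xβ + ε,   ε ~ N(0, σ_e² I),   β_j ~ N(0, σ_b² σ_e² / p),

equivalently y ~ N(1·b₀, σ_e² (σ_b² K + I)) with kinship K = X_c X_cᵀ / p on
column-standardized genotypes.  σ_b² is the genetic variance scaled by the
residual variance, so the narrow-sense heritability is
h² = σ_b² / (σ_b² + 1).

REML maximizes the restricted likelihood over the single ratio σ_b² on a log
scale (default bounds [1e-5, 1e5]); σ_e² and the intercept are profiled out
in closed form after a single eigendecomposition of K.  Prediction for new
individuals is the best linear unbiased prediction (BLUP), available in two
algebraically identical forms:

* effect space:  X_test β̂ with β̂ = (σ_b²/p) X_trainᵀ (σ_b² K + I)⁻¹ ỹ
* kinship space: σ_b² K_test,train (σ_b² K + I)⁻¹ ỹ

where ỹ is the training phenotype minus its GLS intercept.  The effect-space
β̂ equals ridge regression with penalty p/σ_b².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import standardize_columns

__all__ = [
    "Kinship",
    "VarianceComponents",
    "compute_kinship",
    "LinearMixedModel",
    "reml_fit",
    "blup_predict",
]

logger = logging.getLogger(__name__)


@dataclass
class Kinship:
    """An n × n relatedness matrix and how it was built."""

    matrix: np.ndarray
    construction: str = "XX^T/p"

    def validate(self) -> None:
        K = self.matrix
        if not np.allclose(K, K.T, atol=1e-12):
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh(K)
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError("kinship matrix is not positive semi-definite")


@dataclass
class VarianceComponents:
    """REML estimates; sigma_b2 is dimensionless (scaled by sigma_e2)."""

    sigma_b2: float
    sigma_e2: float
    h2: float
    boundary: bool = False
    reml_loglik: float = float("nan")


def compute_kinship(X, standardize: bool = True) -> Kinship:
    """K = X_c X_cᵀ / p on (by default) column-standardized genotypes.

    Zero-variance SNP columns are dropped with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one SNP")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance SNP columns", (~keep).sum())
        X = X[:, keep]
    if standardize:
        Xc, _, _ = standardize_columns(X)
    else:
        Xc = X - X.mean(axis=0)
    p = Xc.shape[1]
    return Kinship(matrix=Xc @ Xc.T / p, construction="XX^T/p" if standardize else "centered XX^T/p")


def _reml_profile(log_delta, s, yt, wt, n):
    """Profiled REML log-likelihood at σ_b² = exp(log_delta).

    ``s``: eigenvalues of K; ``yt``/``wt``: phenotype and intercept column
    rotated into the eigenbasis.
    """
    delta = math.exp(log_delta)
    d = delta * s + 1.0
    A = float(np.sum(wt * wt / d))  # Wᵀ V⁻¹ W (intercept)
    B = float(np.sum(wt * yt / d))
    C = float(np.sum(yt * yt / d))
    ypy = C - B * B / A
    if ypy <= 0:
        return -np.inf
    df = n - 1
    return -0.5 * (df * math.log(ypy / df) + float(np.sum(np.log(d))) + math.log(A) + df)


class LinearMixedModel(RegressorMixin, BaseEstimator):
    """Ridge-type genomic prediction via REML + BLUP.

    Parameters
    ----------
    standardize : bool, default True
        Standardize genotype columns (training statistics reused at predict
        time); otherwise columns are only centered.
    log_bounds : tuple, default (log 1e-5, log 1e5)
        Search interval for log σ_b².

    Attributes
    ----------
    sigma_b2_, sigma_e2_, h2_ : variance components (h² = σ_b²/(σ_b²+1))
    boundary_ : True when the optimizer stopped at a search bound
    beta_ : (p,) effect-space BLUP coefficients on the standardized scale
    """

    def __init__(self, standardize: bool = True, log_bounds=(math.log(1e-5), math.log(1e5))):
        self.standardize = standardize
        self.log_bounds = log_bounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if n < 3 or X.shape[0] != n:
            raise ValueError("need n >= 3 aligned rows in X and y")
        if self.standardize:
            Xc, means, scales = standardize_columns(X)
        else:
            means = X.mean(axis=0)
            scales = np.ones(X.shape[1])
            Xc = X - means
        p = Xc.shape[1]
        K = Xc @ Xc.T / p
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        yt = U.T @ y
        wt = U.T @ np.ones(n)

        lo, hi = self.log_bounds
        # coarse scan guards against local optima, Brent polishes
        grid = np.linspace(lo, hi, 60)
        vals = np.array([_reml_profile(g, s, yt, wt, n) for g in grid])
        g0 = grid[int(np.argmax(vals))]
        a, b = max(lo, g0 - (hi - lo) / 59), min(hi, g0 + (hi - lo) / 59)
        res = minimize_scalar(
            lambda t: -_reml_profile(t, s, yt, wt, n), bounds=(a, b), method="bounded",
            options={"xatol": 1e-10},
        )
        log_delta = float(res.x)
        boundary = log_delta - lo < 1e-3 or hi - log_delta < 1e-3
        delta = math.exp(log_delta)

        d = delta * s + 1.0
        A = float(np.sum(wt * wt / d))
        B = float(np.sum(wt * yt / d))
        intercept = B / A  # GLS intercept
        resid_t = yt - intercept * wt
        ypy = float(np.sum(resid_t * resid_t / d))
        sigma_e2 = ypy / (n - 1)

        self.sigma_b2_ = delta
        self.sigma_e2_ = sigma_e2
        self.h2_ = delta / (delta + 1.0)
        self.boundary_ = bool(boundary)
        self.reml_loglik_ = float(_reml_profile(log_delta, s, yt, wt, n))
        self.intercept_ = float(intercept)
        self.means_ = means
        self.scales_ = scales
        self.p_ = p
        # V⁻¹(y − 1·b₀) in the original basis, for both BLUP routes
        self._vinv_resid = U @ (resid_t / d)
        self._X_train_std = Xc
        self.beta_ = (delta / p) * (Xc.T @ self._vinv_resid)
        return self

    @property
    def variance_components_(self) -> VarianceComponents:
        return VarianceComponents(
            sigma_b2=self.sigma_b2_,
            sigma_e2=self.sigma_e2_,
            h2=self.h2_,
            boundary=self.boundary_,
            reml_loglik=self.reml_loglik_,
        )

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.means_.shape[0]:
            raise ValueError("test genotypes do not align with training SNPs")
        return (X - self.means_) / self.scales_

    def predict(self, X, route: str = "effects"):
        Xt = self._transform(X)
        if route == "effects":
            return Xt @ self.beta_ + self.intercept_
        if route == "kinship":
            K_xt = Xt @ self._X_train_std.T / self.p_
            return self.sigma_b2_ * (K_xt @ self._vinv_resid) + self.intercept_
        raise ValueError("route must be 'effects' or 'kinship'")


def reml_fit(X, y, standardize: bool = True) -> VarianceComponents:
    """REML variance components for the single-ratio LMM."""
    return LinearMixedModel(standardize=standardize).fit(X, y).variance_components_


def blup_predict(vc: VarianceComponents, X_train, y_train, X_test, standardize: bool = True):
    """BLUP prediction at externally supplied variance components."""
    model = LinearMixedModel(standardize=standardize)
    # fit for the preprocessing state, then override the variance ratio
    model.fit(X_train, y_train)
    if not math.isclose(vc.sigma_b2, model.sigma_b2_, rel_tol=1e-6):
        model = _refit_at(model, X_train, y_train, vc.sigma_b2, standardize)
    return model.predict(X_test)


def _refit_at(model, X_train, y_train, sigma_b2, standardize):
    eps = 1e-9
    m = LinearMixedModel(
        standardize=standardize,
        log_bounds=(math.log(max(sigma_b2, 1e-12)) - eps, math.log(max(sigma_b2, 1e-12)) + eps),
    )
    return m.fit(X_train, y_train)
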