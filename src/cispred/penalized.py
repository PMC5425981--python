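"""Lasso and elastic net by cyclic coordinate descent.

The fitted objective is, for an n-vector ``y`` and n × p design ``X``,

    Q(β) = (1/n) (y − Xβ)ᵀ(y − Xβ) + Σ_j P_λ(|β_j|)
    Lasso:  P_λ = λ|β|
    ENET:   P_λ = λ(α|β| + (1 − α)β²)

Note the mean squared error carries no factor 1/2 and the quadratic penalty
term is not halved — this differs from the glmnet/scikit-learn convention by
a factor of two, so the per-coordinate update is a soft-threshold at λα/2:

    β_j ← S(ρ_j, λα/2) / (1 + λ(1 − α)),   ρ_j = x_jᵀ r_j / n

for standardized columns (x_jᵀx_j/n = 1) and partial residual r_j.  The null
model is optimal for λ ≥ 2·max_j|x_jᵀy|/(nα), which sets the top of the
default λ path.

λ is tuned by k-fold cross-validation (default 100 folds, clamped to n),
minimizing the pooled held-out squared error; ties break toward larger λ.
Following the glmnet convention the default path depth is 0.01·λ_max when
p ≥ n (1e-3·λ_max otherwise), and the CV fits run at a relaxed tolerance
(max(tol, 1e-3) on the coefficient change) — λ selection is insensitive to
this while the final model is refit at the full tolerance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import standardize_columns

__all__ = [
    "PenaltyConfig",
    "PenalizedFit",
    "ElasticNetCD",
    "LassoCD",
    "enet_objective",
    "coordinate_descent_fit",
    "cv_select_lambda",
    "lambda_path",
    "kkt_violation",
]


def enet_objective(X, y, beta, lam: float, alpha: float = 1.0) -> float:
    """Evaluate the penalized objective Q(β) exactly as written above."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[1] != beta.shape[0]:
        raise ValueError("dimension mismatch between X, y and beta")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    resid = y - X @ beta
    mse = float(resid @ resid) / X.shape[0]
    penalty = lam * (alpha * np.abs(beta).sum() + (1.0 - alpha) * float(beta @ beta))
    return mse + penalty


@njit(cache=True)
def _cd_kernel(X, y, beta, r, lam, alpha, max_iter, tol):  # pragma: no cover
    """Cyclic coordinate descent sweeps; X columns must satisfy xᵀx/n = 1.

    ``beta`` and the residual ``r = y - X @ beta`` are updated in place.
    Returns (number of sweeps run, converged flag).
    """
    n, p = X.shape
    thr = lam * alpha / 2.0
    denom = 1.0 + lam * (1.0 - alpha)
    sweeps = 0
    converged = False
    for _ in range(max_iter):
        sweeps += 1
        delta_max = 0.0
        for j in range(p):
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += X[i, j] * r[i]
            rho = rho / n + bj
            if rho > thr:
                bnew = (rho - thr) / denom
            elif rho < -thr:
                bnew = (rho + thr) / denom
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bnew
                ad = abs(d)
                if ad > delta_max:
                    delta_max = ad
        if delta_max < tol:
            converged = True
            break
    return sweeps, converged


@njit(cache=True)
def _cd_gram_kernel(G, c, n, beta, q, lam, alpha, max_iter, tol):  # pragma: no cover
    """Coordinate descent via covariance updates: G = XᵀX, c = Xᵀy, q = Gβ.

    Full sweeps alternate with sweeps over the active (nonzero) set;
    convergence requires a full sweep with max|Δβ| < tol.  ``beta`` and ``q``
    are updated in place.
    """
    p = G.shape[0]
    thr = lam * alpha / 2.0
    sweeps = 0
    converged = False
    while sweeps < max_iter:
        sweeps += 1
        delta_max = 0.0
        for j in range(p):
            bj = beta[j]
            gjj = G[j, j]
            rho = (c[j] - q[j] + gjj * bj) / n
            denom = gjj / n + lam * (1.0 - alpha)
            if rho > thr:
                bnew = (rho - thr) / denom
            elif rho < -thr:
                bnew = (rho + thr) / denom
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                beta[j] = bnew
                for k in range(p):
                    q[k] += G[k, j] * d
                ad = abs(d)
                if ad > delta_max:
                    delta_max = ad
        if delta_max < tol:
            converged = True
            break
        while sweeps < max_iter:
            sweeps += 1
            delta_max = 0.0
            for j in range(p):
                bj = beta[j]
                if bj == 0.0:
                    continue
                gjj = G[j, j]
                rho = (c[j] - q[j] + gjj * bj) / n
                denom = gjj / n + lam * (1.0 - alpha)
                if rho > thr:
                    bnew = (rho - thr) / denom
                elif rho < -thr:
                    bnew = (rho + thr) / denom
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    beta[j] = bnew
                    for k in range(p):
                        q[k] += G[k, j] * d
                    ad = abs(d)
                    if ad > delta_max:
                        delta_max = ad
            if delta_max < tol:
                break
    return sweeps, converged


_GRAM_MAX_P = 2000  # above this the p×p Gram matrix is not worth its memory


def _run_cd_gram(G, c, n, lam, alpha, beta0, max_iter, tol):
    beta = np.array(beta0, dtype=float, copy=True)
    q = G @ beta
    sweeps, converged = _cd_gram_kernel(
        G, c, float(n), beta, q, float(lam), float(alpha), int(max_iter), float(tol)
    )
    return beta, sweeps, converged


def _run_cd(Xs, y, lam, alpha, beta0, max_iter, tol):
    Xs = np.asarray(Xs, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if Xs.shape[1] <= _GRAM_MAX_P:
        G = Xs.T @ Xs
        return _run_cd_gram(G, Xs.T @ y, Xs.shape[0], lam, alpha, beta0, max_iter, tol)
    Xs = np.asfortranarray(Xs)
    beta = np.array(beta0, dtype=float, copy=True)
    r = y - Xs @ beta
    sweeps, converged = _cd_kernel(
        Xs, y, beta, r, float(lam), float(alpha), int(max_iter), float(tol)
    )
    return beta, sweeps, converged


def kkt_violation(Xs, y, beta, lam: float, alpha: float) -> float:
    """Maximum violation of the subgradient optimality conditions of Q."""
    Xs = np.asarray(Xs, dtype=float)
    n = Xs.shape[0]
    grad = -2.0 * Xs.T @ (y - Xs @ beta) / n + 2.0 * lam * (1.0 - alpha) * beta
    viol = np.where(
        beta != 0.0,
        np.abs(grad + lam * alpha * np.sign(beta)),
        np.maximum(np.abs(grad) - lam * alpha, 0.0),
    )
    return float(viol.max(initial=0.0))


def lambda_path(Xs, y, alpha: float, n_lambda: int = 100, min_ratio: float | None = None):
    """Geometric λ grid from the null-model threshold down to its min_ratio.

    ``min_ratio=None`` picks 0.01 when p ≥ n and 1e-3 otherwise.
    """
    n = Xs.shape[0]
    if min_ratio is None:
        min_ratio = 0.01 if Xs.shape[1] >= n else 1e-3
    lam_max = 2.0 * np.abs(Xs.T @ y).max() / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


@dataclass
class PenaltyConfig:
    """Tuning knobs for the penalized fit."""

    alpha: float = 0.5
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    n_folds: int = 100
    max_iter: int = 10_000
    tol: float = 1e-7
    seed: int = 0
    cv_rule: str = "min"  # or "1se"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g <= 0) or np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be positive, strictly decreasing")
            self.lambda_grid = g


@dataclass
class PenalizedFit:
    """Result of a single-λ coordinate-descent fit."""

    coefficients: np.ndarray
    lambda_selected: float
    objective_value: float
    n_nonzero: int
    converged: bool
    n_sweeps: int
    cv_curve: np.ndarray | None = None


class ElasticNetCD(RegressorMixin, BaseEstimator):
    """Elastic-net regression on the literal (unhalved) penalized objective.

    Parameters
    ----------
    alpha : float, default 0.5
        Penalty mix; 1 gives the Lasso, 0 pure ridge.
    lam : float or None
        Fixed penalty weight.  When None, selected by cross-validation.
    n_folds : int, default 100
        CV folds (clamped to n, i.e. leave-one-out for small samples).
    standardize : bool, default True
        Center y and scale X columns to unit variance internally;
        coefficients are reported on the original scale.
    cv_rule : {"min", "1se"}
        λ rule: the CV-error minimizer, or the largest λ within one standard
        error of it.

    Attributes
    ----------
    coef_ : (p,) fitted coefficients on the input scale
    intercept_ : float
    lambda_ : selected or fixed penalty weight
    cv_curve_ : per-λ mean held-out squared error (None for fixed λ)
    objective_ : Q(β) on the standardized problem
    n_nonzero_ : number of exactly nonzero coefficients
    converged_ : whether the final fit met the tolerance
    """

    def __init__(
        self,
        alpha: float = 0.5,
        lam: float | None = None,
        n_lambda: int = 100,
        lambda_min_ratio: float | None = None,
        n_folds: int = 100,
        max_iter: int = 10_000,
        tol: float = 1e-7,
        standardize: bool = True,
        cv_rule: str = "min",
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.lam = lam
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.n_folds = n_folds
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.cv_rule = cv_rule
        self.random_state = random_state

    def _preprocess(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        if self.standardize:
            Xs, means, scales = standardize_columns(X)
            ybar = y.mean()
        else:
            Xs, means, scales = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
            ybar = 0.0
        return Xs, y - ybar, means, scales, ybar

    def fit(self, X, y):
        Xs, yc, means, scales, ybar = self._preprocess(X, y)
        n = Xs.shape[0]
        if self.lam is None:
            lam, curve, grid = _cv_lambda(
                Xs,
                yc,
                alpha=self.alpha,
                n_lambda=self.n_lambda,
                min_ratio=self.lambda_min_ratio,
                n_folds=min(self.n_folds, n),
                max_iter=self.max_iter,
                tol=self.tol,
                seed=self.random_state,
                rule=self.cv_rule,
            )
            self.cv_curve_ = curve
            self.lambda_grid_ = grid
            # warm-started path down to the selected λ on the full data
            beta = np.zeros(Xs.shape[1])
            if Xs.shape[1] <= _GRAM_MAX_P:
                G, c = Xs.T @ Xs, Xs.T @ yc
                for l in grid[grid >= lam]:
                    beta, sweeps, conv = _run_cd_gram(
                        G, c, n, l, self.alpha, beta, self.max_iter, self.tol
                    )
            else:
                for l in grid[grid >= lam]:
                    beta, sweeps, conv = _run_cd(
                        Xs, yc, l, self.alpha, beta, self.max_iter, self.tol
                    )
        else:
            lam = float(self.lam)
            self.cv_curve_ = None
            self.lambda_grid_ = None
            beta, sweeps, conv = _run_cd(
                Xs, yc, lam, self.alpha, np.zeros(Xs.shape[1]), self.max_iter, self.tol
            )
        if not conv:
            warnings.warn("coordinate descent did not converge", RuntimeWarning)
        self.converged_ = bool(conv)
        self.n_sweeps_ = int(sweeps)
        self.lambda_ = float(lam)
        self.coef_std_ = beta
        self.coef_ = beta / scales
        self.intercept_ = float(ybar - self.coef_ @ means)
        self.objective_ = enet_objective(Xs, yc, beta, lam, self.alpha)
        self.n_nonzero_ = int(np.count_nonzero(beta))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def to_fit(self) -> PenalizedFit:
        return PenalizedFit(
            coefficients=self.coef_,
            lambda_selected=self.lambda_,
            objective_value=self.objective_,
            n_nonzero=self.n_nonzero_,
            converged=self.converged_,
            n_sweeps=self.n_sweeps_,
            cv_curve=self.cv_curve_,
        )


class LassoCD(ElasticNetCD):
    """Lasso regression (elastic net with mixing weight fixed at 1)."""

    def __init__(
        self,
        lam: float | None = None,
        n_lambda: int = 100,
        lambda_min_ratio: float | None = None,
        n_folds: int = 100,
        max_iter: int = 10_000,
        tol: float = 1e-7,
        standardize: bool = True,
        cv_rule: str = "min",
        random_state: int = 0,
    ):
        super().__init__(
            alpha=1.0,
            lam=lam,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            n_folds=n_folds,
            max_iter=max_iter,
            tol=tol,
            standardize=standardize,
            cv_rule=cv_rule,
            random_state=random_state,
        )


def _cv_lambda(Xs, yc, alpha, n_lambda, min_ratio, n_folds, max_iter, tol, seed, rule):
    n = Xs.shape[0]
    if n < n_folds:
        raise ValueError(f"n={n} is smaller than n_folds={n_folds}")
    grid = lambda_path(Xs, yc, alpha, n_lambda, min_ratio)
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(n_folds), np.diff(np.linspace(0, n, n_folds + 1).astype(int)))
    fold_of = fold_of[rng.permutation(n)]

    errs = np.empty((len(grid), n))  # per-observation held-out squared error
    for k in range(n_folds):
        test = fold_of == k
        Xtr, ytr = Xs[~test], yc[~test]
        # re-standardize within the training fold
        Xtr, m, s = standardize_columns(Xtr)
        ytr_bar = ytr.mean()
        Xte = (Xs[test] - m) / s
        yte = yc[test]
        beta = np.zeros(Xs.shape[1])
        cv_tol = max(tol, 1e-3)  # selection-only fits; final model refits at tol
        use_gram = Xs.shape[1] <= _GRAM_MAX_P
        if use_gram:
            G = Xtr.T @ Xtr
            c = Xtr.T @ (ytr - ytr_bar)
        for i, lam in enumerate(grid):
            if use_gram:
                beta, _, _ = _run_cd_gram(
                    G, c, Xtr.shape[0], lam, alpha, beta, max_iter, cv_tol
                )
            else:
                beta, _, _ = _run_cd(Xtr, ytr - ytr_bar, lam, alpha, beta, max_iter, cv_tol)
            errs[i, test] = (yte - (Xte @ beta + ytr_bar)) ** 2
    curve = errs.mean(axis=1)
    if rule == "1se":
        se = errs.std(axis=1, ddof=1) / np.sqrt(n)
        best = int(np.argmin(curve))
        idx = np.flatnonzero(curve <= curve[best] + se[best])
        lam_sel = float(grid[idx.min()])
    else:
        lam_sel = float(grid[int(np.argmin(curve))])
    return lam_sel, curve, grid


def coordinate_descent_fit(
    X, y, lam: float, alpha: float = 1.0, config: PenaltyConfig | None = None
) -> PenalizedFit:
    """Single-λ coordinate-descent fit on a preprocessed design.

    Assumes ``y`` centered and the columns of ``X`` standardized (unit 1/n
    variance); no internal rescaling is applied.
    """
    cfg = config or PenaltyConfig(alpha=alpha)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta, sweeps, conv = _run_cd(X, y, lam, alpha, np.zeros(X.shape[1]), cfg.max_iter, cfg.tol)
    if not conv:
        warnings.warn("coordinate descent did not converge", RuntimeWarning)
    return PenalizedFit(
        coefficients=beta,
        lambda_selected=float(lam),
        objective_value=enet_objective(X, y, beta, lam, alpha),
        n_nonzero=int(np.count_nonzero(beta)),
        converged=bool(conv),
        n_sweeps=int(sweeps),
    )


def cv_select_lambda(X, y, config: PenaltyConfig | None = None):
    """Cross-validated λ selection; returns (lambda_selected, cv_curve)."""
    cfg = config or PenaltyConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < cfg.n_folds:
        raise ValueError(f"n={n} is smaller than n_folds={cfg.n_folds}")
    Xs, _, _ = standardize_columns(X)
    yc = y - y.mean()
    lam, curve, _grid = _cv_lambda(
        Xs,
        yc,
        alpha=cfg.alpha,
        n_lambda=cfg.n_lambda,
        min_ratio=cfg.lambda_min_ratio,
        n_folds=cfg.n_folds,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        seed=cfg.seed,
        rule=cfg.cv_rule,
    )
    return lam, curve


def save_fit_tsv(fit: PenalizedFit, snp_ids, path, alpha: float) -> None:
    """Write per-SNP coefficients as TSV with a JSON sidecar of fit metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("snp_id\tbeta\n")
        for sid, b in zip(snp_ids, fit.coefficients):
            fh.write(f"{sid}\t{b:.10g}\n")
    sidecar = {
        "lambda": fit.lambda_selected,
        "alpha": alpha,
        "objective": fit.objective_value,
        "n_nonzero": fit.n_nonzero,
        "converged": fit.converged,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
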