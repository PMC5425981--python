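"""Bayesian sparse linear mixed model (spike-and-slab + polygenic) via MCMC.

The model for centered expression y and standardized cis-genotypes X is

    y = X β̃ + u + ε,    ε ~ N(0, σ_e² I)
    u ~ N(0, σ_b² σ_e² K),          K = X Xᵀ / p
    β̃_j ~ π N(0, σ_a² σ_e²) + (1 − π) δ₀

a hybrid of the polygenic LMM (u, small effects on every SNP) and a sparse
model (β̃, large effects on a few SNPs selected by the indicator γ).

Inference is Metropolis-within-Gibbs over the inclusion vector γ
(add / remove / swap proposals, with additions drawn preferentially among
SNPs ranked by marginal association — a standard mixing device for sparse
samplers, accounted for in the Hastings ratio) and random-walk moves on
(log π, log σ_a², log σ_b²), with β̃_γ and σ_e² integrated out analytically:
conditional on (γ, σ_a², σ_b²) the marginal likelihood is

    p(y | γ, σ_a², σ_b²) ∝ |H|^(−1/2) (yᵀH⁻¹y)^(−n/2),
    H = σ_a² X_γ X_γᵀ + σ_b² K + I,

computed after a single eigendecomposition of K with a Woodbury identity of
rank |γ|, so each iteration costs O(n·|γ|² + |γ|³).  Hyperpriors: log π
uniform on [log(1/p), 0]; log₁₀ σ_a², log₁₀ σ_b² uniform on [−5, 5].

Posterior summaries are Rao-Blackwellized conditional means accumulated over
the retained draws; prediction for new individuals is
X_test (E[β̃|y] + E[β|y]) where u = Xβ is the effect-space representation of
the polygenic part.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import standardize_columns

__all__ = ["BslmmPrior", "McmcConfig", "BslmmPosterior", "BSLMM", "mcmc_fit", "bslmm_predict"]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


@dataclass
class BslmmPrior:
    """Hyperprior specification; ``*_fixed = None`` means sampled."""

    pi_fixed: float | None = None
    sigma_a2_fixed: float | None = None
    sigma_b2_fixed: float | None = None
    log10_sigma_a2_bounds: tuple[float, float] = (-5.0, 5.0)
    log10_sigma_b2_bounds: tuple[float, float] = (-5.0, 5.0)

    def __post_init__(self) -> None:
        if self.pi_fixed is not None and not 0.0 <= self.pi_fixed <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        for v in (self.sigma_a2_fixed, self.sigma_b2_fixed):
            if v is not None and v < 0:
                raise ValueError("variances must be non-negative")


@dataclass
class McmcConfig:
    """Chain lengths; defaults follow the simulation-study settings."""

    n_burnin: int = 10_000
    n_sampling: int = 10_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_burnin, self.n_sampling, self.thin) < 1:
            raise ValueError("all MCMC counts must be >= 1")

    @classmethod
    def data_mode(cls, seed: int = 0) -> "McmcConfig":
        """Shorter burn-in used when fitting observed (non-simulated) genes."""
        return cls(n_burnin=2_000, n_sampling=10_000, seed=seed)


@dataclass
class BslmmPosterior:
    """Post-burn-in posterior summaries of one chain."""

    mean_sparse_effects: np.ndarray
    mean_polygenic_effects: np.ndarray
    inclusion_prob: np.ndarray
    pve_draws: np.ndarray
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    n_draws: int = 0
    traces: dict[str, np.ndarray] = field(default_factory=dict)


class _MarginalLikelihood:
    """Marginal log-likelihood machinery in the eigenbasis of K."""

    def __init__(self, Xt: np.ndarray, yt: np.ndarray, s: np.ndarray):
        self.Xt = Xt  # U'X, n × p
        self.yt = yt  # U'y
        self.s = s    # eigenvalues of K
        self.n, self.p = Xt.shape

    def evaluate(self, gamma: np.ndarray, sa2: float, sb2: float):
        """Return (loglik, aux) or (-inf, None) on numerical failure."""
        d = sb2 * self.s + 1.0
        dinv = 1.0 / d
        logdet = float(np.sum(np.log(d)))
        dy = dinv * self.yt
        quad = float(self.yt @ dy)
        aux = {"dinv": dinv, "gamma": gamma, "sa2": sa2, "sb2": sb2}
        if gamma.size:
            Xg = self.Xt[:, gamma]
            DXg = dinv[:, None] * Xg
            G = Xg.T @ DXg
            M = sa2 * G
            M[np.diag_indices_from(M)] += 1.0
            try:
                cho = cho_factor(M, lower=True)
            except np.linalg.LinAlgError:
                return -np.inf, None
            v = Xg.T @ dy
            w = cho_solve(cho, v)
            quad = quad - sa2 * float(v @ w)
            logdet += 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
            if quad <= 0 or not np.isfinite(quad):
                return -np.inf, None
            aux.update(cho=cho, v=v, w=w, DXg=DXg, Xg=Xg)
        aux["quad"] = quad
        loglik = -0.5 * logdet - 0.5 * self.n * math.log(quad)
        return loglik, aux

    def summaries(self, aux):
        """Conditional posterior means and trace(H⁻¹) for the current state."""
        dinv, sa2, sb2, gamma = aux["dinv"], aux["sa2"], aux["sb2"], aux["gamma"]
        h = dinv * self.yt
        tr_hinv = float(np.sum(dinv))
        if gamma.size:
            # H̃⁻¹ỹ via Woodbury; M⁻¹ pieces reused from the likelihood
            h = h - sa2 * (aux["DXg"] @ aux["w"])
            G2 = aux["DXg"].T @ aux["DXg"]
            tr_hinv -= sa2 * float(np.trace(cho_solve(aux["cho"], G2)))
        beta_poly = (sb2 / self.p) * (self.Xt.T @ h)
        beta_sparse = np.zeros(self.p)
        if gamma.size:
            beta_sparse[gamma] = sa2 * (aux["Xg"].T @ h)
        gt = self.Xt @ (beta_poly + beta_sparse)
        var_g = float(gt @ gt) / self.n
        return beta_sparse, beta_poly, var_g, tr_hinv


class BSLMM(RegressorMixin, BaseEstimator):
    """Hybrid sparse + polygenic regression fitted by MCMC.

    Parameters
    ----------
    n_burnin, n_sampling, thin : chain control (defaults sized for desk-scale
        studies; see :class:`McmcConfig` for the larger presets).
    pi_fixed, sigma_a2_fixed, sigma_b2_fixed : pin a hyperparameter instead
        of sampling it.  ``pi_fixed=0`` disables the sparse part entirely and
        the model collapses to the LMM.
    s_max : hard cap on the number of included large-effect SNPs.
    move_probs : base probabilities of (add, remove, swap) proposals on γ.

    Attributes
    ----------
    posterior_ : :class:`BslmmPosterior`
    coef_ : (p,) posterior-mean total effects on the input genotype scale
    """

    def __init__(
        self,
        n_burnin: int = 2_000,
        n_sampling: int = 2_000,
        thin: int = 1,
        pi_fixed: float | None = None,
        sigma_a2_fixed: float | None = None,
        sigma_b2_fixed: float | None = None,
        log10_sigma_a2_bounds: tuple[float, float] = (-5.0, 5.0),
        log10_sigma_b2_bounds: tuple[float, float] = (-5.0, 5.0),
        s_max: int = 300,
        move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2),
        gamma_moves_per_iter: int = 5,
        step_log_pi: float = 0.5,
        step_log_sigma: float = 0.7,
        random_state: int = 0,
    ):
        self.n_burnin = n_burnin
        self.n_sampling = n_sampling
        self.thin = thin
        self.pi_fixed = pi_fixed
        self.sigma_a2_fixed = sigma_a2_fixed
        self.sigma_b2_fixed = sigma_b2_fixed
        self.log10_sigma_a2_bounds = log10_sigma_a2_bounds
        self.log10_sigma_b2_bounds = log10_sigma_b2_bounds
        self.s_max = s_max
        self.move_probs = move_probs
        self.gamma_moves_per_iter = gamma_moves_per_iter
        self.step_log_pi = step_log_pi
        self.step_log_sigma = step_log_sigma
        self.random_state = random_state

    # -- prior -------------------------------------------------------------

    def _log_prior_gamma(self, m: int, p: int, log_pi: float) -> float:
        pi = math.exp(log_pi)
        if pi >= 1.0:  # degenerate prior: every SNP included
            return 0.0 if m == p else -np.inf
        return m * log_pi + (p - m) * math.log1p(-pi)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        config = McmcConfig(
            n_burnin=self.n_burnin, n_sampling=self.n_sampling, thin=self.thin,
            seed=self.random_state,
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y are not aligned")
        rng = np.random.default_rng(self.random_state)

        Xs, means, scales = standardize_columns(X)
        ybar = y.mean()
        yc = y - ybar
        K = Xs @ Xs.T / p
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        lik = _MarginalLikelihood(U.T @ Xs, U.T @ yc, s)

        sparse_enabled = not (self.pi_fixed is not None and self.pi_fixed == 0.0)
        log_pi_lo, log_pi_hi = math.log(1.0 / p), 0.0
        sa_lo, sa_hi = (b * LN10 for b in self.log10_sigma_a2_bounds)
        sb_lo, sb_hi = (b * LN10 for b in self.log10_sigma_b2_bounds)

        # initial state
        log_pi = (
            math.log(self.pi_fixed) if (self.pi_fixed not in (None, 0.0))
            else min(math.log(min(5, p) / p), log_pi_hi)
        )
        sa2 = self.sigma_a2_fixed if self.sigma_a2_fixed is not None else 1.0
        if self.sigma_b2_fixed is not None:
            sb2 = self.sigma_b2_fixed
        else:
            # start the polygenic variance near its marginal-likelihood peak
            # (empty γ), shortening burn-in considerably
            cand = np.geomspace(1e-4, 1e4, 33)
            empty = np.array([], dtype=int)
            sb2 = float(
                max(cand, key=lambda v: lik.evaluate(empty, sa2, float(v))[0])
            )
        # marginal-association ranking drives the weighted add proposals
        marg = np.abs(Xs.T @ yc)
        rank = np.empty(p, dtype=float)
        rank[np.argsort(-marg)] = np.arange(p)
        w_rank = 1.0 / (rank + 10.0)
        if self.pi_fixed is not None and self.pi_fixed >= 1.0:
            if p > self.s_max:
                raise ValueError("pi=1 requires p <= s_max (all SNPs included)")
            gamma = np.arange(p)
        else:
            gamma = np.array([], dtype=int)
        loglik, aux = lik.evaluate(gamma, sa2, sb2)
        logpost = loglik + (self._log_prior_gamma(0, p, log_pi) if sparse_enabled else 0.0)

        move_names = ("add", "remove", "swap", "hyper")
        proposed = dict.fromkeys(move_names, 0)
        accepted = dict.fromkeys(move_names, 0)
        n_singular = 0

        sum_sparse = np.zeros(p)
        sum_poly = np.zeros(p)
        sum_incl = np.zeros(p)
        pve_draws: list[float] = []
        traces = {k: [] for k in ("log_pi", "sigma_a2", "sigma_b2", "m", "sigma_e2")}
        n_draws = 0
        cached_summary = None

        total_iters = config.n_burnin + config.n_sampling
        in_gamma = np.zeros(p, dtype=bool)
        in_gamma[gamma] = True
        w_ex_sum = float(w_rank[~in_gamma].sum())

        for it in range(total_iters):
            # --- γ moves (several Metropolis proposals per iteration, as
            # is standard for indicator-vector samplers) ------------------
            for _ in range(self.gamma_moves_per_iter if sparse_enabled else 0):
                m = gamma.size
                can_add = m < min(p, self.s_max)
                can_rem = m > 0
                can_swap = 0 < m < p
                probs = np.array(
                    [
                        self.move_probs[0] if can_add else 0.0,
                        self.move_probs[1] if can_rem else 0.0,
                        self.move_probs[2] if can_swap else 0.0,
                    ]
                )
                if probs.sum() > 0:
                    probs /= probs.sum()
                    kind = int(rng.choice(3, p=probs))
                    new_gamma, log_hastings, dw = self._propose_gamma(
                        kind, gamma, in_gamma, p, probs, rng, w_rank, w_ex_sum
                    )
                    name = move_names[kind]
                    proposed[name] += 1
                    new_loglik, new_aux = lik.evaluate(new_gamma, sa2, sb2)
                    if not np.isfinite(new_loglik):
                        n_singular += 1
                    else:
                        new_logpost = new_loglik + self._log_prior_gamma(
                            new_gamma.size, p, log_pi
                        )
                        if math.log(rng.random()) < new_logpost - logpost + log_hastings:
                            accepted[name] += 1
                            in_gamma[gamma] = False
                            gamma, loglik, aux, logpost = new_gamma, new_loglik, new_aux, new_logpost
                            in_gamma[gamma] = True
                            w_ex_sum += dw
                            cached_summary = None

            # --- hyperparameter move -------------------------------------
            free_pi = sparse_enabled and self.pi_fixed is None
            free_sa = sparse_enabled and self.sigma_a2_fixed is None
            free_sb = self.sigma_b2_fixed is None
            if free_pi or free_sa or free_sb:
                proposed["hyper"] += 1
                new_log_pi = log_pi + (rng.normal(0, self.step_log_pi) if free_pi else 0.0)
                new_sa2 = sa2 * math.exp(rng.normal(0, self.step_log_sigma)) if free_sa else sa2
                new_sb2 = sb2 * math.exp(rng.normal(0, self.step_log_sigma)) if free_sb else sb2
                ok = (
                    (not free_pi or log_pi_lo <= new_log_pi <= log_pi_hi)
                    and (not free_sa or sa_lo <= math.log(new_sa2) <= sa_hi)
                    and (not free_sb or sb_lo <= math.log(new_sb2) <= sb_hi)
                )
                if ok:
                    new_loglik, new_aux = lik.evaluate(gamma, new_sa2, new_sb2)
                    if not np.isfinite(new_loglik):
                        n_singular += 1
                    else:
                        prior_term = (
                            self._log_prior_gamma(gamma.size, p, new_log_pi)
                            if sparse_enabled
                            else 0.0
                        )
                        new_logpost = new_loglik + prior_term
                        # log-scale random walks are symmetric in the sampled
                        # coordinates (flat priors there), so no Jacobian term
                        if math.log(rng.random()) < new_logpost - logpost:
                            accepted["hyper"] += 1
                            log_pi, sa2, sb2 = new_log_pi, new_sa2, new_sb2
                            loglik, aux, logpost = new_loglik, new_aux, new_logpost
                            cached_summary = None

            # --- retain draw ---------------------------------------------
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                if cached_summary is None:
                    cached_summary = lik.summaries(aux)
                beta_sparse, beta_poly, var_g, tr_hinv = cached_summary
                sigma_e2 = aux["quad"] / 2.0 / rng.standard_gamma(n / 2.0)
                num = var_g + sigma_e2 * max(n - tr_hinv, 0.0) / n
                pve = num / (num + sigma_e2)
                pve_draws.append(min(max(pve, 0.0), 1.0))
                sum_sparse += beta_sparse
                sum_poly += beta_poly
                sum_incl[gamma] += 1.0
                traces["log_pi"].append(log_pi)
                traces["sigma_a2"].append(sa2)
                traces["sigma_b2"].append(sb2)
                traces["m"].append(gamma.size)
                traces["sigma_e2"].append(sigma_e2)
                n_draws += 1

        if n_singular:
            logger.warning("rejected %d proposals with singular subset matrices", n_singular)
        rates = {
            k: (accepted[k] / proposed[k] if proposed[k] else float("nan"))
            for k in move_names
        }
        self.posterior_ = BslmmPosterior(
            mean_sparse_effects=sum_sparse / n_draws,
            mean_polygenic_effects=sum_poly / n_draws,
            inclusion_prob=sum_incl / n_draws,
            pve_draws=np.array(pve_draws),
            acceptance_rates=rates,
            n_draws=n_draws,
            traces={k: np.array(v) for k, v in traces.items()},
        )
        self.means_ = means
        self.scales_ = scales
        self.ybar_ = float(ybar)
        coef_std = self.posterior_.mean_sparse_effects + self.posterior_.mean_polygenic_effects
        self.coef_std_ = coef_std
        self.coef_ = coef_std / scales
        self.intercept_ = float(ybar - self.coef_ @ means)
        return self

    @staticmethod
    def _q_add(j, w, w_ex_sum, n_ex, mix=0.5):
        """Probability of proposing SNP j for addition from the excluded set:
        a mixture of a uniform draw and a marginal-rank-weighted draw."""
        return mix * w[j] / w_ex_sum + (1.0 - mix) / n_ex

    def _propose_gamma(self, kind, gamma, in_gamma, p, probs, rng, w, w_ex_sum):
        """Return (new_gamma, log Hastings ratio, ΔW of the excluded-weight sum)."""
        m = gamma.size
        n_ex = p - m
        if kind == 0:  # add
            j = self._draw_excluded(in_gamma, p, rng, w, w_ex_sum)
            new_gamma = np.append(gamma, j)
            rev_probs = self._move_probs_at(m + 1, p)
            log_h = math.log(rev_probs[1] / (m + 1)) - math.log(
                probs[0] * self._q_add(j, w, w_ex_sum, n_ex)
            )
            dw = -w[j]
        elif kind == 1:  # remove
            i = int(rng.integers(m))
            j = gamma[i]
            new_gamma = np.delete(gamma, i)
            rev_probs = self._move_probs_at(m - 1, p)
            q_rev = self._q_add(j, w, w_ex_sum + w[j], n_ex + 1)
            log_h = math.log(rev_probs[0] * q_rev) - math.log(probs[1] / m)
            dw = w[j]
        else:  # swap: i leaves, j enters
            i = int(rng.integers(m))
            j = self._draw_excluded(in_gamma, p, rng, w, w_ex_sum)
            out = gamma[i]
            new_gamma = gamma.copy()
            new_gamma[i] = j
            q_fwd = self._q_add(j, w, w_ex_sum, n_ex)
            q_rev = self._q_add(out, w, w_ex_sum + w[out] - w[j], n_ex)
            log_h = math.log(q_rev) - math.log(q_fwd)
            dw = w[out] - w[j]
        return np.sort(new_gamma), log_h, dw

    def _move_probs_at(self, m, p):
        probs = np.array(
            [
                self.move_probs[0] if m < min(p, self.s_max) else 0.0,
                self.move_probs[1] if m > 0 else 0.0,
                self.move_probs[2] if 0 < m < p else 0.0,
            ]
        )
        return probs / probs.sum()

    @staticmethod
    def _draw_excluded(in_gamma, p, rng, w, w_ex_sum, mix=0.5):
        if rng.random() < mix:  # marginal-rank-weighted component
            probs = np.where(in_gamma, 0.0, w)
            return int(rng.choice(p, p=probs / probs.sum()))
        while True:
            j = int(rng.integers(p))
            if not in_gamma[j]:
                return j

    def predict(self, X):
        if not hasattr(self, "posterior_"):
            raise AttributeError("BSLMM instance is not fitted yet")
        if self.posterior_.n_draws == 0:
            raise ValueError("empty chain: no retained draws to average")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def mcmc_fit(
    X, y, prior: BslmmPrior | None = None, config: McmcConfig | None = None
) -> BslmmPosterior:
    """Functional wrapper: run the sampler and return the posterior summary."""
    prior = prior or BslmmPrior()
    config = config or McmcConfig()
    model = BSLMM(
        n_burnin=config.n_burnin,
        n_sampling=config.n_sampling,
        thin=config.thin,
        pi_fixed=prior.pi_fixed,
        sigma_a2_fixed=prior.sigma_a2_fixed,
        sigma_b2_fixed=prior.sigma_b2_fixed,
        log10_sigma_a2_bounds=prior.log10_sigma_a2_bounds,
        log10_sigma_b2_bounds=prior.log10_sigma_b2_bounds,
        random_state=config.seed,
    )
    model.fit(X, y)
    posterior = model.posterior_
    posterior._model = model  # keep preprocessing state for prediction
    return posterior


def bslmm_predict(posterior: BslmmPosterior, X_train, y_train, X_test):
    """Posterior-mean prediction using training standardization statistics."""
    if posterior.n_draws == 0:
        raise ValueError("empty chain: no retained draws to average")
    X_train = np.asarray(X_train, dtype=float)
    _, means, scales = standardize_columns(X_train)
    ybar = np.asarray(y_train, dtype=float).mean()
    Xt = (np.asarray(X_test, dtype=float) - means) / scales
    total = posterior.mean_sparse_effects + posterior.mean_polygenic_effects
    return Xt @ total + ybar


def save_posterior_tsv(posterior: BslmmPosterior, snp_ids, path, trace_path=None) -> None:
    """Per-SNP posterior summary TSV; optionally the hyperparameter traces."""
    with open(path, "w") as fh:
        fh.write("snp_id\tinclusion_prob\tmean_sparse_effect\tmean_polygenic_effect\n")
        for i, sid in enumerate(snp_ids):
            fh.write(
                f"{sid}\t{posterior.inclusion_prob[i]:.6g}\t"
                f"{posterior.mean_sparse_effects[i]:.10g}\t"
                f"{posterior.mean_polygenic_effects[i]:.10g}\n"
            )
    if trace_path is not None:
        keys = list(posterior.traces)
        with open(trace_path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in zip(*(posterior.traces[k] for k in keys)):
                fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
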