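"""Likelihood-based diet estimation.

Two models on the centred log-ratio (clr) scale:

* the prey-means MLE: ``clr(pred_j) ~ Normal(clr(sum_i alpha_ji m_i), V)``
  with ``V = sigma^2 I`` (isotropic) or ``diag(sigma_k^2)`` (per-FA).  With
  isotropic variance the fitted diet coincides with the Aitchison-distance
  QFASA diet, because maximizing the Gaussian likelihood in clr coordinates
  minimizes the squared clr residual.

* MUFASA: the prey species means are replaced by latent species effects
  ``z_i ~ Normal(clr(mean_i), S_i / n_i)`` (within-species clr covariance,
  diagonal by default), acknowledging that the predator did not eat the
  sampled prey themselves; the observation model is
  ``clr(pred_j) ~ Normal(clr(sum_i alpha_ji clr_inv(z_i)), sigma_eps^2 I)``.
  The marginal likelihood is approximated by Laplace: the joint log-density
  is maximized over diets and latent effects together (error variance
  profiled out), and the Gaussian curvature correction is evaluated at the
  optimum.  As the within-species dispersion shrinks to zero the latent
  effects pin to the prey means and MUFASA collapses to the MLE.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .compositions import InvalidCompositionError, _auto_zero_replace, cc_to_prey_space, clr, clr_inv, close
from .distances import DistanceSpec
from .estimation import _fit_simplex
from .prey import PreyDatabase

__all__ = [
    "mle_loglik", "mle_diet", "MLEFit", "MLEDietModel", "MLEResults",
    "mufasa_diet", "MufasaFit", "MufasaModel", "MufasaResults",
]

_VAR_FLOOR = 1e-12


# ----------------------------------------------------------------------
# prey-means MLE

def _prep_matrix(preds, cc=None, eps: float = 1e-5) -> np.ndarray:
    X = close(np.atleast_2d(np.asarray(preds, dtype=float)), warn=False)
    if cc is not None:
        X = np.vstack([cc_to_prey_space(x, cc) for x in X])
    return _auto_zero_replace(X, eps)


def mle_loglik(diet, preds, means: pd.DataFrame, sigma2, variance_model: str = "isotropic") -> float:
    """Gaussian log-likelihood of predators' clr signatures at a given diet.

    ``diet`` is either a single composition shared by all predators or one
    row per predator.  ``sigma2`` is a scalar (isotropic) or a length-K
    vector (per-FA diagonal).
    """
    M = means.to_numpy(dtype=float)
    X = _prep_matrix(preds)
    n, K = X.shape
    D = np.atleast_2d(np.asarray(diet, dtype=float))
    if np.any(D < -1e-9) or np.any(np.abs(D.sum(axis=1) - 1) > 1e-6):
        raise InvalidCompositionError("diet is not on the simplex")
    if D.shape[0] == 1:
        D = np.repeat(D, n, axis=0)
    s2 = np.asarray(sigma2, dtype=float)
    if variance_model == "isotropic":
        s2 = np.full(K, float(s2))
    CX = clr(X)
    ll = 0.0
    for j in range(n):
        mix = D[j] @ M
        r = CX[j] - clr(mix / mix.sum())
        ll += float(-0.5 * np.sum(np.log(2 * np.pi * s2)) - 0.5 * np.sum(r * r / s2))
    return ll


@dataclass
class MLEFit:
    """Prey-means MLE fit: diets, variance(s), maximized log-likelihood."""

    species: list
    diets: np.ndarray          # (n, R)
    sigma2: np.ndarray         # scalar array or (K,)
    loglik: float
    n_params: int
    converged: bool
    variance_model: str


def _clr_means_target(CX: np.ndarray) -> np.ndarray:
    # common-diet profile: the summed squared clr residual is minimized by
    # fitting against the clr barycentre of the predators
    return clr_inv(CX.mean(axis=0))


def mle_diet(preds, means: pd.DataFrame, cc=None, variance_model: str = "isotropic", *,
             common_diet: bool = False, n_starts: int = 10, seed: int = 0,
             max_iter: int = 10, eps: float = 1e-5) -> MLEFit:
    """Maximum-likelihood diets under the prey-means Gaussian clr model.

    With ``variance_model="isotropic"`` the per-predator diets equal the
    Aitchison-distance QFASA diets; the per-FA model iterates between
    weighted diet fits and closed-form variance updates and can only raise
    the likelihood relative to its isotropic initialization.
    """
    M = means.to_numpy(dtype=float)
    M = _auto_zero_replace(M, eps)
    M = M / M.sum(axis=1, keepdims=True)
    mdf = pd.DataFrame(M, index=means.index, columns=means.columns)
    X = _prep_matrix(preds, cc, eps)
    n, K = X.shape
    R = M.shape[0]
    CX = clr(X)
    spec = DistanceSpec("AIT", eps=eps)

    def fit_all(weights):
        rows, conv = [], True
        if common_diet:
            target = _clr_means_target(CX)
            rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0]))
            a, _, ok, _ = _fit_simplex(target, M, spec, n_starts=n_starts, rng=rng,
                                       weights=weights)
            rows = [a] * n
            conv = ok
        else:
            for j in range(n):
                rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, j]))
                a, _, ok, _ = _fit_simplex(X[j], M, spec, n_starts=n_starts, rng=rng,
                                           weights=weights)
                rows.append(a)
                conv = conv and ok
        return np.array(rows), conv

    def residuals(D):
        mix = D @ M
        mix = mix / mix.sum(axis=1, keepdims=True)
        return CX - clr(mix)

    D, conv = fit_all(None)
    Rsd = residuals(D)
    if variance_model == "isotropic":
        s2 = max(float((Rsd**2).mean()), _VAR_FLOOR)
        sigma2 = np.array(s2)
        ll = mle_loglik(D, X, mdf, s2, "isotropic")
        n_params = (1 if common_diet else n) * (R - 1) + 1
    elif variance_model == "per_fa":
        s2 = np.maximum((Rsd**2).mean(axis=0), _VAR_FLOOR)
        ll = mle_loglik(D, X, mdf, s2, "per_fa")
        for _ in range(max_iter):
            D_new, ok = fit_all(1.0 / s2)
            s2_new = np.maximum((residuals(D_new) ** 2).mean(axis=0), _VAR_FLOOR)
            ll_new = mle_loglik(D_new, X, mdf, s2_new, "per_fa")
            if ll_new <= ll + 1e-10:
                break
            D, s2, ll, conv = D_new, s2_new, ll_new, conv and ok
        sigma2 = s2
        n_params = (1 if common_diet else n) * (R - 1) + K
    else:
        raise ValueError(f"unknown variance model {variance_model!r}")
    return MLEFit(species=list(means.index), diets=D, sigma2=sigma2, loglik=float(ll),
                  n_params=n_params, converged=conv, variance_model=variance_model)


class MLEDietModel:
    """Statsmodels-style front end for the prey-means MLE."""

    def __init__(self, predators, prey: PreyDatabase, *, fa_subset=None, cc=None,
                 variance_model: str = "isotropic", common_diet: bool = False):
        from .estimation import DietModel
        base = DietModel(predators, prey, fa_subset=fa_subset, cc=cc)
        self.predator_ids = base.predator_ids
        self.exog = base.exog
        self.means = base.means
        self.cc = base.cc
        self.variance_model = variance_model
        self.common_diet = common_diet

    def fit(self, *, n_starts: int = 10, seed: int = 0) -> "MLEResults":
        fit = mle_diet(self.exog, self.means, self.cc, self.variance_model,
                       common_diet=self.common_diet, n_starts=n_starts, seed=seed)
        return MLEResults(self, fit)


class MLEResults:
    def __init__(self, model: MLEDietModel, fit: MLEFit):
        self.model = model
        self.fit_ = fit
        self.diets = pd.DataFrame(fit.diets, index=model.predator_ids, columns=fit.species)
        self.sigma2 = fit.sigma2
        self.loglik = fit.loglik
        self.n_params = fit.n_params
        self.converged = fit.converged

    def summary(self) -> str:
        lines = [
            "Prey-means MLE diet estimation",
            f"  variance model: {self.fit_.variance_model}"
            f"   log-likelihood: {self.loglik:.4f}   parameters: {self.n_params}",
            "",
            "Diet proportions (mean across predators):",
        ]
        for sp in self.diets.columns:
            lines.append(f"  {sp:<16s} {self.diets[sp].mean():.3f}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# MUFASA (Laplace-approximate marginal likelihood with latent prey effects)

def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class _LatentPreyCore:
    """Joint neg-log-density (error sd profiled) and its analytic gradient.

    Parameters are packed as [A | Z | b]: per-predator (or common) diet
    logits A, latent species effects Z on the clr scale, and optionally a
    clr-scale calibration vector b (used by SMUFASA).
    """

    def __init__(self, CX: np.ndarray, mu: np.ndarray, dvar: np.ndarray, *,
                 common_alpha: bool = False, with_cc: bool = False):
        self.CX = CX            # (n, K) clr predator signatures (prey space)
        self.mu = mu            # (R, K) prior means of latent effects
        self.dvar = dvar        # (R, K) prior diagonal variances
        self.n, self.K = CX.shape
        self.R = mu.shape[0]
        self.common = common_alpha
        self.with_cc = with_cc
        self.nA = self.R if common_alpha else self.n * self.R

    def unpack(self, theta):
        A = theta[: self.nA].reshape((1 if self.common else self.n, self.R))
        Z = theta[self.nA : self.nA + self.R * self.K].reshape(self.R, self.K)
        b = theta[self.nA + self.R * self.K :] if self.with_cc else None
        return A, Z, b

    def _pieces(self, theta):
        A, Z, b = self.unpack(theta)
        alpha = _softmax(A)
        if self.common:
            alpha = np.repeat(alpha, self.n, axis=0)
        P = _softmax(Z)                      # (R, K) latent prey compositions
        Mix = alpha @ P                      # (n, K)
        Mix = np.clip(Mix, 1e-300, None)
        lm = np.log(Mix)
        Cmix = lm - lm.mean(axis=1, keepdims=True)
        resid = self.CX - Cmix
        if self.with_cc:
            cb = b - b.mean()
            resid = resid - cb
        return A, Z, b, alpha, P, Mix, resid

    def ssr(self, theta) -> float:
        return float((self._pieces(theta)[6] ** 2).sum())

    def value_grad(self, theta):
        A, Z, b, alpha, P, Mix, resid = self._pieces(theta)
        n, K, R = self.n, self.K, self.R
        ssr = float((resid**2).sum())
        prior_dev = (Z - self.mu)
        neg = 0.5 * float((prior_dev**2 / self.dvar).sum()) + 0.5 * n * K * np.log(max(ssr, 1e-300))
        # gradient pieces: d ssr / d mix_j = -2 resid_j / mix_j (clr rows center to 0)
        V = -2.0 * resid / Mix              # (n, K)
        fac = 0.5 * n * K / max(ssr, 1e-300)
        # Z gradient
        gZ = prior_dev / self.dvar
        W = alpha.T @ V                      # (R, K): sum_j alpha_ji * V_j
        gZ += fac * (P * W - P * (P * W).sum(axis=1, keepdims=True))
        # A gradient
        Q = V @ P.T                          # (n, R): dssr/dalpha_j
        if self.common:
            a1 = _softmax(A)[0]
            q = Q.sum(axis=0)
            gA = fac * (a1 * (q - float(a1 @ q)))[None, :]
        else:
            al = _softmax(A)
            gA = fac * (al * (Q - (al * Q).sum(axis=1, keepdims=True)))
        grad = [gA.ravel(), gZ.ravel()]
        if self.with_cc:
            gb = fac * (-2.0 * resid.sum(axis=0))
            grad.append(gb - gb.mean())
        return neg, np.concatenate(grad)

    # -- Laplace correction --------------------------------------------
    def laplace_loglik(self, theta) -> tuple[float, bool]:
        """Approximate marginal log-likelihood at the joint optimum."""
        A, Z, b, alpha, P, Mix, resid = self._pieces(theta)
        n, K, R = self.n, self.K, self.R
        ssr = float((resid**2).sum())
        s2 = max(ssr / (n * K), _VAR_FLOOR)
        d = R * K

        def negjoint_z(zflat):
            th = theta.copy()
            th[self.nA : self.nA + d] = zflat
            Ai, Zi, bi, al, Pi, Mx, rs = self._pieces(th)
            pr = 0.5 * float(((Zi - self.mu) ** 2 / self.dvar).sum()) \
                + 0.5 * float(np.log(2 * np.pi * self.dvar).sum())
            ob = 0.5 * n * K * np.log(2 * np.pi * s2) + float((rs**2).sum()) / (2 * s2)
            return pr + ob

        def grad_z(zflat):
            th = theta.copy()
            th[self.nA : self.nA + d] = zflat
            Ai, Zi, bi, al, Pi, Mx, rs = self._pieces(th)
            V = -rs / Mx / s2
            W = al.T @ V
            g = (Zi - self.mu) / self.dvar + (Pi * W - Pi * (Pi * W).sum(axis=1, keepdims=True))
            return g.ravel()

        z0 = theta[self.nA : self.nA + d]
        h = 1e-5
        H = np.empty((d, d))
        for i in range(d):
            zp = z0.copy(); zp[i] += h
            zm = z0.copy(); zm[i] -= h
            H[:, i] = (grad_z(zp) - grad_z(zm)) / (2 * h)
        H = (H + H.T) / 2.0
        sign, logdet = np.linalg.slogdet(H)
        ok = sign > 0
        if not ok:
            H = H + 1e-6 * np.eye(d)
            sign, logdet = np.linalg.slogdet(H)
            ok = sign > 0
        ll = -negjoint_z(z0) + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet
        return float(ll), bool(ok)


def _prior_from_db(db: PreyDatabase, faset=None, *, cov_scale: float = 1.0,
                   ridge: float = 1e-8, eps: float = 1e-5):
    mu, covs, ns = db.clr_stats(faset, eps=eps)
    R, K = mu.shape
    dvar = np.empty((R, K))
    for i, (S, n_i) in enumerate(zip(covs, ns)):
        if n_i < 2:
            warnings.warn(f"species {db.species[i]!r} has a single individual; "
                          "using pooled diagonal variance", stacklevel=3)
            pool = np.mean([np.diag(c) for c, m in zip(covs, ns) if m > 1], axis=0)
            dvar[i] = pool / max(n_i, 1)
        else:
            dvar[i] = np.diag(S) / n_i
    dvar = cov_scale * dvar + ridge
    return mu, dvar


@dataclass
class MufasaFit:
    species: list
    diets: np.ndarray        # (n, R)
    re_modes: np.ndarray     # (R, K) latent clr modes
    sigma2: float
    loglik: float
    converged: bool


def mufasa_diet(preds, db: PreyDatabase, cc=None, *, fa_subset=None,
                cov_scale: float = 1.0, seed: int = 0, laplace: bool = True,
                eps: float = 1e-5) -> MufasaFit:
    """Fit the MUFASA random-effects model (Laplace approximation).

    ``cov_scale`` scales the latent-effect prior variances (useful to check
    the degenerate collapse onto the prey-means MLE as it tends to zero).
    """
    means = db.species_means(fa_subset)
    X = _prep_matrix(preds, cc, eps)
    CX = clr(X)
    mu, dvar = _prior_from_db(db, fa_subset, cov_scale=cov_scale, eps=eps)
    n, K = CX.shape
    R = mu.shape[0]
    if R == 1:
        resid = CX - clr(clr_inv(mu[0]))[None, :]
        s2 = max(float((resid**2).mean()), _VAR_FLOOR)
        return MufasaFit(species=list(means.index), diets=np.ones((n, 1)),
                         re_modes=mu.copy(), sigma2=s2, loglik=float("nan"), converged=True)
    core = _LatentPreyCore(CX, mu, dvar)
    # warm start from the prey-means MLE
    init = mle_diet(X, means, None, "isotropic", n_starts=3, seed=seed)
    A0 = np.log(np.clip(init.diets, 1e-6, None))
    theta0 = np.concatenate([A0.ravel(), mu.ravel()])
    res = minimize(core.value_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
    A, Z, _ = core.unpack(res.x)
    alpha = _softmax(A)
    ssr = core.ssr(res.x)
    s2 = max(ssr / (n * K), _VAR_FLOOR)
    if laplace:
        ll, ok = core.laplace_loglik(res.x)
    else:
        ll, ok = float("nan"), True
    return MufasaFit(species=list(means.index), diets=alpha, re_modes=Z, sigma2=s2,
                     loglik=ll, converged=bool(res.success) and ok)


class MufasaModel:
    """Random-effects (MUFASA) diet model front end."""

    def __init__(self, predators, prey: PreyDatabase, *, fa_subset=None, cc=None,
                 cov_scale: float = 1.0):
        from .estimation import DietModel
        base = DietModel(predators, prey, fa_subset=fa_subset, cc=cc)
        self.predator_ids = base.predator_ids
        self.exog = base.exog
        self._faset = base.faset
        self.cc = base.cc
        self.cov_scale = cov_scale
        self._db = prey

    def fit(self, *, seed: int = 0, laplace: bool = True) -> "MufasaResults":
        fit = mufasa_diet(self.exog, self._db, self.cc, fa_subset=self._faset,
                          cov_scale=self.cov_scale, seed=seed, laplace=laplace)
        return MufasaResults(self, fit)


class MufasaResults:
    def __init__(self, model: MufasaModel, fit: MufasaFit):
        self.model = model
        self.fit_ = fit
        self.diets = pd.DataFrame(fit.diets, index=model.predator_ids, columns=fit.species)
        self.re_modes = pd.DataFrame(fit.re_modes, index=fit.species, columns=model._faset)
        self.loglik = fit.loglik
        self.sigma2 = fit.sigma2
        self.converged = fit.converged

    def summary(self) -> str:
        lines = [
            "MUFASA diet estimation (latent prey effects, Laplace approximation)",
            f"  marginal log-likelihood: {self.loglik:.4f}   sigma_eps^2: {self.sigma2:.4g}"
            f"   converged: {self.converged}",
            "",
            "Diet proportions (mean across predators):",
        ]
        for sp in self.diets.columns:
            lines.append(f"  {sp:<16s} {self.diets[sp].mean():.3f}")
        return "\n".join(lines)
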