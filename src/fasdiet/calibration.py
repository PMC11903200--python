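"""Calibration-coefficient (CC) estimation from predator data.

Two routes estimate the per-FA calibration vector ``c`` (with the
identifiability constraint ``sum_k c_k = K``, i.e. mean CC 1) when no
captive-study CCs exist:

* ``simultaneous_diet_cc`` — alternating minimization of the summed squared
  Aitchison distance between calibrated predators and their fitted prey
  mixtures.  Because the Aitchison geometry turns the calibration division
  into a clr subtraction, the c-step has a closed form (the clr barycentre
  of the residuals), so the outer objective is monotone non-increasing.

* ``smufasa`` — a common diet for the whole predator sample and ``c`` are
  estimated jointly by maximizing the MUFASA-type Laplace marginal
  likelihood; the estimated CCs are then typically passed back into any of
  the per-predator diet estimators.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .compositions import _auto_zero_replace, clr, close
from .distances import DistanceSpec
from .estimation import _fit_simplex
from .likelihood import _LatentPreyCore, _prior_from_db, _softmax, mle_diet
from .prey import PreyDatabase

__all__ = ["CCEstimate", "simultaneous_diet_cc", "smufasa", "CalibrationModel", "CCResults"]


@dataclass
class CCEstimate:
    """Estimated calibration vector plus the diets it was fitted with."""

    fa_names: list
    cc: np.ndarray
    diets: np.ndarray            # (n, R) for sim; (R,) common diet for SMUFASA
    species: list
    objective_trace: list
    loglik: float | None
    converged: bool

    def cc_series(self) -> pd.Series:
        return pd.Series(self.cc, index=self.fa_names)


def _normalize_cc(c: np.ndarray) -> np.ndarray:
    return c * (len(c) / c.sum())


def simultaneous_diet_cc(preds, db: PreyDatabase, *, fa_subset=None, max_iter: int = 100,
                         tol: float = 1e-8, n_starts: int = 5, seed: int = 0,
                         eps: float = 1e-5) -> CCEstimate:
    """Alternate per-predator AIT diet fits with the closed-form CC step.

    Needs at least two predators with distinct diets for the CC to be
    identifiable.  Returns the best iterate with its objective trace
    (non-increasing by construction).
    """
    if np.atleast_2d(np.asarray(preds, dtype=float)).shape[0] < 2:
        raise ValueError("CC estimation needs at least two predators")
    means = db.species_means(fa_subset)
    M = means.to_numpy(dtype=float)
    M = _auto_zero_replace(M, eps)
    M = M / M.sum(axis=1, keepdims=True)
    X = close(np.atleast_2d(np.asarray(preds, dtype=float)), warn=False)
    X = _auto_zero_replace(X, eps)
    CX = clr(X)
    n, K = CX.shape
    R = M.shape[0]
    spec = DistanceSpec("AIT", eps=eps)

    clr_c = np.zeros(K)
    D = np.full((n, R), 1.0 / R)
    trace = []
    prev = np.inf
    converged = False
    for it in range(max_iter):
        # (a) diet step: per-predator AIT fit of the calibrated signature;
        # after the first pass, warm-start from the previous diets
        Dnew = D.copy()
        starts = n_starts if it == 0 else 1
        for j in range(n):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, it, j]))
            target = CX[j] - clr_c
            # _fit_simplex matches clr(mix) to clr(x); pass the calibrated
            # signature as a composition
            xj = np.exp(target - target.max())
            xj = xj / xj.sum()
            a, val, ok, _ = _fit_simplex(xj, M, spec, n_starts=starts, rng=rng,
                                         x0=None if it == 0 else D[j])
            # keep the previous diet if the optimizer failed to improve
            mix_old = np.clip(D[j] @ M, 1e-300, None)
            r_old = target - clr(mix_old / mix_old.sum())
            if val <= float(r_old @ r_old):
                Dnew[j] = a
        D = Dnew
        # (b) closed-form c-step: clr(c) = mean_j (clr(x_j) - clr(mix_j))
        Mix = np.clip(D @ M, 1e-300, None)
        CMix = clr(Mix / Mix.sum(axis=1, keepdims=True))
        clr_c = (CX - CMix).mean(axis=0)
        obj = float(((CX - clr_c[None, :] - CMix) ** 2).sum())
        trace.append(obj)
        if prev - obj < tol * max(1.0, abs(obj)):
            converged = True
            break
        prev = obj
    cc = _normalize_cc(np.exp(clr_c))
    return CCEstimate(fa_names=list(means.columns), cc=cc, diets=D,
                      species=list(means.index), objective_trace=trace,
                      loglik=None, converged=converged)


def smufasa(preds, db: PreyDatabase, *, fa_subset=None, seed: int = 0,
            laplace: bool = True, cov_scale: float = 1.0, eps: float = 1e-5) -> CCEstimate:
    """Joint common-diet + CC estimation via the Laplace marginal likelihood."""
    X = close(np.atleast_2d(np.asarray(preds, dtype=float)), warn=False)
    if X.shape[0] < 2:
        raise ValueError("CC estimation needs at least two predators")
    X = _auto_zero_replace(X, eps)
    CX = clr(X)
    means = db.species_means(fa_subset)
    mu, dvar = _prior_from_db(db, fa_subset, cov_scale=cov_scale, eps=eps)
    n, K = CX.shape
    R = mu.shape[0]
    if R == 1:
        clr_c = (CX - clr(np.atleast_2d(np.exp(mu[0]) / np.exp(mu[0]).sum()))[0]).mean(axis=0)
        cc = _normalize_cc(np.exp(clr_c))
        return CCEstimate(fa_names=list(means.columns), cc=cc, diets=np.ones(1),
                          species=list(means.index), objective_trace=[], loglik=None,
                          converged=True)
    core = _LatentPreyCore(CX, mu, dvar, common_alpha=True, with_cc=True)
    init = mle_diet(X, means, None, "isotropic", common_diet=True, n_starts=3, seed=seed)
    A0 = np.log(np.clip(init.diets[0], 1e-6, None))
    theta0 = np.concatenate([A0, mu.ravel(), np.zeros(K)])
    res = minimize(core.value_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 3000, "ftol": 1e-12, "gtol": 1e-9})
    A, Z, b = core.unpack(res.x)
    alpha = _softmax(A)[0]
    cc = _normalize_cc(np.exp(b - b.mean()))
    ll, ok = core.laplace_loglik(res.x) if laplace else (float("nan"), True)
    return CCEstimate(fa_names=list(means.columns), cc=cc, diets=alpha,
                      species=list(means.index), objective_trace=[], loglik=ll,
                      converged=bool(res.success) and ok)


class CalibrationModel:
    """Front end: estimate CCs from a predator sample and a prey library.

    ``method`` is ``"sim"`` (alternating distance minimization with
    per-predator diets) or ``"smufasa"`` (likelihood with one common diet).
    """

    def __init__(self, predators, prey: PreyDatabase, *, method: str = "sim",
                 fa_subset=None):
        if method not in ("sim", "smufasa"):
            raise ValueError("method must be 'sim' or 'smufasa'")
        from .estimation import DietModel
        base = DietModel(predators, prey, fa_subset=fa_subset)
        self.predator_ids = base.predator_ids
        self.exog = base.exog
        self.faset = base.faset
        self.prey = prey
        self.method = method

    def fit(self, *, seed: int = 0, **kwargs) -> "CCResults":
        if self.method == "sim":
            est = simultaneous_diet_cc(self.exog, self.prey, fa_subset=self.faset,
                                       seed=seed, **kwargs)
        else:
            est = smufasa(self.exog, self.prey, fa_subset=self.faset, seed=seed, **kwargs)
        return CCResults(self, est)


class CCResults:
    def __init__(self, model: CalibrationModel, est: CCEstimate):
        self.model = model
        self.estimate_ = est
        self.cc = pd.Series(est.cc, index=est.fa_names, name="cc")
        self.log_cc = np.log(self.cc).rename("log_cc")
        if est.diets.ndim == 2:
            self.diets = pd.DataFrame(est.diets, index=model.predator_ids,
                                      columns=est.species)
        else:
            self.diets = pd.DataFrame([est.diets], index=["common"], columns=est.species)
        self.converged = est.converged
        self.loglik = est.loglik

    def summary(self) -> str:
        est = self.estimate_
        lines = [
            f"Calibration-coefficient estimation ({self.model.method})",
            f"  FAs: {len(self.cc)}   converged: {self.converged}",
            f"  CC range: [{self.cc.min():.3f}, {self.cc.max():.3f}] (mean fixed at 1)",
        ]
        if est.loglik is not None and np.isfinite(est.loglik or np.nan):
            lines.append(f"  marginal log-likelihood: {est.loglik:.4f}")
        if est.objective_trace:
            lines.append(f"  final objective: {est.objective_trace[-1]:.6g} "
                         f"after {len(est.objective_trace)} iterations")
        return "\n".join(lines)
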