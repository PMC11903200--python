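"""Distance-minimization diet estimation (the core QFASA estimator).

For each predator the diet composition ``alpha`` over R prey species
minimizes the chosen compositional distance between the predator's
signature (mapped into prey space with calibration coefficients) and the
convex mixture ``sum_i alpha_i m_i`` of prey-species mean signatures, over
the simplex ``{alpha >= 0, sum alpha = 1}``.

The optimizer is SLSQP on the sum-to-one + bounds formulation with a
seeded multistart (uniform diet plus random Dirichlet(1) draws); analytic
gradients are supplied for KL, AIT and CS (gamma = 1).  The minimized
objective is additive over FAs (KL distance; squared AIT; squared CS), so
its per-FA addends are reported as the contribution of each FA to the fit.

`DietModel` is the statsmodels-style front end; `estimate_diet` /
`estimate_diets` are the functional layer the rest of the toolkit reuses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .compositions import (
    InvalidCompositionError,
    _auto_zero_replace,
    cc_to_prey_space,
    clr,
    close,
    fat_rescale,
)
from .distances import DistanceSpec, as_spec, fa_terms
from .prey import PreyDatabase

__all__ = ["DietEstimate", "estimate_diet", "estimate_diets", "DietModel", "DietResults"]


# ----------------------------------------------------------------------
# simplex optimizer

def _objective_factory(x: np.ndarray, M: np.ndarray, spec: DistanceSpec,
                       weights: np.ndarray | None = None):
    """Return (fun, jac) for the additive objective at mixture ``M.T @ alpha``.

    ``M`` has shape (R, K) with rows = prey mean signatures.  ``weights``
    (AIT only) turns the squared clr residual into a weighted sum, which is
    what the per-FA-variance likelihood profile needs.
    """
    kind = spec.kind
    K = M.shape[1]
    tiny = 1e-300

    if kind == "AIT":
        cx = clr(x)
        w = np.ones(K) if weights is None else np.asarray(weights, dtype=float)

        def fun(a):
            y = np.clip(a @ M, tiny, None)
            ly = np.log(y)
            r = (ly - ly.mean()) - cx
            return float((w * r * r).sum())

        def jac(a):
            y = np.clip(a @ M, tiny, None)
            ly = np.log(y)
            r = (ly - ly.mean()) - cx
            wr = w * r
            g_y = 2.0 * (wr - wr.mean()) / y
            return M @ g_y

        return fun, jac

    if kind == "KL":
        lx = np.log(np.clip(x, tiny, None))

        def fun(a):
            y = np.clip(a @ M, tiny, None)
            return float(((x - y) * (lx - np.log(y))).sum())

        def jac(a):
            y = np.clip(a @ M, tiny, None)
            g_y = -(lx - np.log(y)) - x / y + 1.0
            return M @ g_y

        return fun, jac

    # CS
    if spec.gamma == 1.0:
        def fun(a):
            y = np.clip(a @ M, 0.0, None)
            s = x + y
            t = np.where(s > 0, (x - y) ** 2 / np.where(s > 0, s, 1.0), 0.0)
            return float(2.0 * t.sum())

        def jac(a):
            y = np.clip(a @ M, 0.0, None)
            d = x - y
            s = x + y
            g_y = np.where(s > 0, -2.0 * d * (2.0 * s + d) / np.where(s > 0, s, 1.0) ** 2, 0.0)
            return M @ g_y

        return fun, jac

    gamma = spec.gamma

    def fun(a):  # general gamma: numeric gradient
        y = np.clip(a @ M, 0.0, None)
        return float(fa_terms(x, y, spec).sum())

    return fun, None


def _fit_simplex(x: np.ndarray, M: np.ndarray, spec: DistanceSpec, *,
                 n_starts: int = 10, rng: np.random.Generator | None = None,
                 ftol: float = 1e-12, weights: np.ndarray | None = None,
                 x0: np.ndarray | None = None):
    """Minimize the additive objective over the simplex; multistart SLSQP.

    ``x0`` prepends a warm start to the uniform + Dirichlet(1) multistart.
    Returns ``(alpha, objective, converged, n_starts_used)``.
    """
    R = M.shape[0]
    if R == 1:
        fun, _ = _objective_factory(x, M, spec, weights)
        a = np.ones(1)
        return a, fun(a), True, 1
    rng = rng or np.random.default_rng(0)
    fun, jac = _objective_factory(x, M, spec, weights)
    cons = [{"type": "eq", "fun": lambda a: a.sum() - 1.0, "jac": lambda a: np.ones_like(a)}]
    bounds = [(0.0, 1.0)] * R
    starts = [] if x0 is None else [np.asarray(x0, dtype=float)]
    starts.append(np.full(R, 1.0 / R))
    for _ in range(max(0, n_starts - 1 - len(starts) + 1)):
        starts.append(rng.dirichlet(np.ones(R)))
    starts = starts[: max(n_starts, 1)]
    best = None
    converged = False
    used = 0
    for a0 in starts:
        used += 1
        res = minimize(fun, a0, jac=jac, method="SLSQP", bounds=bounds,
                       constraints=cons, options={"ftol": ftol, "maxiter": 300})
        a = np.clip(res.x, 0.0, None)
        a = a / a.sum()
        val = fun(a)
        if best is None or val < best[1]:
            best = (a, val)
        converged = converged or bool(res.success)
        if best[1] < 1e-16:  # exact fit found; further starts cannot improve
            break
    return best[0], best[1], converged, used


# ----------------------------------------------------------------------
# functional layer

@dataclass
class DietEstimate:
    """Fitted diet for one predator, with fit diagnostics.

    ``min_distance`` is the minimized additive objective (KL distance,
    squared AIT, squared CS) and equals ``fa_contributions.sum()``;
    ``distance`` is the metric-scale value (sqrt for AIT/CS).  When fat
    contents are supplied ``proportions`` is the fat-rescaled diet while
    ``biomass_proportions`` and all diagnostics refer to the biomass-scale
    fit.
    """

    species: list
    proportions: np.ndarray
    biomass_proportions: np.ndarray
    min_distance: float
    distance: float
    modeled_signature: np.ndarray
    fa_contributions: np.ndarray
    converged: bool
    n_starts_used: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.species)


def _prep_predator(pred, fa_names, spec: DistanceSpec, cc=None) -> np.ndarray:
    x = close(np.asarray(pred, dtype=float), warn=False)
    if cc is not None:
        x = cc_to_prey_space(x, cc)
    if spec.kind in ("KL", "AIT"):
        x = _auto_zero_replace(x, spec.eps)[0]
    return x


def estimate_diet(pred, means: pd.DataFrame, spec="KL", cc=None, fat=None, *,
                  n_starts: int = 10, seed: int = 0, _rng=None) -> DietEstimate:
    """Estimate one predator's diet against prey species means.

    Parameters
    ----------
    pred : 1-D array or Series
        Predator FA signature over the same FA index as ``means``.
    means : DataFrame
        Prey mean signatures, rows = species (see
        :meth:`PreyDatabase.species_means`).
    spec : str or DistanceSpec
    cc : array, optional
        Calibration coefficients mapping the predator into prey space.
    fat : array, optional
        Per-species fat contents; when given, ``proportions`` is rescaled to
        prey-count shares after the fit.
    """
    spec = as_spec(spec)
    M = means.to_numpy(dtype=float)
    R, K = M.shape
    if R < 2:
        raise InvalidCompositionError("diet estimation needs at least two prey species")
    if R > K:
        warnings.warn(
            "more prey species than FAs: the diet estimates may not be unique",
            stacklevel=2,
        )
    x = _prep_predator(pred, list(means.columns), spec, cc)
    if spec.kind in ("KL", "AIT"):
        M = _auto_zero_replace(M, spec.eps)
        M = M / M.sum(axis=1, keepdims=True)
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    alpha, obj, conv, used = _fit_simplex(x, M, spec, n_starts=n_starts, rng=rng)
    y = alpha @ M
    y = y / y.sum()
    terms = fa_terms(x, y, spec)
    dist = obj if spec.kind == "KL" else float(np.sqrt(max(obj, 0.0)))
    props = alpha if fat is None else fat_rescale(alpha, fat)
    return DietEstimate(
        species=list(means.index), proportions=props, biomass_proportions=alpha,
        min_distance=float(terms.sum()), distance=dist, modeled_signature=y,
        fa_contributions=terms, converged=conv, n_starts_used=used,
    )


def estimate_diets(preds, means: pd.DataFrame, spec="KL", cc=None, fat=None, *,
                   n_starts: int = 10, seed: int = 0) -> list[DietEstimate]:
    """Elementwise :func:`estimate_diet` over a predator matrix.

    Each predator gets an independent, deterministic multistart stream
    derived from ``seed``; failures are propagated per predator without
    aborting the batch.
    """
    X = np.atleast_2d(np.asarray(preds, dtype=float))
    out = []
    for j, x in enumerate(X):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, j]))
        out.append(estimate_diet(x, means, spec, cc, fat, n_starts=n_starts, _rng=rng))
    return out


# ----------------------------------------------------------------------
# model front end

class DietModel:
    """Distance-minimization diet model for a sample of predators.

    Parameters
    ----------
    predators : DataFrame or 2-D array
        Rows = predators, columns = FA proportions (or percentages).
    prey : PreyDatabase
    fa_subset : sequence of str, optional
        FA set to extract and renormalize before fitting (default: all FAs
        shared by predators and prey).
    distance : str or DistanceSpec
    cc, fat : arrays or Series, optional
        Calibration coefficients (per FA of the subset) and per-species fat
        contents.

    Examples
    --------
    >>> model = DietModel(pred_df, prey_db, distance="KL")   # doctest: +SKIP
    >>> res = model.fit(seed=1)                              # doctest: +SKIP
    >>> res.summary()                                        # doctest: +SKIP
    """

    def __init__(self, predators, prey: PreyDatabase, *, fa_subset=None,
                 distance="KL", cc=None, fat=None):
        self.prey = prey
        self.spec = as_spec(distance)
        if isinstance(predators, pd.DataFrame):
            self.predator_ids = list(predators.index)
            pred_df = predators
        else:
            arr = np.atleast_2d(np.asarray(predators, dtype=float))
            self.predator_ids = list(range(arr.shape[0]))
            pred_df = pd.DataFrame(arr, columns=prey.fa_names)
        self.faset = list(fa_subset) if fa_subset is not None else [
            c for c in prey.fa_names if c in pred_df.columns
        ]
        missing = [f for f in self.faset if f not in pred_df.columns]
        if missing:
            raise InvalidCompositionError(f"FA(s) missing from predator data: {missing}")
        sub = pred_df.loc[:, self.faset].to_numpy(dtype=float)
        sub = close(sub, warn=False)
        self.exog = sub / sub.sum(axis=1, keepdims=True)
        self.means = prey.species_means(self.faset)
        self.cc = None if cc is None else _align(cc, self.faset, "calibration coefficients")
        self.fat = None if fat is None else _align(fat, prey.species, "fat contents")

    @classmethod
    def from_csv(cls, predator_path, prey_path, **kwargs) -> "DietModel":
        from .io import read_predators
        preds = read_predators(predator_path)
        prey = PreyDatabase.from_csv(prey_path)
        return cls(preds, prey, **kwargs)

    def fit(self, *, n_starts: int = 10, seed: int = 0) -> "DietResults":
        ests = estimate_diets(self.exog, self.means, self.spec, self.cc, self.fat,
                              n_starts=n_starts, seed=seed)
        return DietResults(self, ests, seed=seed)


def _align(vec, index, what):
    if isinstance(vec, pd.Series):
        missing = [i for i in index if i not in vec.index]
        if missing:
            raise InvalidCompositionError(f"{what} missing entries: {missing}")
        return vec.loc[list(index)].to_numpy(dtype=float)
    arr = np.asarray(vec, dtype=float)
    if arr.shape[-1] != len(index):
        raise InvalidCompositionError(f"{what}: length {arr.shape[-1]} != {len(index)}")
    return arr


class DietResults:
    """Fitted diets and diagnostics for a predator sample."""

    def __init__(self, model: DietModel, estimates: list[DietEstimate], seed: int):
        self.model = model
        self.estimates_ = estimates
        self.seed = seed
        ids = model.predator_ids
        self.diets = pd.DataFrame([e.proportions for e in estimates],
                                  index=ids, columns=model.means.index)
        self.biomass_diets = pd.DataFrame([e.biomass_proportions for e in estimates],
                                          index=ids, columns=model.means.index)
        self.min_distance = pd.Series([e.min_distance for e in estimates], index=ids)
        self.distance = pd.Series([e.distance for e in estimates], index=ids)
        self.modeled_signatures = pd.DataFrame([e.modeled_signature for e in estimates],
                                               index=ids, columns=model.faset)
        self.fa_contributions = pd.DataFrame([e.fa_contributions for e in estimates],
                                             index=ids, columns=model.faset)
        self.converged = all(e.converged for e in estimates)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Diet estimation (distance minimization)",
            f"  distance: {spec.kind} (eps={spec.eps:g}, gamma={spec.gamma:g})",
            f"  predators: {len(self.diets)}   prey species: {self.diets.shape[1]}"
            f"   FAs: {len(self.model.faset)}",
            f"  mean minimized objective: {self.min_distance.mean():.6g}",
            "",
            "Diet proportions (mean [min, max] across predators):",
        ]
        for sp in self.diets.columns:
            col = self.diets[sp]
            lines.append(f"  {sp:<16s} {col.mean():.3f}  [{col.min():.3f}, {col.max():.3f}]")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        out = self.diets.copy()
        out["min_distance"] = self.min_distance
        return out
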