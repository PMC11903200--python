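"""Stepwise prey-type selection by information criterion.

Both directions wrap the prey-means MLE (isotropic variance, per-predator
diets, one shared error variance): the criterion for a candidate species
set S is ``-2 * loglik + k * (n_pred * (|S| - 1) + 1)``, so ``k = 2`` is
AIC.  Backward elimination protects any species whose estimated proportion
reaches ``cutoff`` in at least one predator; forward selection forces
additions until ``min_spec`` species are included.  Ties are broken toward
the smaller model, and candidate order follows the database species order,
so the whole path is deterministic given the seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import mle_diet
from .prey import PreyDatabase

__all__ = ["SelectionResult", "ic_value", "backward_elimination", "forward_selection"]


@dataclass
class SelectionResult:
    """Outcome of a stepwise selection run."""

    chosen_species: list
    ic_trace: list            # records (step, species tuple, IC, action)
    final_diets: pd.DataFrame
    k_penalty: float
    settings: dict


def _fit_subset(subset, preds, db: PreyDatabase, cc, faset, n_starts, seed):
    means = db.subset_species(subset).species_means(faset)
    if len(subset) >= 2:
        fit = mle_diet(preds, means, cc, "isotropic", n_starts=n_starts, seed=seed)
    else:
        fit = _single_species_fit(preds, means, cc)
    return fit, means


def _single_species_fit(preds, means, cc):
    from .likelihood import MLEFit, _prep_matrix, _VAR_FLOOR
    from .compositions import clr
    X = _prep_matrix(preds, cc)
    m = means.to_numpy(dtype=float)[0]
    r = clr(X) - clr(m / m.sum())[None, :]
    n, K = X.shape
    s2 = max(float((r**2).mean()), _VAR_FLOOR)
    ll = float(-0.5 * n * K * np.log(2 * np.pi * s2) - (r**2).sum() / (2 * s2))
    return MLEFit(species=list(means.index), diets=np.ones((n, 1)), sigma2=np.array(s2),
                  loglik=ll, n_params=1, converged=True, variance_model="isotropic")


def ic_value(subset, preds, db: PreyDatabase, cc=None, k: float = 2.0, *,
             faset=None, n_starts: int = 3, seed: int = 0) -> float:
    """Information criterion for a candidate prey-species set."""
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("empty prey subset")
    fit, _ = _fit_subset(subset, preds, db, cc, faset, n_starts, seed)
    n_pred = np.atleast_2d(np.asarray(preds, dtype=float)).shape[0]
    n_params = n_pred * (len(subset) - 1) + 1
    return float(-2.0 * fit.loglik + k * n_params)


def backward_elimination(preds, db: PreyDatabase, cc=None, cutoff: float = 0.1,
                         k: float = 2.0, *, faset=None, n_starts: int = 3,
                         seed: int = 0) -> SelectionResult:
    """Drop prey types greedily while the criterion improves.

    Species whose estimated proportion is >= ``cutoff`` for any individual
    predator are protected from removal; among the unprotected, the drop
    with the lowest criterion is committed whenever it does not exceed the
    current criterion (ties favour the smaller model).
    """
    if db.n_species < 2:
        raise ValueError("backward elimination needs at least two species")
    current = list(db.species)
    trace = []
    step = 0
    current_ic = ic_value(current, preds, db, cc, k, faset=faset, n_starts=n_starts, seed=seed)
    trace.append((step, tuple(current), current_ic, "start"))
    while len(current) > 1:
        fit, _ = _fit_subset(current, preds, db, cc, faset, n_starts, seed)
        protected = {sp for i, sp in enumerate(current) if np.any(fit.diets[:, i] >= cutoff)}
        candidates = [sp for sp in current if sp not in protected]
        if not candidates:
            trace.append((step, tuple(current), current_ic, "stop: all protected"))
            break
        best_sp, best_ic = None, None
        for sp in candidates:
            trial = [s for s in current if s != sp]
            ic = ic_value(trial, preds, db, cc, k, faset=faset, n_starts=n_starts, seed=seed)
            if best_ic is None or ic < best_ic:
                best_sp, best_ic = sp, ic
        if best_ic <= current_ic:
            step += 1
            current = [s for s in current if s != best_sp]
            current_ic = best_ic
            trace.append((step, tuple(current), current_ic, f"drop {best_sp}"))
        else:
            trace.append((step, tuple(current), current_ic, "stop: no improving drop"))
            break
    final, _ = _fit_subset(current, preds, db, cc, faset, n_starts, seed)
    diets = pd.DataFrame(final.diets, columns=current)
    return SelectionResult(chosen_species=current, ic_trace=trace, final_diets=diets,
                           k_penalty=k, settings={"cutoff": cutoff, "method": "backward"})


def forward_selection(preds, db: PreyDatabase, cc=None, start=None, min_spec: int = 5,
                      k: float = 2.0, *, faset=None, n_starts: int = 3,
                      seed: int = 0) -> SelectionResult:
    """Add prey types greedily; force additions until ``min_spec`` reached.

    Without a starting set, the single species with the lowest one-species
    criterion seeds the search.  Additions beyond ``min_spec`` must strictly
    improve the criterion (ties stop the search).
    """
    species = list(db.species)
    if min_spec > len(species):
        warnings.warn(f"min_spec={min_spec} exceeds the {len(species)} available species; capped",
                      stacklevel=2)
        min_spec = len(species)
    trace = []
    step = 0
    if start:
        unknown = [s for s in start if s not in species]
        if unknown:
            raise ValueError(f"unknown starting species: {unknown}")
        current = [s for s in species if s in set(start)]
        current_ic = ic_value(current, preds, db, cc, k, faset=faset, n_starts=n_starts, seed=seed)
        trace.append((step, tuple(current), current_ic, "start (given)"))
    else:
        best_sp, best_ic = None, None
        for sp in species:
            ic = ic_value([sp], preds, db, cc, k, faset=faset, n_starts=n_starts, seed=seed)
            if best_ic is None or ic < best_ic:
                best_sp, best_ic = sp, ic
        current = [best_sp]
        current_ic = best_ic
        trace.append((step, tuple(current), current_ic, f"start {best_sp}"))
    while len(current) < len(species):
        remaining = [s for s in species if s not in current]
        best_sp, best_ic = None, None
        for sp in remaining:
            trial = [s for s in species if s in set(current) | {sp}]
            ic = ic_value(trial, preds, db, cc, k, faset=faset, n_starts=n_starts, seed=seed)
            if best_ic is None or ic < best_ic:
                best_sp, best_ic = sp, ic
        if len(current) < min_spec or best_ic < current_ic:
            step += 1
            current = [s for s in species if s in set(current) | {best_sp}]
            forced = len(current) <= min_spec
            current_ic = best_ic
            trace.append((step, tuple(current), current_ic,
                          f"add {best_sp}" + (" (forced)" if forced else "")))
        else:
            trace.append((step, tuple(current), current_ic, "stop: no improving addition"))
            break
    final, _ = _fit_subset(current, preds, db, cc, faset, n_starts, seed)
    diets = pd.DataFrame(final.diets, columns=current)
    return SelectionResult(chosen_species=current, ic_trace=trace, final_diets=diets,
                           k_penalty=k, settings={"min_spec": min_spec, "start": list(start or []),
                                                  "method": "forward"})
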