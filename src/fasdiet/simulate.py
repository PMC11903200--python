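"""Pseudo-predator generation and the synthetic prey-library generator.

Pseudo-predators are simulated predators with known ("true") diets, the
standard device for benchmarking signature-based diet estimators:

* :func:`pseudo_pred` (nonparametric): resample the prey library — either
  one random individual per supported species (``preysize=1``) or a
  bootstrap mean per species (``preysize=2``, the default) — and mix the
  sampled signatures with weights proportional to ``diet_i * fat_i`` (so
  that estimating and fat-rescaling inverts the construction exactly);
  calibration coefficients multiply the final signature.

* :func:`pseudo_pred_norm` (parametric): draw each supported species'
  signature from a multivariate normal on the clr scale (species mean,
  pooled within-species covariance) and mix.

:func:`synth_prey_db` builds a seeded synthetic prey library with a
two-layer generator: species base profiles are Dirichlet draws whose clr
deviations from the across-species centre are scaled by a ``separation``
knob, and individuals are logistic-normal noise around the species clr
means.  All ground truth (means, CC, fat, covariance) is returned, so
every estimator in the package can be exercised against known answers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .compositions import InvalidCompositionError, clr, clr_inv, renormalize, validate_positive
from .prey import PreyDatabase

__all__ = [
    "SyntheticScenario", "SyntheticTruth", "synth_prey_db",
    "PseudoPredator", "pseudo_pred", "pseudo_preds", "pseudo_pred_norm", "pseudo_preds_norm",
]


# ----------------------------------------------------------------------
# synthetic prey library

@dataclass
class SyntheticScenario:
    """Parameters of a synthetic prey library.

    Defaults emulate a marine prey library of the shape used in QFASA
    practice: 11 prey types, 39 FAs, 10-50 individuals per type.
    ``separation`` scales between-species clr contrast; ``within_sd`` is
    the within-species logistic-normal standard deviation per clr
    coordinate; ``concentration`` is the Dirichlet parameter of the base
    profiles.  ``seed`` is mandatory — the library is a pure function of
    the scenario.
    """

    n_species: int = 11
    n_individuals: int | Sequence[int] = 15
    n_fa: int = 39
    separation: float = 1.0
    concentration: float = 1.0
    within_sd: float = 0.15
    cc: np.ndarray | None = None
    fat: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility contract)")
        if self.n_species < 1 or self.n_fa < 2:
            raise ValueError("need at least one species and two FAs")
        if self.separation <= 0 or self.within_sd < 0 or self.concentration <= 0:
            raise ValueError("infeasible separation/noise request")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic prey library."""

    species: list
    fa_names: list
    clr_means: np.ndarray          # (R, K)
    mean_signatures: pd.DataFrame  # (R, K)
    within_cov: np.ndarray         # (K, K), common across species
    cc: np.ndarray
    fat: np.ndarray
    scenario: SyntheticScenario


def _centered_normal(rng, size, sd):
    e = rng.normal(0.0, sd, size=size)
    return e - e.mean(axis=-1, keepdims=True)


def synth_prey_db(scenario: SyntheticScenario) -> tuple[PreyDatabase, SyntheticTruth]:
    """Generate a seeded synthetic prey library plus its ground truth."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    R, K = sc.n_species, sc.n_fa
    base = rng.dirichlet(np.full(K, sc.concentration), size=R)
    B = clr(np.clip(base, 1e-12, None))
    centre = B.mean(axis=0, keepdims=True)
    B = centre + sc.separation * (B - centre)
    counts = ([int(sc.n_individuals)] * R if np.isscalar(sc.n_individuals)
              else [int(c) for c in sc.n_individuals])
    if len(counts) != R or min(counts) < 1:
        raise ValueError("n_individuals must be a positive int or one per species")
    species = [f"sp{i + 1:02d}" for i in range(R)]
    fa_names = [f"fa{k + 1:02d}" for k in range(K)]
    rows, labels = [], []
    for i in range(R):
        noise = _centered_normal(rng, (counts[i], K), sc.within_sd)
        rows.append(clr_inv(B[i][None, :] + noise))
        labels += [species[i]] * counts[i]
    X = np.vstack(rows)
    df = pd.DataFrame(X, columns=fa_names)
    df.insert(0, "species", labels)
    db = PreyDatabase(df)
    cc = np.ones(K) if sc.cc is None else validate_positive(sc.cc, "cc")
    fat = np.ones(R) if sc.fat is None else validate_positive(sc.fat, "fat")
    P = clr_inv(B)
    truth = SyntheticTruth(
        species=species, fa_names=fa_names, clr_means=B,
        mean_signatures=pd.DataFrame(P, index=species, columns=fa_names),
        within_cov=sc.within_sd**2 * (np.eye(K) - np.ones((K, K)) / K),
        cc=cc, fat=fat, scenario=sc,
    )
    return db, truth


# ----------------------------------------------------------------------
# pseudo-predators

@dataclass
class PseudoPredator:
    """One simulated predator with its generating diet and provenance."""

    signature: pd.Series
    true_diet: pd.Series
    seed: int
    provenance: dict


def _diet_vector(diet, species) -> np.ndarray:
    if isinstance(diet, pd.Series):
        d = diet.reindex(species).fillna(0.0).to_numpy(dtype=float)
    elif isinstance(diet, dict):
        unknown = set(diet) - set(species)
        if unknown:
            raise InvalidCompositionError(f"diet names unknown species: {sorted(unknown)}")
        d = np.array([float(diet.get(s, 0.0)) for s in species])
    else:
        d = np.asarray(diet, dtype=float)
        if d.shape[-1] != len(species):
            raise InvalidCompositionError("diet length does not match species count")
    if np.any(d < 0) or d.sum() <= 0:
        raise InvalidCompositionError("diet must be a nonnegative composition")
    return d / d.sum()


def _species_draw(rng, X_by_species, preysize):
    # one summary signature per species: a random individual, or a
    # bootstrap mean of the species sample
    out = {}
    for s, X in X_by_species.items():
        n = X.shape[0]
        if preysize == 1:
            idx = [int(rng.integers(n))]
        else:
            idx = list(rng.integers(n, size=n))
        out[s] = (X[idx].mean(axis=0), idx)
    return out


def pseudo_pred(diet, db: PreyDatabase, preysize: int = 2, cc=None, fat=None, *,
                seed: int | None = None, faset=None) -> PseudoPredator:
    """Generate one nonparametric pseudo-predator.

    ``preysize=1`` samples one individual per supported species;
    ``preysize=2`` (default) uses a per-species bootstrap mean.  Mixing
    weights are proportional to ``diet_i * fat_i``; the final signature is
    multiplied componentwise by ``cc`` and renormalized.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if preysize not in (1, 2):
        raise ValueError("preysize must be 1 or 2")
    rng = np.random.default_rng(seed)
    d = _diet_vector(diet, db.species)
    X = db.individuals(faset)
    fa_names = list(X.columns)
    lab = db.labels.to_numpy()
    support = [s for s, w in zip(db.species, d) if w > 0]
    X_by = {s: X.to_numpy()[lab == s] for s in support}
    draws = _species_draw(rng, X_by, preysize)
    fat_arr = np.ones(len(db.species)) if fat is None else validate_positive(fat, "fat")
    w = d * fat_arr
    w = w / w.sum()
    sig = np.zeros(len(fa_names))
    prov = {"preysize": preysize, "indices": {}}
    for s, wi in zip(db.species, w):
        if wi > 0:
            sig += wi * draws[s][0]
            prov["indices"][s] = draws[s][1]
    sig = renormalize(sig)
    if cc is not None:
        sig = renormalize(sig * validate_positive(cc, "cc"))
    return PseudoPredator(signature=pd.Series(sig, index=fa_names),
                          true_diet=pd.Series(d, index=db.species),
                          seed=int(seed), provenance=prov)


def pseudo_preds(diet, db: PreyDatabase, n: int, preysize: int = 2, cc=None, fat=None, *,
                 seed: int | None = None, faset=None) -> pd.DataFrame:
    """Generate ``n`` pseudo-predators (rows) with one seeded stream."""
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    ss = np.random.SeedSequence([int(seed) % 2**31])
    children = ss.spawn(n)
    rows = []
    for child in children:
        p = pseudo_pred(diet, db, preysize, cc, fat,
                        seed=int(child.generate_state(1)[0] % 2**31), faset=faset)
        rows.append(p.signature)
    return pd.DataFrame(rows).reset_index(drop=True)


def pseudo_pred_norm(diet, db: PreyDatabase, *, seed: int | None = None,
                     faset=None, eps: float = 1e-5) -> PseudoPredator:
    """Generate one parametric (logistic-normal) pseudo-predator.

    Each supported species' signature is drawn from a normal on the clr
    scale with the species clr mean and the pooled within-species clr
    covariance, then mixed by the diet.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    d = _diet_vector(diet, db.species)
    mu, covs, ns = db.clr_stats(faset, eps=eps)
    K = mu.shape[1]
    support = np.nonzero(d > 0)[0]
    if any(ns[i] < 2 for i in support):
        raise InvalidCompositionError("pooled covariance needs >= 2 individuals per supported species")
    dofs = np.array([n_i - 1 for n_i in ns if n_i > 1])
    pooled = sum((n_i - 1) * S for S, n_i in zip(covs, ns) if n_i > 1) / dofs.sum()
    try:
        L = np.linalg.cholesky(pooled + 1e-12 * np.eye(K))
    except np.linalg.LinAlgError:  # pragma: no cover - ridge makes this rare
        import warnings
        warnings.warn("singular pooled covariance; falling back to its diagonal", stacklevel=2)
        L = np.diag(np.sqrt(np.clip(np.diag(pooled), 1e-12, None)))
    sig = np.zeros(K)
    fa_names = db.fa_names if faset is None else list(faset)
    for i in support:
        z = mu[i] + L @ rng.standard_normal(K)
        sig += d[i] * clr_inv(z)
    sig = renormalize(sig)
    return PseudoPredator(signature=pd.Series(sig, index=fa_names),
                          true_diet=pd.Series(d, index=db.species),
                          seed=int(seed), provenance={"parametric": True})


def pseudo_preds_norm(diet, db: PreyDatabase, n: int, *, seed: int | None = None,
                      faset=None) -> pd.DataFrame:
    """Batch version of :func:`pseudo_pred_norm`."""
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    ss = np.random.SeedSequence([int(seed) % 2**31, 1])
    rows = [pseudo_pred_norm(diet, db, seed=int(c.generate_state(1)[0] % 2**31),
                             faset=faset).signature
            for c in ss.spawn(n)]
    return pd.DataFrame(rows).reset_index(drop=True)
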