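"""Compositional distances between FA signatures.

Three distances are selectable everywhere in the toolkit:

* ``KL`` — the symmetrized Kullback–Leibler divergence
  ``sum_k (x_k - y_k) * ln(x_k / y_k)`` of the original QFASA lineage;
* ``AIT`` — the Aitchison distance, the Euclidean norm of the difference of
  centred log-ratio (clr) vectors; a true metric on the simplex, invariant
  under perturbation;
* ``CS`` — a chi-square-type distance on power-transformed compositions,
  ``(1/gamma) * sqrt(2 * sum_k (u_k - v_k)^2 / (u_k + v_k))`` with
  ``u = x^gamma / sum(x^gamma)``.  It tolerates zeros without replacement:
  components where both parts are zero are dropped.

KL and AIT need strictly positive parts; zeros are replaced (see
:func:`fasdiet.compositions.zero_replace`) using the ``eps`` of the spec.
:func:`fa_terms` exposes the per-FA addends whose sum is the additive
objective minimized by the estimators (KL itself; squared AIT; squared CS).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositions import InvalidCompositionError, _auto_zero_replace, clr

__all__ = ["DistanceSpec", "as_spec", "distance", "fa_terms", "objective", "distance_matrix"]

KINDS = ("KL", "AIT", "CS")


@dataclass(frozen=True)
class DistanceSpec:
    """Choice of distance plus its preprocessing knobs.

    Parameters
    ----------
    kind : {"KL", "AIT", "CS"}
    eps : float
        Zero-replacement constant for KL/AIT (ignored by CS).
    gamma : float
        Power parameter of the CS distance, in (0, 1].
    """

    kind: str = "KL"
    eps: float = 1e-5
    gamma: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"distance kind must be one of {KINDS}, got {self.kind!r}")
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")


def as_spec(spec) -> DistanceSpec:
    if isinstance(spec, DistanceSpec):
        return spec
    if isinstance(spec, str):
        return DistanceSpec(kind=spec)
    raise TypeError(f"cannot interpret {spec!r} as a distance specification")


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidCompositionError(f"FA index mismatch: {x.shape} vs {y.shape}")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidCompositionError("negative proportions")
    return x, y


def _power_close(x: np.ndarray, gamma: float) -> np.ndarray:
    if gamma == 1.0:
        return x
    u = np.where(x > 0, x, 0.0) ** gamma
    return u / u.sum(axis=-1, keepdims=True)


def fa_terms(x, y, spec) -> np.ndarray:
    """Per-FA addends of the additive objective for the chosen distance.

    The sum of the returned vector is the KL distance, the *squared* AIT
    distance, or the *squared* CS distance respectively — the quantity the
    diet optimizer minimizes and reports as ``min_distance``.
    """
    spec = as_spec(spec)
    x, y = _check_pair(x, y)
    if spec.kind == "KL":
        x = _auto_zero_replace(x, spec.eps)[0] if x.ndim == 1 else _auto_zero_replace(x, spec.eps)
        y = _auto_zero_replace(y, spec.eps)[0] if y.ndim == 1 else _auto_zero_replace(y, spec.eps)
        return (x - y) * np.log(x / y)
    if spec.kind == "AIT":
        x = _auto_zero_replace(x, spec.eps)[0] if x.ndim == 1 else _auto_zero_replace(x, spec.eps)
        y = _auto_zero_replace(y, spec.eps)[0] if y.ndim == 1 else _auto_zero_replace(y, spec.eps)
        return (clr(x) - clr(y)) ** 2
    u = _power_close(x, spec.gamma)
    v = _power_close(y, spec.gamma)
    s = u + v
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, (u - v) ** 2 / np.where(s > 0, s, 1.0), 0.0)
    return 2.0 * t / spec.gamma**2


def objective(x, y, spec) -> float:
    """Sum of :func:`fa_terms` — the additive minimization objective."""
    return float(fa_terms(x, y, spec).sum(axis=-1))


def distance(x, y, spec) -> float:
    """The distance on its metric scale (sqrt of the objective for AIT/CS)."""
    spec = as_spec(spec)
    obj = objective(x, y, spec)
    if spec.kind == "KL":
        return max(obj, 0.0)
    return float(np.sqrt(max(obj, 0.0)))


def distance_matrix(sigs, spec) -> np.ndarray:
    """Symmetric pairwise distance matrix for a stack of signatures."""
    spec = as_spec(spec)
    X = np.atleast_2d(np.asarray(sigs, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two signatures")
    if np.any(X < 0):
        raise InvalidCompositionError("negative proportions")
    D = np.zeros((n, n))
    if spec.kind == "AIT":
        C = clr(_auto_zero_replace(X, spec.eps))
        diff = C[:, None, :] - C[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
    elif spec.kind == "KL":
        Z = _auto_zero_replace(X, spec.eps)
        L = np.log(Z)
        for i in range(n):
            D[i] = ((Z[i] - Z) * (L[i] - L)).sum(axis=1)
        D = np.maximum(D, 0.0)
    else:
        U = _power_close(X, spec.gamma)
        for i in range(n):
            s = U[i] + U
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(s > 0, (U[i] - U) ** 2 / np.where(s > 0, s, 1.0), 0.0)
            D[i] = np.sqrt(2.0 * t.sum(axis=1)) / spec.gamma
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0
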