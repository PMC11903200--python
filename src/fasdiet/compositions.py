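"""Compositional primitives for fatty-acid (FA) signature data.

An FA signature is a composition: K named, nonnegative proportions that sum
to one.  Everything downstream — diet estimation, calibration, inference —
operates on the simplex, so this module collects the low-level moves:
closure (validation + renormalization), subsetting to a chosen FA set,
zero replacement, the centred log-ratio (clr) transform and its inverse,
mapping predator signatures into prey space with calibration coefficients,
and converting biomass diet proportions to prey-count proportions with fat
contents.

Array-level functions accept 1-D signatures or 2-D stacks of signatures
(rows = individuals); pandas-facing helpers preserve FA names.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidCompositionError",
    "close",
    "renormalize",
    "subset_renormalize",
    "subset_frame",
    "zero_replace",
    "clr",
    "clr_inv",
    "cc_to_prey_space",
    "fat_rescale",
    "validate_positive",
]

#: tolerance under which a signature is accepted as already closed
SUM_TOL = 1e-8


class InvalidCompositionError(ValueError):
    """Raised when data cannot be interpreted as a valid composition."""


def _asarray(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidCompositionError("empty composition")
    if not np.all(np.isfinite(x)):
        raise InvalidCompositionError("non-finite values in composition")
    return x


def close(values, *, warn: bool = True) -> np.ndarray:
    """Validate raw signature data and close it to the unit simplex.

    Laboratory FA exports circulate both as proportions and as percentages,
    usually with rounding.  Rows whose raw sum lies in [90, 110] are taken
    to be percent-scale and divided by 100; rows whose sum then lies in
    [0.9, 1.1] are renormalized (with a warning unless already within
    ``SUM_TOL`` of one).  Sums outside those bands are rejected.
    """
    x = _asarray(values)
    if np.any(x < 0):
        raise InvalidCompositionError("negative proportions")
    single = x.ndim == 1
    X = np.atleast_2d(x).astype(float).copy()
    s = X.sum(axis=1)
    pct = (s >= 90.0) & (s <= 110.0)
    if pct.any():
        X[pct] /= 100.0
        s = X.sum(axis=1)
    bad = (s < 0.9) | (s > 1.1)
    if bad.any():
        raise InvalidCompositionError(
            f"signature sums outside [0.9, 1.1] (rows {np.nonzero(bad)[0][:5].tolist()}): "
            "not interpretable as proportions or percentages"
        )
    off = np.abs(s - 1.0) > SUM_TOL
    if warn and off.any():
        warnings.warn(
            f"{int(off.sum())} signature(s) renormalized to unit sum "
            f"(max deviation {np.abs(s - 1).max():.3g})",
            stacklevel=2,
        )
    X = X / s[:, None]
    return X[0] if single else X


def renormalize(values) -> np.ndarray:
    """Divide by the (positive) sum; error on a zero-sum vector."""
    x = _asarray(values)
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise InvalidCompositionError("cannot renormalize: nonpositive sum")
    return x / s


def subset_renormalize(sig: pd.Series, faset: Sequence[str]) -> pd.Series:
    """Extract the FAs in ``faset`` (in that order) and re-close to sum 1."""
    names = list(faset)
    if len(names) == 0:
        raise InvalidCompositionError("empty FA subset")
    if len(set(names)) != len(names):
        raise InvalidCompositionError("duplicate names in FA subset")
    missing = [n for n in names if n not in sig.index]
    if missing:
        raise InvalidCompositionError(f"FA(s) not present in signature: {missing}")
    sub = sig.loc[names].to_numpy(dtype=float)
    if sub.sum() <= 0:
        raise InvalidCompositionError("FA subset has zero total proportion")
    return pd.Series(sub / sub.sum(), index=names)


def subset_frame(df: pd.DataFrame, faset: Sequence[str] | None) -> pd.DataFrame:
    """Row-wise :func:`subset_renormalize` for a signature matrix."""
    if faset is None:
        names = list(df.columns)
    else:
        names = list(faset)
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise InvalidCompositionError(f"FA(s) not present in data: {missing}")
    sub = df.loc[:, names].to_numpy(dtype=float)
    s = sub.sum(axis=1)
    if np.any(s <= 0):
        raise InvalidCompositionError("FA subset has zero total proportion in some row(s)")
    return pd.DataFrame(sub / s[:, None], index=df.index, columns=names)


def zero_replace(values, eps: float = 1e-5, mode: str = "multiplicative") -> np.ndarray:
    """Replace zero parts so log-ratio methods are applicable.

    ``multiplicative`` sets each zero to ``eps`` and scales the nonzero
    parts by ``1 - z*eps`` (z = number of zeros in that row), preserving the
    unit sum exactly.  ``replace_renorm`` sets zeros to ``eps`` and recloses.
    ``eps`` must be positive and smaller than the smallest positive part.
    """
    if mode not in ("multiplicative", "replace_renorm"):
        raise ValueError(f"unknown zero-replacement mode {mode!r}")
    x = _asarray(values)
    if np.any(x < 0):
        raise InvalidCompositionError("negative proportions")
    single = x.ndim == 1
    X = np.atleast_2d(x).astype(float).copy()
    if np.any(X.sum(axis=1) <= 0):
        raise InvalidCompositionError("all-zero signature")
    pos = X[X > 0]
    if not (0 < eps < pos.min()):
        raise InvalidCompositionError(
            f"eps={eps} must lie in (0, smallest positive part={pos.min():.3g})"
        )
    zero = X == 0
    if zero.any():
        if mode == "multiplicative":
            z = zero.sum(axis=1)
            X = X * (1.0 - z[:, None] * eps)
            X[zero] = eps
        else:
            X[zero] = eps
            X = X / X.sum(axis=1, keepdims=True)
    return X[0] if single else X


def _auto_zero_replace(X: np.ndarray, eps: float) -> np.ndarray:
    # internal: apply zero replacement only when needed, shrinking eps below
    # the smallest positive part so sparse signatures never abort a fit
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not (X == 0).any():
        return X
    safe = min(eps, float(X[X > 0].min()) / 10.0)
    return zero_replace(X, eps=safe, mode="multiplicative")


def clr(values) -> np.ndarray:
    """Centred log-ratio transform: ln x_k - mean_j ln x_j (rows sum to 0)."""
    x = _asarray(values)
    if np.any(x <= 0):
        raise InvalidCompositionError("clr requires strictly positive parts (zero_replace first)")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def clr_inv(values) -> np.ndarray:
    """Inverse clr: closed exponentials (softmax), back on the simplex."""
    t = _asarray(values)
    e = np.exp(t - t.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def validate_positive(values, name: str = "vector") -> np.ndarray:
    x = _asarray(values)
    if np.any(x <= 0):
        raise InvalidCompositionError(f"{name} must be strictly positive")
    return x


def cc_to_prey_space(pred, cc) -> np.ndarray:
    """Map a predator signature into prey space: close(pred / cc).

    Calibration coefficients (CCs) are per-FA multiplicative constants for
    predator lipid metabolism; dividing by them undoes the deposition bias.
    Unit CCs are the identity.
    """
    x = _asarray(pred)
    c = validate_positive(cc, "calibration coefficients")
    if x.shape[-1] != c.shape[-1]:
        raise InvalidCompositionError(
            f"length mismatch: signature has {x.shape[-1]} FAs, CC has {c.shape[-1]}"
        )
    return renormalize(x / c)


def fat_rescale(diet, fat) -> np.ndarray:
    """Convert biomass diet proportions to prey-count proportions.

    Dividing each species' proportion by that species' mean fat content and
    reclosing turns "share of fat consumed" into "share of animals
    consumed".  Unit fat contents are the identity.
    """
    d = _asarray(diet)
    f = validate_positive(fat, "fat contents")
    if d.shape[-1] != f.shape[-1]:
        raise InvalidCompositionError(
            f"length mismatch: diet over {d.shape[-1]} species, fat over {f.shape[-1]}"
        )
    return renormalize(d / f)
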