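"""Distance-based repeatability of individual diet estimates over time.

Repeated diet estimates (individuals x occasions) are summarized by an
intraclass-correlation-type measure: pairwise squared distances between
diet compositions are decomposed with the Gower identity into among- and
within-group sums of squares for the individual and occasion groupings,
giving two-way pseudo mean squares, and the two-way agreement ICC formula
is applied.  The chi-square distance is the default because diet estimates
are compositional and frequently contain zeros.  The raw estimate is
biased; a bootstrap over individuals supplies the bias reversal
``2 * r_raw - mean(r*)`` and, optionally, a percentile confidence
interval of the bias-corrected bootstrap distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import as_spec, distance_matrix

__all__ = ["RepeatabilityResult", "distance_ss", "repeatability"]


def distance_ss(dm: np.ndarray, labels) -> tuple[float, float]:
    """Gower decomposition of squared pairwise distances by a grouping.

    ``SS_total = (1/N) * sum_{i<j} d_ij^2``;
    ``SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2``;
    returns ``(SS_among, SS_within)`` with ``SS_among = SS_total - SS_within``.
    """
    D = np.asarray(dm, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    lab = np.asarray(labels)
    if lab.shape[0] != D.shape[0]:
        raise ValueError("labels length must match the distance matrix")
    N = D.shape[0]
    D2 = D**2
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    for g in pd.unique(lab):
        idx = np.nonzero(lab == g)[0]
        if len(idx) == 0:
            raise ValueError("empty group")
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return float(ss_total - ss_within), float(ss_within)


@dataclass
class RepeatabilityResult:
    r_raw: float
    r_corrected: float
    ci: tuple[float, float] | None
    balanced: bool
    n_individuals: int
    n_occasions: int
    boot_estimates: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            "Distance-based repeatability of diet estimates",
            f"  individuals: {self.n_individuals}   occasions: {self.n_occasions}"
            f"   layout: {'balanced' if self.balanced else 'unbalanced'}",
            f"  r (raw): {self.r_raw:.4f}   r (bias-corrected): {self.r_corrected:.4f}",
        ]
        if self.ci is not None:
            lines.append(f"  bootstrap CI: ({self.ci[0]:.4f}, {self.ci[1]:.4f})")
        return "\n".join(lines)


def _icc_from_matrix(D: np.ndarray, ids: np.ndarray, occ: np.ndarray) -> float:
    N = len(ids)
    uniq_ids = pd.unique(ids)
    uniq_occ = pd.unique(occ)
    n, T = len(uniq_ids), len(uniq_occ)
    df_res = N - n - T + 1
    if n < 2 or df_res < 1:
        raise ValueError("repeatability needs >= 2 individuals and residual degrees of freedom")
    ss_ind, _ = distance_ss(D, ids)
    ss_occ, _ = distance_ss(D, occ)
    D2 = D**2
    ss_total = D2[np.triu_indices(N, 1)].sum() / N
    ss_res = max(ss_total - ss_ind - ss_occ, 0.0)
    ms_ind = ss_ind / (n - 1)
    ms_occ = ss_occ / (T - 1)
    ms_res = ss_res / df_res
    counts = pd.Series(ids).value_counts().to_numpy(dtype=float)
    if np.all(counts == counts[0]):
        k0 = float(counts[0])
    else:
        k0 = (N - (counts**2).sum() / N) / (n - 1)
    denom = ms_ind + (k0 - 1.0) * ms_res + (k0 / n) * (ms_occ - ms_res)
    if denom <= 0:
        return 0.0
    return float((ms_ind - ms_res) / denom)


def repeatability(diets, ids, occasions, spec="CS", *, B: int = 100,
                  want_ci: bool = False, ci_level: float = 0.95,
                  seed: int = 0) -> RepeatabilityResult:
    """Two-way distance-based repeatability with bootstrap bias correction.

    Parameters
    ----------
    diets : 2-D array or DataFrame
        One diet composition per row, aligned with ``ids`` and
        ``occasions``.
    ids, occasions : sequences
        Individual and occasion labels per row; missing cells are simply
        absent rows (the unbalanced formulas adjust the degrees of
        freedom and the ``k0`` coefficient).
    B : int
        Bootstrap resamples of individuals (with their occasion sets).
    """
    spec = as_spec(spec)
    X = (diets.to_numpy(dtype=float) if isinstance(diets, pd.DataFrame)
         else np.atleast_2d(np.asarray(diets, dtype=float)))
    ids = np.asarray(ids)
    occ = np.asarray(occasions)
    if not (len(ids) == len(occ) == X.shape[0]):
        raise ValueError("diets, ids and occasions must align row-wise")
    counts = pd.Series(ids).value_counts()
    if (counts >= 2).sum() == 0:
        raise ValueError("repeatability undefined: no individual has repeated occasions")
    D = distance_matrix(X, spec)
    r_raw = _icc_from_matrix(D, ids, occ)
    uniq_ids = pd.unique(ids)
    balanced = bool(counts.nunique() == 1)
    rng = np.random.default_rng(seed)
    stars = []
    rows_of = {i: np.nonzero(ids == i)[0] for i in uniq_ids}
    for _ in range(B):
        draw = rng.integers(len(uniq_ids), size=len(uniq_ids))
        rows, new_ids, new_occ = [], [], []
        for new_label, j in enumerate(draw):
            r = rows_of[uniq_ids[j]]
            rows.extend(r.tolist())
            new_ids.extend([new_label] * len(r))
            new_occ.extend(occ[r].tolist())
        idx = np.array(rows)
        try:
            stars.append(_icc_from_matrix(D[np.ix_(idx, idx)],
                                          np.array(new_ids), np.array(new_occ)))
        except ValueError:
            continue
    stars = np.array(stars) if stars else np.array([r_raw])
    r_corr = 2.0 * r_raw - float(stars.mean())
    ci = None
    if want_ci:
        bc = 2.0 * r_raw - stars
        a = (1.0 - ci_level) / 2.0
        ci = (float(np.quantile(bc, a)), float(np.quantile(bc, 1.0 - a)))
    return RepeatabilityResult(r_raw=float(r_raw), r_corrected=float(r_corr), ci=ci,
                               balanced=balanced, n_individuals=len(uniq_ids),
                               n_occasions=len(pd.unique(occ)),
                               boot_estimates=stars)
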