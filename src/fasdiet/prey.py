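"""The prey library: individual FA signatures grouped by species."""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .compositions import InvalidCompositionError, close, clr, subset_frame, zero_replace

__all__ = ["PreyDatabase", "prey_means"]


class PreyDatabase:
    """Reference collection of prey FA signatures, grouped by species.

    Parameters
    ----------
    data : DataFrame
        One row per prey individual: a species-label column plus one column
        per FA (proportions or percentages; closed on construction).
    species_col : str
        Name of the label column (default ``"species"``).

    Species order is the order of first appearance; at least one individual
    per species is required, and at least two species for diet estimation.
    """

    def __init__(self, data: pd.DataFrame, species_col: str = "species"):
        if species_col not in data.columns:
            raise InvalidCompositionError(f"missing species column {species_col!r}")
        fa_cols = [c for c in data.columns if c != species_col]
        if len(fa_cols) < 2:
            raise InvalidCompositionError("prey data needs at least two FA columns")
        if len(set(fa_cols)) != len(fa_cols):
            raise InvalidCompositionError("duplicated FA columns in prey data")
        labels = data[species_col].astype(str)
        sig = close(data[fa_cols].to_numpy(dtype=float))
        self.species_col = species_col
        self.fa_names: list[str] = list(fa_cols)
        self.labels: pd.Series = labels.reset_index(drop=True)
        self.signatures: pd.DataFrame = pd.DataFrame(sig, columns=self.fa_names)
        self.species: list[str] = list(dict.fromkeys(labels))
        counts = labels.value_counts()
        if (counts < 1).any():  # pragma: no cover - value_counts never yields 0
            raise InvalidCompositionError("species with no individuals")

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, species_col: str | None = None) -> "PreyDatabase":
        df = pd.read_csv(path)
        col = species_col or df.columns[0]
        return cls(df, species_col=col)

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def counts(self) -> pd.Series:
        """Individuals per species, in species order."""
        return self.labels.value_counts().reindex(self.species)

    def to_frame(self) -> pd.DataFrame:
        out = self.signatures.copy()
        out.insert(0, self.species_col, self.labels.to_numpy())
        return out

    # ------------------------------------------------------------------
    def subset_species(self, labels: Sequence[str]) -> "PreyDatabase":
        keep = [s for s in self.species if s in set(labels)]
        unknown = set(labels) - set(self.species)
        if unknown:
            raise InvalidCompositionError(f"unknown species: {sorted(unknown)}")
        mask = self.labels.isin(keep).to_numpy()
        return PreyDatabase(self.to_frame().loc[mask], species_col=self.species_col)

    def individuals(self, faset: Sequence[str] | None = None) -> pd.DataFrame:
        """Signature matrix, subset-renormalized to ``faset`` when given."""
        return subset_frame(self.signatures, faset)

    def species_means(self, faset: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-species arithmetic means of (subset-renormalized) signatures.

        Rows are species in species order; each row is re-closed so it lies
        exactly on the simplex.
        """
        X = self.individuals(faset)
        means = X.groupby(self.labels.to_numpy()).mean().reindex(self.species)
        m = means.to_numpy()
        return pd.DataFrame(m / m.sum(axis=1, keepdims=True), index=self.species, columns=X.columns)

    def clr_stats(self, faset: Sequence[str] | None = None, eps: float = 1e-5):
        """Per-species clr means and within-species clr covariances.

        Returns ``(clr_means, covs, counts)`` with ``clr_means`` an R x K
        array in species order and ``covs`` a list of K x K covariance
        matrices (zero matrix for single-individual species).
        """
        X = self.individuals(faset).to_numpy()
        X = zero_replace(X, eps=min(eps, float(X[X > 0].min()) / 10) if (X == 0).any() else eps)
        C = clr(X)
        lab = self.labels.to_numpy()
        mus, covs, ns = [], [], []
        for s in self.species:
            Cs = C[lab == s]
            mus.append(Cs.mean(axis=0))
            ns.append(len(Cs))
            covs.append(np.cov(Cs.T) if len(Cs) > 1 else np.zeros((C.shape[1], C.shape[1])))
        return np.array(mus), covs, np.array(ns)


def prey_means(db: PreyDatabase, faset: Sequence[str] | None = None) -> pd.DataFrame:
    """Functional alias for :meth:`PreyDatabase.species_means`."""
    return db.species_means(faset)
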