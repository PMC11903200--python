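"""Prey-library diagnostics.

Diet estimation can only distinguish prey types whose FA signatures are
distinct.  Two checks:

* :func:`prey_cluster` — agglomerative hierarchical clustering of the
  species mean signatures under a chosen compositional distance, with a
  dendrogram exportable to newick;
* :func:`prey_on_prey` — the leave-one-prey-out confusion matrix: each
  prey individual is treated as a predator (its own species mean is
  recomputed without it) and its diet estimated with unit calibration
  coefficients and no fat rescaling; for distinguishable species the
  diagonal of the per-species average diets is near one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import squareform

from .distances import as_spec, distance_matrix
from .estimation import estimate_diet
from .prey import PreyDatabase

__all__ = ["Dendrogram", "prey_cluster", "prey_on_prey"]

LINKAGES = ("average", "complete", "single", "ward")


@dataclass
class Dendrogram:
    """Merge tree over prey species mean signatures."""

    labels: list
    linkage_matrix: np.ndarray   # scipy linkage format, (R-1, 4)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def merges(self) -> np.ndarray:
        return self.linkage_matrix[:, :2].astype(int)

    def to_newick(self) -> str:
        """Serialize with branch lengths = merge-height differences."""
        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
        return root

    def plot(self, ax=None):
        """Basic dendrogram rendering (matplotlib)."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram
        if ax is None:
            _, ax = plt.subplots()
        scipy_dendrogram(self.linkage_matrix, labels=self.labels, ax=ax)
        ax.set_ylabel("merge distance")
        return ax


def prey_cluster(db: PreyDatabase, faset=None, spec="KL",
                 linkage: str = "average") -> Dendrogram:
    """Cluster species mean signatures under the chosen distance."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if db.n_species < 2:
        raise ValueError("clustering needs at least two species")
    spec = as_spec(spec)
    means = db.species_means(faset)
    D = distance_matrix(means.to_numpy(), spec)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(labels=list(means.index), linkage_matrix=Z)


def prey_on_prey(db: PreyDatabase, faset=None, spec="KL", *, n_starts: int = 5,
                 seed: int = 0) -> pd.DataFrame:
    """Leave-one-prey-out confusion matrix of average diet estimates.

    Row t is the mean estimated diet over the individuals of species t,
    each estimated against species means recomputed with that individual
    excluded (only the focal individual is removed).  Species with a single
    individual cannot be their own candidate and are skipped (row of NaN)
    with a warning.
    """
    spec = as_spec(spec)
    X = db.individuals(faset)
    lab = db.labels.to_numpy()
    species = db.species
    cols = list(X.columns)
    Xv = X.to_numpy()
    sums = {s: Xv[lab == s].sum(axis=0) for s in species}
    ns = {s: int((lab == s).sum()) for s in species}
    out = np.full((len(species), len(species)), np.nan)
    for t_i, t in enumerate(species):
        if ns[t] < 2:
            warnings.warn(f"species {t!r} has a single individual; leave-one-out "
                          "mean undefined — row skipped", stacklevel=2)
            continue
        rows = np.nonzero(lab == t)[0]
        acc = np.zeros(len(species))
        for j, r in enumerate(rows):
            means = np.vstack([
                (sums[s] - Xv[r]) / (ns[s] - 1) if s == t else sums[s] / ns[s]
                for s in species
            ])
            means = means / means.sum(axis=1, keepdims=True)
            mdf = pd.DataFrame(means, index=species, columns=cols)
            rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, t_i, j]))
            est = estimate_diet(Xv[r], mdf, spec, n_starts=n_starts, _rng=rng)
            acc += est.proportions
        out[t_i] = acc / len(rows)
    return pd.DataFrame(out, index=species, columns=species)
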