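"""Cross-species comparison of upstream bias profiles.

Each species is summarized by its vector of g_n values over upstream
positions -40..-1 for the four nucleotides (160 variables). Pairwise
similarity is the Pearson correlation r over these values (one grand mean
per species across all positions and nucleotides), converted to the
dissimilarity D = 1 - r. Species are clustered by group-average (UPGMA)
agglomeration over D and ordinated by a centered (unscaled) principal
component analysis of the same vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode
from sklearn.decomposition import PCA

from .errors import DegenerateInputError
from .gstats import NUCLEOTIDES, GProfile

#: Default upstream window summarized in a BiasVector.
DEFAULT_BIAS_WINDOW = (-40, -1)


@dataclass(frozen=True)
class BiasVector:
    """One species' ordered g_n vector over an upstream window.

    ``values`` is ordered position-major: for each position (ascending,
    -40..-1 by default) the four nucleotides in A, U, G, C order.
    """

    species_id: str
    values: np.ndarray
    window: tuple[int, int] = DEFAULT_BIAS_WINDOW

    def __post_init__(self) -> None:
        lo, hi = self.window
        expect = 4 * (hi - lo + 1)
        if len(self.values) != expect:
            raise ValueError(
                f"{self.species_id}: expected {expect} values for window "
                f"{self.window}, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.species_id}: non-finite g_n values")

    @classmethod
    def from_profile(
        cls,
        species_id: str,
        profile: GProfile,
        window: tuple[int, int] = DEFAULT_BIAS_WINDOW,
    ) -> "BiasVector":
        lo, hi = window
        values = []
        for pos in range(lo, hi + 1):
            idx = np.nonzero(profile.positions == pos)[0]
            if len(idx) == 0:
                raise DegenerateInputError(
                    f"{species_id}: profile lacks position {pos} needed for "
                    "the bias vector"
                )
            values.extend(profile.gn[idx[0]])
        return cls(species_id=species_id, values=np.array(values), window=window)

    def labels(self) -> list[str]:
        lo, hi = self.window
        return [f"{pos}:{n}" for pos in range(lo, hi + 1) for n in NUCLEOTIDES]


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson r and D = 1 - r between species bias vectors."""

    species: list[str]
    r: pd.DataFrame
    D: pd.DataFrame


def similarity_matrix(vectors: Sequence[BiasVector]) -> SimilarityMatrix:
    """Pearson-correlation similarity of species bias vectors.

    r is the standard Pearson correlation of the two vectors, centering each
    species by its grand mean over all positions and nucleotides; D = 1 - r.
    """
    if len(vectors) < 2:
        raise DegenerateInputError("similarity requires at least 2 species")
    windows = {v.window for v in vectors}
    if len(windows) != 1:
        raise DegenerateInputError(f"bias vectors use mismatched windows: {windows}")
    ids = [v.species_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise DegenerateInputError("duplicate species ids in cohort")
    X = np.vstack([v.values for v in vectors])
    sd = X.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            raise DegenerateInputError(
                f"species {ids[i]!r} has a zero-variance bias vector; "
                "correlation is undefined"
            )
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    r_df = pd.DataFrame(r, index=ids, columns=ids)
    return SimilarityMatrix(species=ids, r=r_df, D=1.0 - r_df)


@dataclass
class Dendrogram:
    """Group-average (UPGMA) agglomeration of species over D."""

    species: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.species)
        return str(tree).strip()

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster labels for the given number of clusters."""
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.species, (int(x) for x in labels)))


def cluster(matrix: SimilarityMatrix) -> Dendrogram:
    """Cluster species by group-average linkage on the D matrix."""
    D = matrix.D.to_numpy()
    condensed = squareform(D, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(species=list(matrix.species), linkage=linkage)


@dataclass
class PCAResult:
    """Centered PCA of species bias vectors.

    ``loadings`` rows are components over the 160 variables; ``scores`` rows
    are species. Signs are fixed by making each component's
    largest-magnitude loading positive.
    """

    species: list[str]
    variable_labels: list[str]
    scores: pd.DataFrame  # species x components
    loadings: pd.DataFrame  # components x variables
    variance_ratio: np.ndarray
    degenerate: bool = False


def pca(vectors: Sequence[BiasVector], k: int = 3) -> PCAResult:
    """Principal components of the species' g_n vectors (centered, unscaled)."""
    if len(vectors) < 2:
        raise DegenerateInputError("PCA requires at least 2 species")
    n_var = len(vectors[0].values)
    max_k = min(len(vectors) - 1, n_var)
    if k > max_k:
        raise DegenerateInputError(
            f"k={k} components exceed the maximum {max_k} for "
            f"{len(vectors)} species x {n_var} variables"
        )
    ids = [v.species_id for v in vectors]
    X = np.vstack([v.values for v in vectors])
    if np.allclose(X, X[0]):
        comp_labels = [f"PC{i + 1}" for i in range(k)]
        return PCAResult(
            species=ids,
            variable_labels=vectors[0].labels(),
            scores=pd.DataFrame(0.0, index=ids, columns=comp_labels),
            loadings=pd.DataFrame(
                0.0, index=comp_labels, columns=vectors[0].labels()
            ),
            variance_ratio=np.zeros(k),
            degenerate=True,
        )
    model = PCA(n_components=k)
    scores = model.fit_transform(X)
    loadings = model.components_
    # reproducible sign convention: dominant loading entry positive
    for c in range(k):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    comp_labels = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        species=ids,
        variable_labels=vectors[0].labels(),
        scores=pd.DataFrame(scores, index=ids, columns=comp_labels),
        loadings=pd.DataFrame(
            loadings, index=comp_labels, columns=vectors[0].labels()
        ),
        variance_ratio=model.explained_variance_ratio_,
    )
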