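"""PPI adjacency construction and PCA embedding.

Each mRNA inherits the weighted interaction row of its encoded protein.
The corpus-level adjacency matrix (n_mrna x n_mrna, symmetric,
zero diagonal; mRNAs absent from the network get all-zero rows) is
column-mean-centred and reduced by PCA, keeping a fixed number of
principal components per mRNA (default 500). Component signs are fixed
by forcing the largest-magnitude loading of each component to be
positive, so embeddings are reproducible across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.decomposition import PCA

from rnaloc.io import PpiEdgeList

DEFAULT_N_COMPONENTS = 500


@dataclass
class PpiAdjacency:
    ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n, n):
            raise ValueError("adjacency must be square over the id list")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if (self.weights < 0).any():
            raise ValueError("adjacency weights must be non-negative")


@dataclass
class PpiEmbedding:
    ids: list[str]
    components: np.ndarray  # (n_mrna, n_components) scores
    explained_variance_ratio: np.ndarray
    mean: np.ndarray  # column means subtracted before projection
    rotation: np.ndarray  # (n_features, n_components) loadings

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, rows: np.ndarray) -> np.ndarray:
        """Project new adjacency rows with the fitted centring/rotation."""
        return (np.asarray(rows, dtype=float) - self.mean) @ self.rotation


def build_adjacency(edges: PpiEdgeList, ids: Sequence[str]) -> PpiAdjacency:
    """Symmetric weighted adjacency over ``ids``; unknown-id edges dropped.

    mRNAs with no edges get all-zero rows. Edges whose endpoints are not
    in ``ids`` are skipped with a single warning giving the count.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    index = {m: i for i, m in enumerate(ids)}
    weights = np.zeros((len(ids), len(ids)))
    skipped = 0
    for a, b, w in edges.edges:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            skipped += 1
            continue
        weights[ia, ib] = weights[ib, ia] = w
    if skipped:
        warnings.warn(f"{skipped} edge(s) skipped: endpoint not in the corpus")
    return PpiAdjacency(ids=ids, weights=weights)


def _fix_signs(rotation: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: largest-magnitude loading of each component is positive
    flip = np.sign(rotation[np.abs(rotation).argmax(axis=0), np.arange(rotation.shape[1])])
    flip[flip == 0] = 1.0
    return rotation * flip, scores * flip


def pca_reduce(
    adj: PpiAdjacency,
    n_components: int = DEFAULT_N_COMPONENTS,
    fit_scope: Literal["whole_corpus", "train_fold_only"] = "whole_corpus",
    train_ids: Sequence[str] | None = None,
) -> PpiEmbedding:
    """PCA-project the adjacency rows to ``n_components`` scores per mRNA.

    Columns are mean-centred before the SVD (no variance scaling). With
    ``fit_scope="train_fold_only"`` the centring and rotation are fitted
    on the rows of ``train_ids`` only and applied to every row, so no
    held-out information enters the fit; the default fits the whole
    corpus once, matching a workflow where the embedding is computed
    before cross-validation.
    """
    n = len(adj.ids)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if fit_scope == "train_fold_only":
        if train_ids is None:
            raise ValueError("train_fold_only scope requires train_ids")
        rows = [adj.ids.index(m) for m in train_ids]
        fit_data = adj.weights[rows]
    elif fit_scope == "whole_corpus":
        fit_data = adj.weights
    else:
        raise ValueError(f"unknown fit_scope {fit_scope!r}")
    if n_components > fit_data.shape[0]:
        raise ValueError(
            f"n_components={n_components} exceeds the {fit_data.shape[0]} fitted rows; "
            "lower n_components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(fit_data)
    rotation = pca.components_.T  # (n_features, n_components)
    scores = (adj.weights - pca.mean_) @ rotation
    rotation, scores = _fix_signs(rotation, scores)
    return PpiEmbedding(
        ids=list(adj.ids),
        components=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
        rotation=rotation,
    )
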