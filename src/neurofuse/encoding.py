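"""Visual vocabulary learning and BoVW/VLAD encoding.

A codebook of K centroids is learned by K-means on training-fold
descriptors only.  Descriptors are assigned to their nearest centroid
(hard assignment, ties broken toward the lowest centroid index) either by
an exact linear scan or by a k-d-tree index queried approximately; per
pyramid cell the bag-of-visual-words (BoVW) encoding counts assignments
per word, while VLAD sums descriptor-minus-centroid residuals per word.
Per-cell blocks are concatenated in word order within cell order within
layer order; normalization is a separate stage (:mod:`neurofuse.normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .descriptors import DescriptorSet, PyramidLayout, assign_pyramid_cells
from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "Codebook",
    "fit_codebook",
    "assign_words",
    "encode_bovw",
    "encode_vlad",
    "BoVWEncoder",
    "VLADEncoder",
    "EncodedFeature",
]

_CODEBOOK_FORMAT_VERSION = 1


@dataclass
class Codebook:
    """K-means visual vocabulary with a nearest-neighbor index.

    ``assign`` with ``exact=True`` guarantees the true nearest centroid
    with ties broken toward the lowest index; the default query goes
    through a k-d tree with a small approximation slack (``approx_eps``),
    which must agree with the exact assignment on at least 99% of probes.
    """

    centroids: np.ndarray
    approx_eps: float = 0.05
    train_fold_id: str = ""

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ConfigurationError("centroids must be a (K, D) array, K >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise InputDataError("centroids must be finite")
        self._index = cKDTree(self.centroids)

    @property
    def n_words(self) -> int:
        return self.centroids.shape[0]

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def assign(self, X: np.ndarray, exact: bool = False) -> np.ndarray:
        """Nearest-centroid index per row of X (Eq.-style hard assignment)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise InputDataError(
                f"descriptor dimension {X.shape[1]} does not match "
                f"codebook dimension {self.dim}"
            )
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        if exact:
            # argmin returns the first (lowest-index) minimizer: tie rule.
            return np.argmin(cdist(X, self.centroids), axis=1)
        _, idx = self._index.query(X, k=1, eps=self.approx_eps)
        return np.asarray(idx, dtype=int)

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            version=np.array([_CODEBOOK_FORMAT_VERSION]),
            centroids=self.centroids,
            approx_eps=np.array([self.approx_eps]),
            train_fold_id=np.array([self.train_fold_id]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        data = np.load(path, allow_pickle=False)
        version = int(data["version"][0])
        if version != _CODEBOOK_FORMAT_VERSION:
            raise InputDataError(f"unsupported codebook format version {version}")
        return cls(
            centroids=data["centroids"],
            approx_eps=float(data["approx_eps"][0]),
            train_fold_id=str(data["train_fold_id"][0]),
        )


def fit_codebook(
    X: np.ndarray,
    n_words: int,
    seed: int = 0,
    n_init: int = 2,
    train_fold_id: str = "",
) -> Codebook:
    """Learn a K-means codebook from pooled training descriptors.

    Runs Lloyd's algorithm to convergence (no reassignment changes on the
    final pass); deterministic given ``seed``.  Raises a descriptive error
    when fewer than ``n_words`` distinct descriptors are provided.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise InputDataError("cannot fit a codebook on an empty descriptor set")
    if X.ndim != 2:
        raise InputDataError(f"descriptors must be (M, D), got shape {X.shape}")
    if n_words < 1:
        raise ConfigurationError(f"n_words must be >= 1, got {n_words}")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < n_words:
        raise InputDataError(
            f"need at least {n_words} distinct descriptors to learn "
            f"{n_words} words, got {n_distinct}"
        )
    km = KMeans(
        n_clusters=n_words,
        n_init=n_init,
        random_state=seed % (2**31),
        algorithm="lloyd",
        tol=1e-10,
        max_iter=300,
    ).fit(X)
    return Codebook(centroids=km.cluster_centers_, train_fold_id=train_fold_id)


def assign_words(
    codebook: Codebook, dset: DescriptorSet | np.ndarray, exact: bool = False
) -> np.ndarray:
    """One-hot cluster indicator per descriptor, returned as indices."""
    X = dset.descriptors if isinstance(dset, DescriptorSet) else dset
    return codebook.assign(X, exact=exact)


@dataclass
class EncodedFeature:
    """One subject-volume encoding: concatenated per-cell blocks."""

    kind: str
    vector: np.ndarray
    n_words: int
    dim: int
    n_cells: int

    @property
    def block_length(self) -> int:
        return self.vector.size // self.n_cells


def _require_cells(dset: DescriptorSet, layout: PyramidLayout) -> DescriptorSet:
    if dset.layout != layout or set(dset.cells) != set(range(len(layout.grids))):
        dset = assign_pyramid_cells(dset, layout)
    return dset


def encode_bovw(
    codebook: Codebook,
    dset: DescriptorSet,
    layout: PyramidLayout = PyramidLayout(),
    exact: bool = False,
) -> EncodedFeature:
    """Per-cell K-bin occurrence histograms, concatenated over cells.

    Within one layer the per-cell histograms sum bin-wise to the layer-1
    histogram (partition additivity); empty cells yield zero blocks.
    """
    dset = _require_cells(dset, layout)
    words = assign_words(codebook, dset, exact=exact)
    K = codebook.n_words
    parts = []
    for li, (gr, gc) in enumerate(layout.grids):
        ncells = gr * gc
        ids = dset.cells[li]
        hist = np.bincount(ids * K + words, minlength=ncells * K).astype(float)
        parts.append(hist)
    return EncodedFeature(
        kind="bovw",
        vector=np.concatenate(parts),
        n_words=K,
        dim=codebook.dim,
        n_cells=layout.total_cells,
    )


def encode_vlad(
    codebook: Codebook,
    dset: DescriptorSet,
    layout: PyramidLayout = PyramidLayout(),
    exact: bool = False,
    intra_l2: bool = False,
) -> EncodedFeature:
    """Per-cell, per-word residual sums v_k = Σ_{NN(x)=μ_k} (x − μ_k).

    Blocks are concatenated in word order within cell order within layer
    order.  ``intra_l2`` optionally l2-normalizes each per-word block
    before concatenation (off by default); global normalization is a
    separate stage.
    """
    dset = _require_cells(dset, layout)
    words = assign_words(codebook, dset, exact=exact)
    K, D = codebook.n_words, codebook.dim
    X = dset.descriptors
    residuals = X - codebook.centroids[words] if len(dset) else X
    parts = []
    for li, (gr, gc) in enumerate(layout.grids):
        ncells = gr * gc
        ids = dset.cells[li]
        acc = np.zeros((ncells, K, D))
        if len(dset):
            np.add.at(acc, (ids, words), residuals)
        if intra_l2:
            norms = np.linalg.norm(acc, axis=2, keepdims=True)
            acc = np.divide(acc, norms, out=acc, where=norms > 1e-12)
        parts.append(acc.reshape(-1))
    return EncodedFeature(
        kind="vlad",
        vector=np.concatenate(parts),
        n_words=K,
        dim=D,
        n_cells=layout.total_cells,
    )


class _BaseEncoder(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing for the BoVW and VLAD encoders.

    ``fit`` pools the descriptors of the provided (training-fold)
    descriptor sets and learns the codebook; ``transform`` encodes any
    descriptor sets with that fixed vocabulary, one row per set.
    """

    _kind = ""

    def __init__(
        self,
        n_words: int,
        layout: PyramidLayout = PyramidLayout(),
        seed: int = 0,
        n_init: int = 2,
        exact: bool = False,
    ):
        self.n_words = n_words
        self.layout = layout
        self.seed = seed
        self.n_init = n_init
        self.exact = exact

    def fit(self, dsets: list[DescriptorSet], y=None):
        pooled = np.vstack([d.descriptors for d in dsets])
        self.codebook_ = fit_codebook(
            pooled, self.n_words, seed=self.seed, n_init=self.n_init
        )
        return self

    def _encode(self, dset: DescriptorSet) -> EncodedFeature:
        raise NotImplementedError

    def transform(self, dsets: list[DescriptorSet]) -> np.ndarray:
        if not hasattr(self, "codebook_"):
            raise InputDataError("encoder is not fitted")
        return np.vstack([self._encode(d).vector for d in dsets])


class BoVWEncoder(_BaseEncoder):
    """Bag-of-visual-words encoder (default vocabulary size 256)."""

    _kind = "bovw"

    def __init__(self, n_words: int = 256, layout=PyramidLayout(), seed: int = 0,
                 n_init: int = 2, exact: bool = False):
        super().__init__(n_words, layout, seed, n_init, exact)

    def _encode(self, dset):
        return encode_bovw(self.codebook_, dset, self.layout, exact=self.exact)


class VLADEncoder(_BaseEncoder):
    """VLAD encoder (default vocabulary size 64)."""

    _kind = "vlad"

    def __init__(self, n_words: int = 64, layout=PyramidLayout(), seed: int = 0,
                 n_init: int = 2, exact: bool = False, intra_l2: bool = False):
        super().__init__(n_words, layout, seed, n_init, exact)
        self.intra_l2 = intra_l2

    def _encode(self, dset):
        return encode_vlad(
            self.codebook_, dset, self.layout, exact=self.exact,
            intra_l2=self.intra_l2,
        )
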