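"""Vector-quantization codebook: 150 Voronoi cells over spectral slices.

The codebook is a k-means partition of the training slice vectors
(squared-Euclidean distance on dB spectra).  Encoding maps each slice to
the index of its nearest centroid, which becomes the discrete emission
symbol consumed by the HMMs.  Codebooks are fitted on training-partition
slices only — pooled across subjects within an experiment so that
log-probabilities are comparable across subject models.
"""

from __future__ import annotations

import hashlib

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin
from sklearn.utils.validation import check_is_fitted

from .containers import EmissionSequence, SliceSequence

__all__ = ["VectorQuantizer", "fit_codebook", "encode"]


class VectorQuantizer(BaseEstimator, TransformerMixin):
    """K-means codebook with nearest-centroid (Voronoi) encoding.

    Parameters
    ----------
    n_codes : int
        Number of Voronoi cells (default 150).
    n_restarts : int
        k-means++ restarts; the run with the lowest inertia wins.
    max_training_vectors : int or None
        Optional seeded subsample cap on the training slices; useful for
        reduced-scale runs where fitting on every slice buys nothing.
    random_state : int or None
        Seed for initialization and subsampling.

    Attributes
    ----------
    centroids_ : ndarray of shape (n_codes, n_dims)
    inertia_ : float
        Total squared quantization error on the (possibly subsampled)
        training slices.
    fingerprint_ : str
        SHA-256 prefix of the training partition, recorded to make
        train/test leakage auditable.
    """

    def __init__(
        self,
        n_codes: int = 150,
        n_restarts: int = 5,
        max_iter: int = 300,
        tol: float = 1e-6,
        max_training_vectors: int | None = None,
        random_state: int | None = None,
    ):
        self.n_codes = n_codes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.max_training_vectors = max_training_vectors
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("training slices must form a 2-D (n, dim) array")
        if X.shape[0] < self.n_codes:
            raise ValueError(
                f"codebook of {self.n_codes} cells needs at least "
                f"{self.n_codes} training slices, got {X.shape[0]}"
            )
        fingerprint = hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()[:16]
        if (
            self.max_training_vectors is not None
            and X.shape[0] > self.max_training_vectors
        ):
            rng = np.random.default_rng(self.random_state)
            keep = rng.choice(X.shape[0], self.max_training_vectors, replace=False)
            X = X[np.sort(keep)]
        km = KMeans(
            n_clusters=self.n_codes,
            init="k-means++",
            n_init=self.n_restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(X)
        self.centroids_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        self.fingerprint_ = fingerprint
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Symbols: index of the nearest centroid per slice (ties -> lowest)."""
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[0] == 0:
            raise ValueError("cannot encode an empty slice collection")
        if X.shape[1] != self.centroids_.shape[1]:
            raise ValueError(
                f"slice dimension {X.shape[1]} does not match codebook "
                f"dimension {self.centroids_.shape[1]}"
            )
        return pairwise_distances_argmin(X, self.centroids_).astype(np.int64)

    def quantization_error(self, X) -> float:
        """Total squared distance of slices to their assigned centroids."""
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        sym = self.transform(X)
        return float(np.sum((X - self.centroids_[sym]) ** 2))


def fit_codebook(
    slices: np.ndarray, k: int = 150, seed: int | None = None, **kwargs
) -> VectorQuantizer:
    """Fit a ``k``-cell codebook on a stack of slice vectors."""
    return VectorQuantizer(n_codes=k, random_state=seed, **kwargs).fit(slices)


def encode(seq: SliceSequence, codebook: VectorQuantizer) -> EmissionSequence:
    """Quantize one slice sequence into discrete emission symbols."""
    symbols = codebook.transform(seq.slices)
    return EmissionSequence(symbols=symbols, labels=dict(seq.labels))
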