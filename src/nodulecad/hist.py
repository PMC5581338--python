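"""Histogram-feature baseline (HIST): segmentation-dependent KNN method.

The comparison method summarises the HU histogram of the voxels inside a
nodule's (radiologist-drawn) segmentation with seven statistics --
entropy, standard deviation, mean normalized bin height, maximum
normalized bin height, and the 5%, 25% and 75% HU quantiles -- and
classifies or scores nodules with a k-nearest-neighbour rule (k = 12,
Euclidean distance on z-scored features).  Unlike the CNN route, this
method fails outright when the segmentation is empty, which is exactly the
failure mode that motivates the segmentation-free approach.

Histogram defaults: 48 bins over (-1000, 200) HU, a 25 HU bin width that
spans aerated lung through solid soft tissue; out-of-range voxels are
clipped into the end bins.  All features are computed from the full 3D set
of masked voxels of a nodule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

__all__ = [
    "HistFeatures",
    "hist_features",
    "knn_classify",
    "knn_regress",
    "HistKNNClassifier",
    "HistKNNRegressor",
]

DEFAULT_N_BINS = 48
DEFAULT_HU_RANGE = (-1000.0, 200.0)
DEFAULT_K = 12

#: Order of the feature vector columns.
FEATURE_NAMES = (
    "entropy",
    "std_hu",
    "mean_bin_height",
    "max_bin_height",
    "q05",
    "q25",
    "q75",
)


@dataclass
class HistFeatures:
    """The seven histogram summary statistics of one nodule."""

    entropy: float
    std_hu: float
    mean_bin_height: float
    max_bin_height: float
    q05: float
    q25: float
    q75: float
    nodule_id: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def hist_features(
    masked_voxels: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE,
    nodule_id: str | None = None,
) -> HistFeatures:
    """Histogram summary statistics of the voxels inside a segmentation.

    The histogram is normalized to fractions; entropy is
    ``-sum(p * log2 p)`` over non-zero bins (bits, at most ``log2 n_bins``);
    the standard deviation is the population SD of the raw voxel values;
    quantiles use linear interpolation.
    """
    voxels = np.asarray(masked_voxels, dtype=np.float64).ravel()
    if voxels.size == 0:
        raise ValueError(
            "empty segmentation mask: histogram features are undefined"
        )
    lo, hi = hu_range
    clipped = np.clip(voxels, lo, hi)  # out-of-range voxels land in end bins
    counts, _ = np.histogram(clipped, bins=n_bins, range=hu_range)
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return HistFeatures(
        entropy=entropy,
        std_hu=float(voxels.std(ddof=0)),
        mean_bin_height=float(p.mean()),
        max_bin_height=float(p.max()),
        q05=float(np.quantile(voxels, 0.05)),
        q25=float(np.quantile(voxels, 0.25)),
        q75=float(np.quantile(voxels, 0.75)),
        nodule_id=nodule_id,
    )


def _check_knn_inputs(train_feats, train_y, query_feats, k):
    train_feats = np.asarray(train_feats, dtype=np.float64)
    query_feats = np.atleast_2d(np.asarray(query_feats, dtype=np.float64))
    train_y = np.asarray(train_y)
    if len(train_feats) != len(train_y):
        raise ValueError("feature/label length mismatch")
    if k > len(train_feats):
        raise ValueError(f"k={k} exceeds the {len(train_feats)} training samples")
    return train_feats, train_y, query_feats


class HistKNNClassifier(BaseEstimator, ClassifierMixin):
    """KNN majority vote on z-scored histogram features.

    Features are standardised with statistics of the training fold only.
    Vote ties are broken in favour of the class with the smaller mean
    neighbour distance, then the lower class index, making predictions
    fully deterministic.
    """

    def __init__(self, k: int = DEFAULT_K):
        self.k = k

    def fit(self, X, y):
        X, y, _ = _check_knn_inputs(X, y, X[:1], self.k)
        self.scaler_ = StandardScaler().fit(X)
        self._Xs = self.scaler_.transform(X)
        self._y = y
        self.classes_ = np.unique(y)
        self.nn_ = NearestNeighbors(n_neighbors=self.k).fit(self._Xs)
        return self

    def predict(self, X) -> np.ndarray:
        Xq = self.scaler_.transform(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        dist, idx = self.nn_.kneighbors(Xq)
        out = []
        for d_row, i_row in zip(dist, idx):
            labels = self._y[i_row]
            votes = {c: int((labels == c).sum()) for c in np.unique(labels)}
            top = max(votes.values())
            tied = sorted(c for c, v in votes.items() if v == top)
            if len(tied) > 1:
                mean_d = {c: d_row[labels == c].mean() for c in tied}
                best = min(mean_d.values())
                tied = sorted(c for c, v in mean_d.items() if v <= best + 1e-12)
            out.append(tied[0])
        return np.asarray(out)


class HistKNNRegressor(BaseEstimator, RegressorMixin):
    """KNN regression: mean score of the k nearest training nodules."""

    def __init__(self, k: int = DEFAULT_K):
        self.k = k

    def fit(self, X, y):
        X, y, _ = _check_knn_inputs(X, y, X[:1], self.k)
        self.scaler_ = StandardScaler().fit(X)
        self._y = np.asarray(y, dtype=np.float64)
        self.nn_ = NearestNeighbors(n_neighbors=self.k).fit(self.scaler_.transform(X))
        return self

    def predict(self, X) -> np.ndarray:
        Xq = self.scaler_.transform(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        _, idx = self.nn_.kneighbors(Xq)
        return self._y[idx].mean(axis=1)


def knn_classify(train_feats, train_labels, query_feats, k: int = DEFAULT_K):
    """Functional form of :class:`HistKNNClassifier` (z-scored, tie-broken)."""
    train_feats, train_labels, query_feats = _check_knn_inputs(
        train_feats, train_labels, query_feats, k
    )
    model = HistKNNClassifier(k=k).fit(train_feats, train_labels)
    return model.predict(query_feats)


def knn_regress(train_feats, train_scores, query_feats, k: int = DEFAULT_K):
    """Functional form of :class:`HistKNNRegressor`."""
    train_feats, train_scores, query_feats = _check_knn_inputs(
        train_feats, train_scores, query_feats, k
    )
    model = HistKNNRegressor(k=k).fit(train_feats, train_scores)
    return model.predict(query_feats)
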