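"""Random-forest regression from CNN features to a 1-5 attenuation score.

The regression target for a nodule is the mean of its annotators' integer
scores, so targets are continuous in [1, 5].  A standard CART regression
forest (bootstrap resampling, sqrt(d) candidate features per split,
unlimited depth) maps the 84-dimensional penultimate-layer CNN features of
each patch to a score; because forest predictions are means of training
leaf values they are guaranteed to stay inside the training-target range,
hence inside [1, 5].  Patch-level predictions are aggregated to nodule
level by the evaluation module, which keeps the regressor agnostic of the
slice-selection strategy.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .cnn import SmallCNNClassifier

__all__ = ["train_rf", "predict_score", "CNNFeatureRegressor"]


def train_rf(
    features: np.ndarray,
    targets: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> RandomForestRegressor:
    """Fit the regression forest on patch features and per-patch targets."""
    features = np.asarray(features, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if features.ndim != 2 or len(features) != len(targets):
        raise ValueError("features must be (n, d) with one target per row")
    if len(np.unique(targets)) < 2:
        # A constant-target forest is still valid (predicts the constant),
        # but warn-level situations are left to the caller; fit proceeds.
        pass
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(features, targets)
    return forest


def predict_score(forest: RandomForestRegressor, features: np.ndarray) -> np.ndarray:
    """Per-patch score: mean of the trees' leaf predictions."""
    return forest.predict(np.asarray(features, dtype=np.float64))


class CNNFeatureRegressor(BaseEstimator, RegressorMixin):
    """CNN feature extractor composed with a random forest, fit on patches.

    Parameters
    ----------
    cnn : SmallCNNClassifier
        A *fitted* classifier whose hidden-layer activations are used as
        features.  It is not re-trained here.
    n_trees, max_features, random_state :
        Forest hyper-parameters (standard defaults; the forest is not the
        sensitive part of the pipeline).
    """

    def __init__(
        self,
        cnn: SmallCNNClassifier,
        n_trees: int = 100,
        max_features: str | float = "sqrt",
        random_state: int = 0,
    ):
        self.cnn = cnn
        self.n_trees = n_trees
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        feats = self.cnn.extract_features(X)
        self.forest_ = train_rf(
            feats, y, n_trees=self.n_trees, seed=self.random_state,
            max_features=self.max_features,
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise RuntimeError("regressor is not fitted")
        return predict_score(self.forest_, self.cnn.extract_features(X))
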