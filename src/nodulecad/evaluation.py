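"""Consensus aggregation, score-to-class mapping and agreement statistics.

A nodule's class/score is predicted per 2D patch and then combined:

* SINGLE -- exactly one patch per orthogonal view; scores are averaged,
  class probabilities are averaged then arg-maxed.
* ALL-Mean -- the average over all patches irrespective of view.
* ALL-Median -- the per-view median score (even counts use the mean of the
  middle two), then the average of the three view medians.
* Classification under ALL always averages the softmax vectors of all
  patches; ties go to the lower class index.

Agreement with annotators is measured with Cohen's kappa (classification),
RMSE and signed differences (regression; signed difference = CAD score
minus radiologist score, so negative medians mean the CAD under-scores),
and a two-sample pooled-variance t-test on the score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .common import CLASS_NAMES, VIEWS

__all__ = [
    "map_score_to_class",
    "PatchResult",
    "NoduleResult",
    "aggregate_single",
    "aggregate_all",
    "cohen_kappa",
    "rmse",
    "signed_diffs",
    "ttest_two_sample",
]


def map_score_to_class(score: float) -> int:
    """Map a (possibly averaged) 1-5 score to a class index.

    Integer scores 1-2 are non-solid, 3 part-solid, 4-5 solid; averaged
    scores extend this with thresholds at 2.5 and 3.5, the boundary always
    going to the upper class.  Returns 0/1/2 indexing ``CLASS_NAMES``.
    """
    if not 1.0 <= score <= 5.0:
        raise ValueError(f"score {score} outside [1, 5]")
    if score < 2.5:
        return 0
    if score < 3.5:
        return 1
    return 2


@dataclass
class PatchResult:
    """Per-patch model output with provenance."""

    view: str
    slice_index: int = 0
    score: float | None = None
    proba: np.ndarray | None = None


@dataclass
class NoduleResult:
    """Consensus prediction for one nodule."""

    nodule_id: str
    strategy: str
    method: str
    predicted_class: int | None = None
    predicted_score: float | None = None

    def __post_init__(self) -> None:
        if self.predicted_score is not None and not (
            1.0 <= self.predicted_score <= 5.0
        ):
            raise ValueError("predicted_score must lie in [1, 5]")


def _consensus_class(probas: list[np.ndarray]) -> int | None:
    if not probas or any(p is None for p in probas):
        return None
    mean = np.mean(np.asarray(probas, dtype=np.float64), axis=0)
    # argmax returns the lowest index on ties, which is the documented rule
    return int(mean.argmax())


def aggregate_single(
    patch_results: list[PatchResult],
    nodule_id: str = "",
    method: str = "CNN",
) -> NoduleResult:
    """Combine the three median-slice results (one per view)."""
    if len(patch_results) != 3 or {p.view for p in patch_results} != set(VIEWS):
        raise ValueError("SINGLE consensus needs exactly one patch per view")
    scores = [p.score for p in patch_results]
    score = float(np.mean(scores)) if all(s is not None for s in scores) else None
    cls = _consensus_class([p.proba for p in patch_results])
    return NoduleResult(nodule_id, "SINGLE", method, cls, score)


def aggregate_all(
    patch_results: list[PatchResult],
    mode: str = "mean",
    nodule_id: str = "",
    method: str = "CNN",
) -> NoduleResult:
    """Combine all per-slice results of a nodule under the ALL strategy.

    ``mode="mean"`` averages over every patch; ``mode="median"`` first
    takes the median score within each view, then averages the three view
    medians.  Classification always averages all softmax vectors.
    """
    by_view: dict[str, list[PatchResult]] = {v: [] for v in VIEWS}
    for p in patch_results:
        by_view[p.view].append(p)
    missing = [v for v, ps in by_view.items() if not ps]
    if missing:
        raise ValueError(f"ALL consensus is missing views: {missing}")

    scores_present = all(p.score is not None for p in patch_results)
    score = None
    if scores_present:
        if mode == "mean":
            score = float(np.mean([p.score for p in patch_results]))
        elif mode == "median":
            medians = [
                float(np.median([p.score for p in by_view[v]])) for v in VIEWS
            ]
            score = float(np.mean(medians))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    cls = _consensus_class([p.proba for p in patch_results])
    label = f"ALL-{mode.capitalize()}"
    return NoduleResult(nodule_id, label, method, cls, score)


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two categorical label vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with expected agreement from the
    marginal products.  When ``p_e = 1`` (both raters constant on the same
    label) agreement is perfect and 1.0 is returned.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    categories = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for c in categories:
        p_e += (np.sum(a == c) / n) * (np.sum(b == c) / n)
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def rmse(pred_scores, annot_scores) -> float:
    """Root mean squared error over paired scores."""
    pred = np.asarray(pred_scores, dtype=np.float64)
    annot = np.asarray(annot_scores, dtype=np.float64)
    if pred.shape != annot.shape or pred.size == 0:
        raise ValueError("need non-empty paired samples")
    return float(np.sqrt(np.mean((pred - annot) ** 2)))


def signed_diffs(pred_scores, annot_scores) -> np.ndarray:
    """Signed differences, CAD minus radiologist (negative = under-scoring)."""
    pred = np.asarray(pred_scores, dtype=np.float64)
    annot = np.asarray(annot_scores, dtype=np.float64)
    if pred.shape != annot.shape or pred.size == 0:
        raise ValueError("need non-empty paired samples")
    return pred - annot


def ttest_two_sample(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test on two score samples.

    Degenerate zero-variance samples with equal means return (0.0, 1.0) by
    convention.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = _stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
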