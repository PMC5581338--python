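import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from nodulecad.evaluation import (
    PatchResult,
    aggregate_all,
    aggregate_single,
    cohen_kappa,
    map_score_to_class,
    rmse,
    signed_diffs,
    ttest_two_sample,
)


@pytest.mark.parametrize(
    "score,expected",
    [
        (1.0, 0),
        (2.0, 0),
        (2.49, 0),
        (2.5, 1),  # boundary goes to the upper class
        (3.0, 1),
        (3.49, 1),
        (3.5, 2),
        (4.2, 2),
        (5.0, 2),
    ],
)
def test_map_score_to_class(score, expected):
    assert map_score_to_class(score) == expected


@pytest.mark.parametrize("score", [0.5, 5.5, -1.0])
def test_map_score_out_of_range(score):
    with pytest.raises(ValueError):
        map_score_to_class(score)


def _patches(view_scores, view_probas=None):
    out = []
    for i, (view, scores) in enumerate(view_scores.items()):
        for j, s in enumerate(scores):
            proba = None
            if view_probas is not None:
                proba = view_probas[view][j]
            out.append(PatchResult(view=view, slice_index=j, score=s, proba=proba))
    return out


def test_single_consensus_mean_of_three_views():
    patches = _patches({"axial": [2.0], "coronal": [3.0], "sagittal": [4.0]})
    res = aggregate_single(patches)
    assert res.predicted_score == pytest.approx(3.0)


def test_single_consensus_probability_averaging():
    probas = {
        "axial": [np.array([0.6, 0.3, 0.1])],
        "coronal": [np.array([0.2, 0.5, 0.3])],
        "sagittal": [np.array([0.2, 0.5, 0.3])],
    }
    patches = _patches(
        {"axial": [3.0], "coronal": [3.0], "sagittal": [3.0]}, probas
    )
    res = aggregate_single(patches)
    assert res.predicted_class == 1  # mean (.333, .433, .233) -> part-solid


def test_single_consensus_requires_three_views():
    with pytest.raises(ValueError):
        aggregate_single(_patches({"axial": [2.0, 3.0], "coronal": [3.0]}))


def test_all_consensus_hand_example():
    """Per-view scores [2,3,4], [3], [3,5]: medians 3, 3, 4 -> 10/3; the
    plain mean over six patches is also 10/3."""
    patches = _patches({"axial": [2.0, 3.0, 4.0], "coronal": [3.0], "sagittal": [3.0, 5.0]})
    median = aggregate_all(patches, "median")
    mean = aggregate_all(patches, "mean")
    assert median.predicted_score == pytest.approx(10.0 / 3.0)
    assert mean.predicted_score == pytest.approx(10.0 / 3.0)
    assert median.strategy == "ALL-Median" and mean.strategy == "ALL-Mean"


def test_consensus_modes_coincide_on_constant_scores():
    const = {"axial": [2.5, 2.5], "coronal": [2.5], "sagittal": [2.5, 2.5, 2.5]}
    res_mean = aggregate_all(_patches(const), "mean")
    res_median = aggregate_all(_patches(const), "median")
    single = aggregate_single(
        _patches({"axial": [2.5], "coronal": [2.5], "sagittal": [2.5]})
    )
    assert (
        res_mean.predicted_score
        == res_median.predicted_score
        == single.predicted_score
        == 2.5
    )


def test_all_consensus_missing_view_errors():
    with pytest.raises(ValueError, match="missing views"):
        aggregate_all(_patches({"axial": [2.0], "coronal": [3.0]}), "mean")


def test_kappa_identical_vectors():
    assert cohen_kappa([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)


def test_kappa_disjoint_marginals():
    assert cohen_kappa([0, 0, 0], [1, 1, 1]) == pytest.approx(0.0)


def test_kappa_hand_computed_example():
    # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
    assert cohen_kappa([1, 1, 2, 2], [1, 2, 2, 2]) == pytest.approx(0.5)


def test_kappa_constant_identical_vectors():
    assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0


def test_kappa_matches_sklearn_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(2, 50)
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        if len(np.unique(np.concatenate([a, b]))) < 2:
            continue
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=50
    )
)
def test_kappa_symmetric_and_bounded(pairs):
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    k_ab = cohen_kappa(a, b)
    assert cohen_kappa(b, a) == pytest.approx(k_ab)
    assert -1.0 - 1e-12 <= k_ab <= 1.0 + 1e-12


def test_kappa_length_mismatch():
    with pytest.raises(ValueError):
        cohen_kappa([1, 2], [1, 2, 3])


def test_rmse_and_signed_diffs():
    assert rmse([3.0, 3.0], [2.0, 4.0]) == pytest.approx(1.0)
    assert rmse([2.0, 4.0], [2.0, 4.0]) == 0.0
    assert np.allclose(signed_diffs([2.5], [3.0]), [-0.5])  # CAD minus radiologist
    with pytest.raises(ValueError):
        rmse([], [])


def test_ttest_identical_samples():
    t, p = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_ttest_degenerate_equal_constant_samples():
    assert ttest_two_sample([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


def test_ttest_separated_samples_significant():
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 1e-4, 10)
    b = 1.0 + rng.normal(0.0, 1e-4, 10)
    _, p = ttest_two_sample(a, b)
    assert p < 1e-10


def test_ttest_needs_two_per_sample():
    with pytest.raises(ValueError):
        ttest_two_sample([1.0], [1.0, 2.0])
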