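import numpy as np
import pytest

from nodulecad.protocol import (
    EvaluationReport,
    prepare_nodules,
    protocol_splits,
    run_protocol,
)


def _full_scale_ids():
    return {c: [f"c{c}-{i:03d}" for i in range(190)] for c in range(3)}


def test_full_scale_split_bookkeeping():
    """At 190 nodules per class with 10x10 CV: pool 170/class, test
    20/class, folds train on 153/class and validate on 17/class."""
    plan = protocol_splits(_full_scale_ids(), rounds=10, folds=10, seed=0)
    assert len(plan) == 10
    for round_plan in plan:
        test = round_plan["test"]
        assert len(test) == 60  # 20 per class
        for c in range(3):
            assert sum(1 for n in test if n.startswith(f"c{c}-")) == 20
        assert len(round_plan["folds"]) == 10
        for train, val in round_plan["folds"]:
            for c in range(3):
                assert sum(1 for n in train if n.startswith(f"c{c}-")) == 153
                assert sum(1 for n in val if n.startswith(f"c{c}-")) == 17
            assert not set(train) & set(val)


def test_no_leakage_across_all_repetitions():
    plan = protocol_splits(_full_scale_ids(), rounds=10, folds=10, seed=3)
    for round_plan in plan:
        test = set(round_plan["test"])
        for train, val in round_plan["folds"]:
            assert not set(train) & test
            assert not set(val) & test
            assert set(train) | set(val) | test == set(
                n for ids in _full_scale_ids().values() for n in ids
            )


def test_split_plan_deterministic():
    a = protocol_splits(_full_scale_ids(), 3, 5, seed=9)
    b = protocol_splits(_full_scale_ids(), 3, 5, seed=9)
    assert [sorted(r["test"]) for r in a] == [sorted(r["test"]) for r in b]
    c = protocol_splits(_full_scale_ids(), 3, 5, seed=10)
    assert [sorted(r["test"]) for r in a] != [sorted(r["test"]) for r in c]


def test_too_few_nodules_errors():
    with pytest.raises(ValueError):
        protocol_splits({0: ["a", "b"]}, 1, 3, seed=0)
    with pytest.raises(ValueError):
        protocol_splits({0: list("abcdef")}, 1, 1, seed=0)


def test_hist_protocol_report_shapes(small_phantom):
    _, volume, annotations = small_phantom
    report = run_protocol(
        volume, annotations, method="hist", strategy="all",
        rounds=2, folds=2, seed=1,
    )
    assert isinstance(report, EvaluationReport)
    assert report.confusion_matrices.shape == (4, 3, 3)  # 2 rounds x 2 folds
    # each confusion row sums to that class's test count
    for cm in report.confusion_matrices:
        assert cm.sum() == len(report.nodule_table) / 4
    assert 0.0 <= report.summary["accuracy_mean"] <= 1.0
    assert set(report.summary["per_class"]) == {"non-solid", "part-solid", "solid"}
    assert "rmse" in report.summary and "mean" in report.summary["rmse"]
    # regression scores stay on the 1-5 scale
    assert report.nodule_table["pred_score"].between(1, 5).all()


def test_hist_protocol_deterministic(small_phantom):
    _, volume, annotations = small_phantom
    kw = dict(method="hist", strategy="single", rounds=1, folds=2, seed=4)
    a = run_protocol(volume, annotations, **kw)
    b = run_protocol(volume, annotations, **kw)
    assert np.array_equal(a.confusion_matrices, b.confusion_matrices)
    assert a.summary["accuracy_mean"] == b.summary["accuracy_mean"]


def test_precision_recall_consistent_with_confusion(small_phantom):
    _, volume, annotations = small_phantom
    report = run_protocol(
        volume, annotations, method="hist", strategy="all",
        rounds=1, folds=2, seed=2,
    )
    cms = report.confusion_matrices
    with np.errstate(invalid="ignore", divide="ignore"):
        recalls = np.stack([np.diag(c) / c.sum(axis=1) for c in cms])
    for i, name in enumerate(("non-solid", "part-solid", "solid")):
        expect = float(np.nanmean(recalls[:, i]))
        assert report.summary["per_class"][name]["recall_mean"] == pytest.approx(expect)


def test_report_files_written(tmp_path, small_phantom):
    _, volume, annotations = small_phantom
    report = run_protocol(
        volume, annotations, method="hist", strategy="all",
        rounds=1, folds=2, seed=2,
    )
    report.write(tmp_path)
    assert (tmp_path / "summary_hist_all.json").exists()
    assert (tmp_path / "confusion_hist_all.csv").exists()
    assert (tmp_path / "nodule_results_hist_all.csv").exists()
    assert (tmp_path / "signed_diffs_hist_all.csv").exists()


def test_cnn_protocol_smoke(small_phantom):
    """A minimal CNN protocol run: shapes, leak-free bookkeeping, scores
    in range.  Accuracy at this tiny scale is not asserted."""
    _, volume, annotations = small_phantom
    report = run_protocol(
        volume, annotations, method="cnn", strategy="single",
        rounds=1, folds=2, seed=1,
        cnn_params={"epochs": 3, "patience": 0},
        contourlet_enabled=False,
    )
    assert report.confusion_matrices.shape == (2, 3, 3)
    assert report.nodule_table["pred_score"].between(1, 5).all()
    assert report.nodule_table["pred_class"].isin([0, 1, 2]).all()
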