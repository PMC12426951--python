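"""Cross-validation folds, metrics, the Welch test and the ablation table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dredct import (
    CLASS_NAMES,
    DatasetManifest,
    TrainConfig,
    ablate_block_size,
    compare_runs,
    compute_metrics,
    generate_arrays,
    make_folds,
    run_cross_validation,
)


def _labels(n_per_class=10):
    return np.repeat(list(CLASS_NAMES), n_per_class)


# -- folds --------------------------------------------------------------------

def test_folds_partition_and_stratify():
    y = _labels(10)
    folds = make_folds(y, k=5, seed=0)
    assert len(folds) == 5
    all_test = [i for f in folds for i in f.test_idx]
    assert sorted(all_test) == list(range(30))  # disjoint union = full set
    for f in folds:
        assert len(f.test_idx) == 6
        test_labels = y[list(f.test_idx)]
        assert all((test_labels == c).sum() == 2 for c in CLASS_NAMES)
        # train/val/test of one fold are pairwise disjoint
        assert not (set(f.train_idx) | set(f.val_idx)) & set(f.test_idx)
        assert not set(f.train_idx) & set(f.val_idx)


def test_validation_fraction_of_training_portion():
    folds = make_folds(_labels(20), k=5, val_fraction=0.1, seed=1)
    for f in folds:
        n_train_portion = len(f.train_idx) + len(f.val_idx)
        assert len(f.val_idx) == pytest.approx(0.1 * n_train_portion, abs=1)


def test_folds_deterministic_under_seed():
    y = _labels(10)
    assert make_folds(y, seed=4) == make_folds(y, seed=4)
    assert make_folds(y, seed=4) != make_folds(y, seed=5)


def test_folds_reject_small_class():
    y = np.array(["healthy"] * 10 + ["bean_rust"] * 3 + ["angular_leaf_spot"] * 10)
    with pytest.raises(ValueError, match="bean_rust"):
        make_folds(y, k=5)


def test_folds_accept_manifest():
    m = DatasetManifest(
        paths=tuple(f"p{i}.png" for i in range(15)),
        labels=tuple(np.repeat(list(CLASS_NAMES), 5)),
    )
    folds = make_folds(m, k=5)
    train_m, val_m, test_m = folds[0].manifests(m)
    assert len(train_m) + len(val_m) + len(test_m) == 15


# -- metrics ------------------------------------------------------------------

def test_perfect_predictions():
    y = _labels(4)
    r = compute_metrics(y, y)
    assert r.accuracy == 1.0 and r.f1 == 1.0
    assert np.array_equal(r.confusion, np.diag([4, 4, 4]))


def test_constant_classifier_on_balanced_labels():
    y = _labels(5)
    pred = np.array(["healthy"] * 15)
    r = compute_metrics(y, pred)
    assert r.accuracy == pytest.approx(1 / 3)
    assert r.recall == pytest.approx(1 / 3)


def test_toy_confusion_matrix_accuracy():
    # rows: true healthy [4,1,0], angular [0,5,0], rust [0,0,5]
    y_true = ["healthy"] * 5 + ["angular_leaf_spot"] * 5 + ["bean_rust"] * 5
    y_pred = (
        ["healthy"] * 4 + ["angular_leaf_spot"]
        + ["angular_leaf_spot"] * 5
        + ["bean_rust"] * 5
    )
    r = compute_metrics(y_true, y_pred)
    assert np.array_equal(r.confusion, [[4, 1, 0], [0, 5, 0], [0, 0, 5]])
    assert r.accuracy == pytest.approx(14 / 15)
    assert r.confusion.sum() == r.n


def test_metrics_match_bruteforce_on_random_labels(rng):
    for _ in range(5):
        y_true = rng.choice(CLASS_NAMES, size=100)
        y_pred = rng.choice(CLASS_NAMES, size=100)
        r = compute_metrics(y_true, y_pred)
        # independent per-class evaluation
        precs, recs, f1s = [], [], []
        for c in CLASS_NAMES:
            tp = np.sum((y_true == c) & (y_pred == c))
            fp = np.sum((y_true != c) & (y_pred == c))
            fn = np.sum((y_true == c) & (y_pred != c))
            p = tp / (tp + fp) if tp + fp else 0.0
            q = tp / (tp + fn) if tp + fn else 0.0
            precs.append(p)
            recs.append(q)
            f1s.append(2 * p * q / (p + q) if p + q else 0.0)
        assert r.accuracy == pytest.approx(np.mean(y_true == y_pred))
        assert r.precision == pytest.approx(np.mean(precs))
        assert r.recall == pytest.approx(np.mean(recs))
        assert r.f1 == pytest.approx(np.mean(f1s))
        # conservation: row sums equal per-class truth counts
        for i, c in enumerate(CLASS_NAMES):
            assert r.confusion[i].sum() == np.sum(y_true == c)


def test_metrics_reject_unknown_label():
    with pytest.raises(ValueError):
        compute_metrics(["healthy"], ["weeds"])
    with pytest.raises(ValueError):
        compute_metrics(["healthy", "healthy"], ["healthy"])


# -- Welch t-test ---------------------------------------------------------------

def welch_reference(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def test_compare_runs_matches_reference_evaluation():
    a = [0.9, 0.91, 0.92]
    b = [0.5, 0.51, 0.52]
    res = compare_runs(a, b)
    t, df, p = welch_reference(a, b)
    assert res.statistic == pytest.approx(t, abs=1e-8)
    assert res.dof == pytest.approx(df, abs=1e-8)
    assert res.pvalue == pytest.approx(p, abs=1e-8)
    assert res.pvalue < 0.001


def test_compare_runs_null_and_symmetry():
    a = [0.9, 0.91, 0.92]
    res = compare_runs(a, a)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0, abs=1e-12)
    fwd = compare_runs(a, [0.5, 0.51, 0.52])
    rev = compare_runs([0.5, 0.51, 0.52], a)
    assert fwd.statistic == pytest.approx(-rev.statistic, abs=1e-12)
    assert fwd.pvalue == pytest.approx(rev.pvalue, abs=1e-12)


def test_compare_runs_degenerate_groups_flagged():
    res = compare_runs([0.5, 0.5, 0.5], [0.7, 0.7])
    assert res.degenerate and np.isnan(res.pvalue)
    with pytest.raises(ValueError):
        compare_runs([0.5], [0.6, 0.7])


# -- harness smoke on tiny data -------------------------------------------------

@pytest.fixture(scope="module")
def micro_data():
    return generate_arrays(6, side=64, seed=9)


def _micro_cfg(seed=0):
    return TrainConfig.for_tiny(seed=seed, epochs=2, image_side=64)


def test_cross_validation_reports_satisfy_invariants(micro_data):
    X, y = micro_data
    res = run_cross_validation((X, y), k=3, seed=0, train_config=_micro_cfg())
    assert len(res.reports) == 3
    for rep in res.reports:
        assert rep.confusion.sum() == rep.n
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / rep.n)
        assert 0.0 <= rep.accuracy <= 1.0
    frame = res.summary_frame()
    assert list(frame["fold"]) == [1, 2, 3]


def test_ablation_table_contract_and_caching(micro_data):
    X, y = micro_data
    table = ablate_block_size(
        (X, y), [8, 8, 16], train_config=_micro_cfg(), seed=0, k=3
    )
    assert list(table.columns) == ["block_size", "accuracy"]
    assert list(table["block_size"]) == [8, 16]  # duplicates collapse
    assert table["accuracy"].between(0, 1).all()
    table2 = ablate_block_size(
        (X, y), [8, 16], train_config=_micro_cfg(), seed=0, k=3
    )
    pd.testing.assert_frame_equal(table.reset_index(drop=True), table2)
    with pytest.raises(ValueError):
        ablate_block_size((X, y), [], train_config=_micro_cfg())
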