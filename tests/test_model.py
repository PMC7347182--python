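"""Ordinal kNN model: c-index, kNN prediction, nested LOSO CV machinery,
final-model selection and permutation significance."""

import numpy as np
import pandas as pd
import pytest

import painemg
from painemg.model import (c_index, final_loso_evaluation, knn_predict,
                           loso_folds, nested_loso_cv, permutation_pvalue,
                           permutation_test, select_final_model)

from conftest import make_labelled


# ---------------------------------------------------------------------------
# c-index

def test_cindex_perfect_predictions():
    rng = np.random.default_rng(0)
    y = rng.integers(1, 5, size=200)
    assert c_index(y, y) == 1.0


def test_cindex_hand_example_with_tie():
    assert c_index([1, 1, 2, 3], [1, 2, 2, 3]) == pytest.approx(0.9)


def test_cindex_random_predictions_near_half():
    rng = np.random.default_rng(1)
    y = rng.integers(1, 5, size=10_000)
    p = rng.integers(1, 5, size=10_000)
    assert abs(c_index(y, p) - 0.5) < 0.02


def test_cindex_equals_auc_on_binary_labels():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(2)
    for _ in range(10):
        y = rng.integers(0, 2, size=60)
        scores = rng.normal(size=60)
        assert c_index(y, scores) == pytest.approx(roc_auc_score(y, scores))


def test_cindex_matches_lifelines_concordance():
    from lifelines.utils import concordance_index
    rng = np.random.default_rng(3)
    y = rng.integers(1, 5, size=150).astype(float)
    p = rng.integers(1, 5, size=150).astype(float)
    assert c_index(y, p) == pytest.approx(concordance_index(y, p))


def test_cindex_invariant_to_monotone_relabelling():
    rng = np.random.default_rng(4)
    y = rng.integers(1, 5, size=80)
    p = rng.integers(1, 5, size=80)
    assert c_index(y, p) == pytest.approx(c_index(y, 10 * p + 3))


def test_cindex_undefined_without_comparable_pairs():
    assert np.isnan(c_index([2, 2, 2], [1, 2, 3]))


# ---------------------------------------------------------------------------
# kNN

def test_knn_exact_match_k1():
    train = np.array([[0.0], [1.0], [2.0]])
    labels = np.array(["P1", "P2", "P3"])
    assert knn_predict(train, labels, [[1.0]], k=1)[0] == "P2"


def test_knn_majority_vote():
    train = np.array([[0.0], [0.1], [5.0], [9.0]])
    labels = np.array(["P2", "P2", "P4", "P4"])
    assert knn_predict(train, labels, [[0.05]], k=3)[0] == "P2"


def test_knn_vote_tie_goes_to_lower_label():
    train = np.array([[0.0], [1.0]])
    labels = np.array(["P3", "P1"])
    assert knn_predict(train, labels, [[0.5]], k=2)[0] == "P1"


def test_knn_errors():
    with pytest.raises(ValueError):
        knn_predict(np.empty((0, 2)), np.array([]), [[0, 0]], k=1)
    with pytest.raises(ValueError):
        knn_predict([[0.0]], ["P1"], [[0.0]], k=2)


def _knn_oracle(train, labels, test, k):
    """Exhaustive-distance reference with the same deterministic tie rules."""
    levels = sorted(set(labels))
    preds = []
    for x in test:
        d = [(float(np.sum((x - r) ** 2)), i) for i, r in enumerate(train)]
        nearest = sorted(d)[:k]
        votes = {}
        for _, i in nearest:
            votes[labels[i]] = votes.get(labels[i], 0) + 1
        best = max(levels, key=lambda l: (votes.get(l, 0), -levels.index(l)))
        preds.append(best)
    return np.array(preds)


def test_knn_matches_bruteforce_oracle_all_k():
    rng = np.random.default_rng(5)
    train = rng.normal(size=(200, 3))
    labels = np.array([f"P{i}" for i in rng.integers(1, 5, size=200)])
    test = rng.normal(size=(40, 3))
    for k in range(1, 32, 2):
        got = knn_predict(train, labels, test, k=k)
        np.testing.assert_array_equal(got, _knn_oracle(train, labels, test, k))


# ---------------------------------------------------------------------------
# LOSO folds

def test_loso_fold_structure():
    ids = [f"S{i:02d}" for i in range(31)] * 3
    folds = loso_folds(ids)
    assert len(folds) == 31
    held = [h for _, h in folds]
    assert sorted(held) == sorted(set(ids))
    for train, h in folds:
        assert h not in train
        assert len(train) == 30


def test_loso_single_subject_errors():
    with pytest.raises(ValueError):
        loso_folds(["S01", "S01"])


# ---------------------------------------------------------------------------
# nested CV

def test_candidate_subset_count():
    from painemg._engine import enumerate_subsets
    assert len(enumerate_subsets(4)) == 15
    sizes = [len(s) for s in enumerate_subsets(4)]
    assert sizes == sorted(sizes)


def _slow_nested_cv(df, features, k_grid):
    """Independent pure-Python nested LOSO CV with the spec tie rules."""
    from painemg._engine import enumerate_subsets
    df = df.sort_values(["subject_id", "test_id", "time_s"], kind="mergesort")
    subjects = sorted(df["subject_id"].unique())
    subsets = enumerate_subsets(len(features))
    period_code = {p: i for i, p in enumerate(painemg.MODEL_PERIODS, start=1)}
    y_all = df["period"].map(period_code).to_numpy()
    results = []
    for o in subjects:
        best = (-1.0, None, None)
        for cols in subsets:
            feats = [features[c] for c in cols]
            for k in k_grid:
                scores = []
                for j in subjects:
                    if j == o:
                        continue
                    train = df[~df["subject_id"].isin([o, j])]
                    test = df[df["subject_id"] == j]
                    preds = knn_predict(train[feats].to_numpy(),
                                        train["period"].map(period_code).to_numpy(),
                                        test[feats].to_numpy(), k=k)
                    c = c_index(test["period"].map(period_code).to_numpy(), preds)
                    if not np.isnan(c):
                        scores.append(c)
                mean = np.mean(scores)
                if mean > best[0]:
                    best = (mean, cols, k)
        _, cols, k = best
        feats = [features[c] for c in cols]
        train = df[df["subject_id"] != o]
        test = df[df["subject_id"] == o]
        preds = knn_predict(train[feats].to_numpy(),
                            train["period"].map(period_code).to_numpy(),
                            test[feats].to_numpy(), k=k)
        fold_c = c_index(test["period"].map(period_code).to_numpy(), preds)
        results.append((o, tuple(feats), k, fold_c))
    return results


def test_nested_cv_matches_pure_python_oracle():
    """The kd-tree/numba engine must reproduce a naive nested LOSO CV exactly."""
    rng = np.random.default_rng(6)
    df = make_labelled(4, 3, rng, signal=0.35, tests_per_subject=2)
    features = ("corwl", "levwl")
    config = painemg.ModelConfig(candidate_features=features, k_grid=(1, 3, 5))
    got = nested_loso_cv(df, config)
    expected = _slow_nested_cv(df, list(features), (1, 3, 5))
    for row, (sid, feats, k, fold_c) in zip(got.folds.itertuples(), expected):
        assert row.subject_id == sid
        assert tuple(row.features) == feats
        assert row.k == k
        assert row.c_index == pytest.approx(fold_c)


def test_nested_cv_separable_cohort_scores_high():
    rng = np.random.default_rng(7)
    df = make_labelled(6, 6, rng, signal=3.0)
    cv = nested_loso_cv(df, painemg.ModelConfig(candidate_features=("corwl", "levwl"),
                                                k_grid=(1, 3, 5, 7)))
    assert cv.aggregate > 0.9
    assert len(cv.folds) == 6


def test_nested_cv_uninformative_features_near_chance():
    aggs = []
    for seed in (8, 9, 10):
        rng = np.random.default_rng(seed)
        df = make_labelled(8, 10, rng, signal=0.0)
        cv = nested_loso_cv(df, painemg.ModelConfig(candidate_features=("corwl", "levwl"),
                                                    k_grid=(3, 7, 11)))
        aggs.append(cv.aggregate)
    assert abs(np.mean(aggs) - 0.5) < 0.05


def test_training_blind_to_held_out_labels():
    """Corrupting a held-out subject's labels must not change what the inner
    loop selects for that subject's fold."""
    rng = np.random.default_rng(11)
    df = make_labelled(5, 4, rng, signal=0.8)
    config = painemg.ModelConfig(candidate_features=("corwl", "levwl"), k_grid=(1, 3, 5))
    before = nested_loso_cv(df, config).folds.set_index("subject_id")
    corrupted = df.copy()
    mask = corrupted["subject_id"] == "S03"
    corrupted.loc[mask, "period"] = rng.permutation(corrupted.loc[mask, "period"].to_numpy())
    after = nested_loso_cv(corrupted, config).folds.set_index("subject_id")
    assert tuple(before.loc["S03", "features"]) == tuple(after.loc["S03", "features"])
    assert before.loc["S03", "k"] == after.loc["S03", "k"]


# ---------------------------------------------------------------------------
# final model selection and evaluation

def _cv_from(rows):
    from painemg.model import CVResult
    frame = pd.DataFrame(rows, columns=["subject_id", "features", "k", "c_index"])
    frame["inner_c_index"] = 0.6
    return CVResult(folds=frame, aggregate=float(frame["c_index"].mean()))


def test_select_modal_subset_and_k():
    rows = ([("S%d" % i, ("corwl", "levwl"), 5, 0.6) for i in range(20)]
            + [("T%d" % i, ("corrms",), 3, 0.6) for i in range(11)])
    assert select_final_model(_cv_from(rows)) == (("corwl", "levwl"), 5)


def test_select_unanimous():
    rows = [("S%d" % i, ("corwl",), 7, 0.7) for i in range(5)]
    assert select_final_model(_cv_from(rows)) == (("corwl",), 7)


def test_select_frequency_tie_prefers_smaller_subset():
    rows = ([("S1", ("corwl",), 9, 0.6), ("S2", ("corwl",), 9, 0.6),
             ("S3", ("corwl", "levwl"), 3, 0.6), ("S4", ("corwl", "levwl"), 3, 0.6)])
    subset, k = select_final_model(_cv_from(rows))
    assert subset == ("corwl",)
    assert k == 9


def test_final_loso_reports_one_score_per_subject():
    rng = np.random.default_rng(12)
    df = make_labelled(5, 5, rng, signal=1.0)
    per_subject, mean = final_loso_evaluation(df, ("corwl",), 3)
    assert len(per_subject) == 5
    assert mean == pytest.approx(per_subject["c_index"].mean())
    assert per_subject["c_index"].min() <= mean <= per_subject["c_index"].max()


# ---------------------------------------------------------------------------
# permutation test

def test_permutation_pvalue_boundaries():
    assert permutation_pvalue(0.9, np.full(19, 0.5)) == pytest.approx(1 / 20)
    assert permutation_pvalue(0.4, np.full(19, 0.5)) == 1.0


def test_permutation_detects_separable_signal():
    rng = np.random.default_rng(13)
    df = make_labelled(5, 5, rng, signal=2.5)
    config = painemg.ModelConfig(candidate_features=("corwl", "levwl"),
                                 k_grid=(1, 3, 5), n_permutations=19, seed=0)
    res = permutation_test(df, config)
    assert res.p_value == pytest.approx(1 / 20)
    assert res.observed > np.max(res.null_distribution)


def test_permutation_preserves_within_test_label_counts():
    from painemg._engine import NeighborEngine, build_dataset
    rng = np.random.default_rng(14)
    df = make_labelled(3, 4, rng, signal=0.5)
    eng = NeighborEngine(build_dataset(df, ("corwl", "levwl")), (1, 3))
    y_perm = eng.permute_labels(np.random.default_rng(0))
    for t in np.unique(eng.ds.test):
        idx = eng.ds.test == t
        assert sorted(eng.ds.y[idx]) == sorted(y_perm[idx])
    assert not np.array_equal(y_perm, eng.ds.y)
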