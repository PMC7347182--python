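"""Ordinal pain-intensity prediction: kNN, c-index, nested LOSO CV,
permutation significance and final per-subject evaluation.

The model maps the selected standardized 1-Hz sEMG features to the ordinal
pain periods P1 < P2 < P3 < P4.  Performance is measured with the
concordance index (c-index): over all row pairs whose true labels differ,
the fraction ordered correctly by the predictions, with predicted ties
credited 0.5 — a generalization of the area under the ROC curve, equal to
0.5 for label-independent predictions.

Subject structure drives the evaluation design: folds are
leave-subject-out, feature-subset and k selection happen in an inner LOSO
loop (nested CV), and significance is assessed by re-running the nested CV
on labels permuted within each test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._engine import NeighborEngine, build_dataset
from .config import ModelConfig

__all__ = [
    "c_index", "knn_predict", "loso_folds", "CVResult", "nested_loso_cv",
    "select_final_model", "final_loso_evaluation", "PermutationResult",
    "permutation_pvalue", "permutation_test",
]


def c_index(true_labels, predicted_labels) -> float:
    """Concordance between ordinal truths and predictions.

    credit(i, j) for pairs with true_i < true_j: 1 if pred_i < pred_j,
    0.5 if equal, 0 otherwise; returns total credit / comparable pairs.
    NaN when no pair of rows has differing true labels.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    levels = np.unique(np.concatenate([t, p]))
    ti = np.searchsorted(levels, t)
    pi = np.searchsorted(levels, p)
    L = len(levels)
    C = np.zeros((L, L))
    np.add.at(C, (ti, pi), 1.0)
    # S[b] = counts of rows with true label below level b, per predicted level
    S = np.cumsum(C, axis=0) - C
    U = np.triu(np.ones((L, L)), 1) + 0.5 * np.eye(L)  # credit(pred_low, pred_high)
    num = float(np.einsum("bi,ij,bj->", S, U, C))
    den = float((S.sum(axis=1) * C.sum(axis=1)).sum())
    if den == 0.0:
        return float("nan")
    return num / den


def knn_predict(train_rows, train_labels, test_rows, k: int,
                distance: str = "euclidean") -> np.ndarray:
    """Majority-vote kNN with deterministic tie handling.

    Neighbors are the k training rows closest to the query (ties in distance
    broken by the smaller training index); vote ties go to the lower ordinal
    label.
    """
    if distance != "euclidean":
        raise ValueError("only the Euclidean distance is supported")
    Xtr = np.atleast_2d(np.asarray(train_rows, dtype=np.float64))
    Xte = np.atleast_2d(np.asarray(test_rows, dtype=np.float64))
    labels = np.asarray(train_labels)
    if Xtr.shape[0] == 0:
        raise ValueError("empty training set")
    if k > Xtr.shape[0]:
        raise ValueError(f"k={k} exceeds the {Xtr.shape[0]} training rows")
    levels, codes = np.unique(labels, return_inverse=True)
    d = np.sqrt(((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2))
    preds = np.empty(Xte.shape[0], dtype=np.int64)
    for i in range(Xte.shape[0]):
        order = np.lexsort((np.arange(Xtr.shape[0]), d[i]))[:k]
        counts = np.bincount(codes[order], minlength=len(levels))
        preds[i] = int(np.argmax(counts))  # argmax takes the lowest index on ties
    return levels[preds]


def loso_folds(subject_ids: Sequence) -> List[Tuple[List, object]]:
    """Leave-subject-out folds in sorted subject order."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise ValueError("leave-subject-out needs at least two subjects")
    return [([s for s in subjects if s != held], held) for held in subjects]


@dataclass
class CVResult:
    """Outcome of the nested LOSO meta-learning run."""

    folds: pd.DataFrame      # subject_id, features, k, c_index, inner_c_index
    aggregate: float         # mean of per-subject fold c-indices

    def __repr__(self) -> str:  # pragma: no cover
        return f"CVResult(aggregate={self.aggregate:.3f}, n_folds={len(self.folds)})"


def _get_engine(labelled: pd.DataFrame, config: ModelConfig,
                engine: NeighborEngine | None) -> NeighborEngine:
    if engine is not None:
        return engine
    ds = build_dataset(labelled, config.candidate_features)
    return NeighborEngine(ds, config.k_grid)


def nested_loso_cv(labelled: pd.DataFrame, config: ModelConfig = ModelConfig(),
                   engine: NeighborEngine | None = None) -> CVResult:
    """Nested leave-subject-out cross-validation.

    For every outer fold, an inner LOSO loop over the remaining subjects
    scores every non-empty subset of the candidate features crossed with
    every k; the argmax (ties: smaller subset, then smaller k) is evaluated
    on the held-out subject.  The aggregate is the mean of the per-subject
    fold c-indices.
    """
    config.validate()
    eng = _get_engine(labelled, config, engine)
    best_s, best_k, fold_c, best_val = eng.nested_cv()
    names = eng.ds.feature_names
    rows = []
    for o, sid in enumerate(eng.ds.subject_ids):
        subset = tuple(names[i] for i in eng.subsets[best_s[o]])
        rows.append(dict(subject_id=sid, features=subset, k=int(eng.k_grid[best_k[o]]),
                         c_index=float(fold_c[o]), inner_c_index=float(best_val[o])))
    frame = pd.DataFrame(rows)
    return CVResult(folds=frame, aggregate=float(np.nanmean(fold_c)))


def select_final_model(cv_result: CVResult) -> Tuple[Tuple[str, ...], int]:
    """Modal feature subset across outer folds, then modal k among the folds
    that chose it.  Ties: smaller subset, then lexicographic, then smaller k."""
    if cv_result.folds.empty:
        raise ValueError("empty CV result")
    subsets = [tuple(f) for f in cv_result.folds["features"]]
    counts = Counter(subsets)
    best_subset = min(counts, key=lambda s: (-counts[s], len(s), s))
    ks = [int(k) for s, k in zip(subsets, cv_result.folds["k"]) if s == best_subset]
    k_counts = Counter(ks)
    best_k = min(k_counts, key=lambda k: (-k_counts[k], k))
    return best_subset, best_k


def final_loso_evaluation(labelled: pd.DataFrame, feature_subset: Sequence[str],
                          k: int, config: ModelConfig = ModelConfig(),
                          engine: NeighborEngine | None = None,
                          ) -> Tuple[pd.DataFrame, float]:
    """Plain (non-nested) LOSO with a fixed feature subset and k.

    Returns the per-subject c-index table ordered by score, plus the
    unweighted mean.
    """
    if engine is None:
        eng = NeighborEngine(build_dataset(labelled, tuple(feature_subset)),
                             config.k_grid)
    else:
        eng = engine
    names = eng.ds.feature_names
    cols = tuple(sorted(names.index(f) for f in feature_subset))
    per_subject = eng.plain_loso(cols, k)
    frame = pd.DataFrame({"subject_id": eng.ds.subject_ids, "c_index": per_subject})
    frame = frame.dropna().sort_values("c_index").reset_index(drop=True)
    return frame, float(np.nanmean(per_subject))


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float


def permutation_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (1 + B)."""
    null_values = np.asarray(null_values, dtype=np.float64)
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))


def permutation_test(labelled: pd.DataFrame, config: ModelConfig = ModelConfig(),
                     n_permutations: int | None = None,
                     rng: np.random.Generator | None = None,
                     engine: NeighborEngine | None = None) -> PermutationResult:
    """Permutation significance of the nested-CV classifier statistic.

    Each replicate shuffles the period labels within every test (features
    untouched, subject/test structure preserved) and recomputes the nested
    LOSO CV aggregate; the p-value uses the add-one estimator, so it is
    never exactly zero.
    """
    config.validate()
    B = config.n_permutations if n_permutations is None else int(n_permutations)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eng = _get_engine(labelled, config, engine)
    observed = float(np.nanmean(eng.nested_cv()[2]))
    null = np.empty(B)
    for b in range(B):
        y_perm = eng.permute_labels(rng)
        null[b] = float(np.nanmean(eng.nested_cv(y_perm)[2]))
    return PermutationResult(observed=observed, null_distribution=null,
                             p_value=permutation_pvalue(observed, null))
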