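"""Fast neighbor machinery behind the nested leave-subject-out CV.

The nested CV evaluates every non-empty candidate-feature subset and every k
on every inner fold, and the permutation test repeats the whole nested CV
hundreds of times with shuffled labels.  Both reuse the same label-independent
geometry: for each feature subset, each row's nearest neighbors in subset
space.  We therefore precompute, per subset, each row's top-L neighbor list
(kd-tree), and let a numba kernel walk those lists while skipping the
excluded subjects of the current fold.  When a list is exhausted before k
valid neighbors are found (heavy exclusions or tiny data), the kernel falls
back to an exact scan over all rows.

Correctness of this machinery is checked in the test-suite against a plain
pure-Python nested CV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial import cKDTree

from .labelling import MODEL_PERIODS

N_CLASSES = 4  # ordinal classes P1..P4


def enumerate_subsets(n_features: int) -> list[Tuple[int, ...]]:
    """All non-empty index subsets, ordered by (size, lexicographic)."""
    out = []
    for size in range(1, n_features + 1):
        out.extend(itertools.combinations(range(n_features), size))
    return out


@dataclass
class OrdinalDataset:
    """Model-ready view of the labelled feature table (P1-P4 rows only)."""

    X: np.ndarray              # (N, F) float64, candidate features
    y: np.ndarray              # (N,) int64 in 0..3
    subj: np.ndarray           # (N,) int64 codes, rows contiguous per subject
    test: np.ndarray           # (N,) int64 test codes
    subject_ids: list          # code -> subject_id
    feature_names: Tuple[str, ...]


def build_dataset(labelled: pd.DataFrame, features: Sequence[str]) -> OrdinalDataset:
    df = labelled[labelled["period"].isin(MODEL_PERIODS)].copy()
    if df.empty:
        raise ValueError("no P1-P4 rows to model")
    df = df.sort_values(["subject_id", "test_id", "time_s"], kind="mergesort")
    subject_ids = sorted(df["subject_id"].unique())
    subj_code = {s: i for i, s in enumerate(subject_ids)}
    test_ids = list(dict.fromkeys(df["test_id"]))
    test_code = {t: i for i, t in enumerate(test_ids)}
    period_code = {p: i for i, p in enumerate(MODEL_PERIODS)}
    return OrdinalDataset(
        X=df[list(features)].to_numpy(dtype=np.float64),
        y=df["period"].astype(str).map(period_code).to_numpy(dtype=np.int64),
        subj=df["subject_id"].map(subj_code).to_numpy(dtype=np.int64),
        test=df["test_id"].map(test_code).to_numpy(dtype=np.int64),
        subject_ids=subject_ids,
        feature_names=tuple(features),
    )


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _collect_from_order(order_row, subj, y, e1, e2, kmax, out_labels):
    found = 0
    for pos in range(order_row.shape[0]):
        j = order_row[pos]
        s = subj[j]
        if s == e1 or s == e2:
            continue
        out_labels[found] = y[j]
        found += 1
        if found == kmax:
            break
    return found


@njit(cache=True)
def _collect_exact(i, X, feat_idx, nf, subj, y, e1, e2, kmax, best_d, best_j, out_labels):
    """Exact top-kmax neighbors of row i by insertion, excluding subjects e1/e2."""
    n = X.shape[0]
    count = 0
    for j in range(n):
        if j == i:
            continue
        s = subj[j]
        if s == e1 or s == e2:
            continue
        d = 0.0
        for f in range(nf):
            diff = X[i, feat_idx[f]] - X[j, feat_idx[f]]
            d += diff * diff
        if count < kmax:
            pos = count
            while pos > 0 and best_d[pos - 1] > d:
                best_d[pos] = best_d[pos - 1]
                best_j[pos] = best_j[pos - 1]
                pos -= 1
            best_d[pos] = d
            best_j[pos] = j
            count += 1
        elif d < best_d[kmax - 1]:
            pos = kmax - 1
            while pos > 0 and best_d[pos - 1] > d:
                best_d[pos] = best_d[pos - 1]
                best_j[pos] = best_j[pos - 1]
                pos -= 1
            best_d[pos] = d
            best_j[pos] = j
    for p in range(count):
        out_labels[p] = y[best_j[p]]
    return count


@njit(cache=True)
def _vote_prefix(labels, n_av, k_grid, preds):
    """Majority vote over the first k neighbors for every k in the grid.

    Ties go to the lower ordinal label.  For k beyond the available
    neighbors, all available votes are used.
    """
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    ki = 0
    nk = k_grid.shape[0]
    for pos in range(n_av):
        counts[labels[pos]] += 1
        while ki < nk and k_grid[ki] == pos + 1:
            best = 0
            for c in range(1, N_CLASSES):
                if counts[c] > counts[best]:
                    best = c
            preds[ki] = best
            ki += 1
    while ki < nk:
        best = 0
        for c in range(1, N_CLASSES):
            if counts[c] > counts[best]:
                best = c
        preds[ki] = best
        ki += 1


@njit(cache=True)
def _cindex_contingency(C):
    """Concordance index from a (true, pred) contingency table.

    Pairs with differing true labels: full credit when predictions are
    ordered the same way, half credit on predicted ties.
    """
    num = 0.0
    den = 0.0
    for a in range(N_CLASSES):
        for b in range(a + 1, N_CLASSES):
            for pa in range(N_CLASSES):
                ca = C[a, pa]
                if ca == 0:
                    continue
                for pb in range(N_CLASSES):
                    cb = C[b, pb]
                    if cb == 0:
                        continue
                    pairs = ca * cb
                    den += pairs
                    if pa < pb:
                        num += pairs
                    elif pa == pb:
                        num += 0.5 * pairs
    if den == 0.0:
        return np.nan
    return num / den


@njit(cache=True)
def _predict_rows(orders_s, X, feat_idx, nf, subj, y, rows, e1, e2, k_grid, preds_out):
    """Predictions for ``rows`` (test rows) for every k, training on all rows
    whose subject is neither e1 nor e2."""
    kmax = k_grid[k_grid.shape[0] - 1]
    labels = np.empty(kmax, dtype=np.int64)
    best_d = np.empty(kmax, dtype=np.float64)
    best_j = np.empty(kmax, dtype=np.int64)
    for r in range(rows.shape[0]):
        i = rows[r]
        n_av = _collect_from_order(orders_s[i], subj, y, e1, e2, kmax, labels)
        if n_av < kmax:
            n_av = _collect_exact(i, X, feat_idx, nf, subj, y, e1, e2, kmax,
                                  best_d, best_j, labels)
        _vote_prefix(labels, n_av, k_grid, preds_out[r])


@njit(cache=True)
def _nested_cv_kernel(orders, X, subset_feats, subset_sizes, subj, y,
                      subj_start, n_subjects, k_grid):
    """Full nested leave-subject-out CV.

    Returns per outer fold: chosen subset index, chosen k-grid index, fold
    c-index, and best inner mean c-index.  Subset/k ties resolve to the
    first encountered in (size-then-lex subset, ascending k) order.
    """
    n_subsets = subset_feats.shape[0]
    nk = k_grid.shape[0]
    best_s = np.zeros(n_subjects, dtype=np.int64)
    best_k = np.zeros(n_subjects, dtype=np.int64)
    best_val = np.full(n_subjects, np.nan)
    fold_c = np.full(n_subjects, np.nan)

    max_rows = 0
    for u in range(n_subjects):
        r = subj_start[u + 1] - subj_start[u]
        if r > max_rows:
            max_rows = r
    preds = np.empty((max_rows, nk), dtype=np.int64)

    for o in range(n_subjects):
        sum_c = np.zeros((n_subsets, nk))
        cnt_c = np.zeros((n_subsets, nk), dtype=np.int64)
        for j in range(n_subjects):
            if j == o:
                continue
            rows = np.arange(subj_start[j], subj_start[j + 1])
            # inner held-out subject must have at least two distinct labels
            distinct = 0
            seen = np.zeros(N_CLASSES, dtype=np.int64)
            for r in rows:
                if seen[y[r]] == 0:
                    seen[y[r]] = 1
                    distinct += 1
            if distinct < 2:
                continue
            for s in range(n_subsets):
                nf = subset_sizes[s]
                feat_idx = subset_feats[s]
                _predict_rows(orders[s], X, feat_idx, nf, subj, y, rows, o, j,
                              k_grid, preds)
                for ki in range(nk):
                    C = np.zeros((N_CLASSES, N_CLASSES))
                    for r in range(rows.shape[0]):
                        C[y[rows[r]], preds[r, ki]] += 1.0
                    c = _cindex_contingency(C)
                    if not np.isnan(c):
                        sum_c[s, ki] += c
                        cnt_c[s, ki] += 1
        # argmax of mean inner c-index, first-encountered tie rule
        bv = -1.0
        bs = 0
        bk = 0
        for s in range(n_subsets):
            for ki in range(nk):
                if cnt_c[s, ki] == 0:
                    continue
                v = sum_c[s, ki] / cnt_c[s, ki]
                if v > bv:
                    bv = v
                    bs = s
                    bk = ki
        best_s[o] = bs
        best_k[o] = bk
        best_val[o] = bv
        # outer evaluation with the selected model
        rows = np.arange(subj_start[o], subj_start[o + 1])
        one_k = k_grid[bk:bk + 1]
        _predict_rows(orders[bs], X, subset_feats[bs], subset_sizes[bs], subj, y,
                      rows, o, -1, one_k, preds[:, :1])
        C = np.zeros((N_CLASSES, N_CLASSES))
        for r in range(rows.shape[0]):
            C[y[rows[r]], preds[r, 0]] += 1.0
        fold_c[o] = _cindex_contingency(C)
    return best_s, best_k, fold_c, best_val


@njit(cache=True)
def _plain_loso_kernel(orders_s, X, feat_idx, nf, subj, y, subj_start, n_subjects, k):
    """Per-subject c-index for a fixed feature subset and k (plain LOSO)."""
    out = np.full(n_subjects, np.nan)
    k_grid = np.empty(1, dtype=np.int64)
    k_grid[0] = k
    for o in range(n_subjects):
        rows = np.arange(subj_start[o], subj_start[o + 1])
        preds = np.empty((rows.shape[0], 1), dtype=np.int64)
        _predict_rows(orders_s, X, feat_idx, nf, subj, y, rows, o, -1, k_grid, preds)
        C = np.zeros((N_CLASSES, N_CLASSES))
        for r in range(rows.shape[0]):
            C[y[rows[r]], preds[r, 0]] += 1.0
        out[o] = _cindex_contingency(C)
    return out


# ---------------------------------------------------------------------------

class NeighborEngine:
    """Precomputed per-subset neighbor lists plus the CV entry points."""

    def __init__(self, dataset: OrdinalDataset, k_grid: Sequence[int],
                 cache_depth: int = 96):
        self.ds = dataset
        self.k_grid = np.asarray(sorted(k_grid), dtype=np.int64)
        n, n_feat = dataset.X.shape
        self.subsets = enumerate_subsets(n_feat)
        kmax = int(self.k_grid[-1])
        depth = int(min(n, max(cache_depth, kmax + 40)))
        self.subset_feats = np.zeros((len(self.subsets), n_feat), dtype=np.int64)
        self.subset_sizes = np.zeros(len(self.subsets), dtype=np.int64)
        self.orders = np.empty((len(self.subsets), n, depth), dtype=np.int64)
        for si, cols in enumerate(self.subsets):
            self.subset_sizes[si] = len(cols)
            self.subset_feats[si, :len(cols)] = np.asarray(cols, dtype=np.int64)
            tree = cKDTree(dataset.X[:, list(cols)])
            _, idx = tree.query(dataset.X[:, list(cols)], k=depth)
            if depth == 1:
                idx = idx[:, None]
            self.orders[si] = idx
        self.n_subjects = len(dataset.subject_ids)
        counts = np.bincount(dataset.subj, minlength=self.n_subjects)
        self.subj_start = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)

    def nested_cv(self, y: np.ndarray | None = None):
        y = self.ds.y if y is None else np.asarray(y, dtype=np.int64)
        return _nested_cv_kernel(self.orders, self.ds.X, self.subset_feats,
                                 self.subset_sizes, self.ds.subj, y,
                                 self.subj_start, self.n_subjects, self.k_grid)

    def plain_loso(self, subset: Tuple[int, ...], k: int, y: np.ndarray | None = None):
        y = self.ds.y if y is None else np.asarray(y, dtype=np.int64)
        si = self.subsets.index(tuple(sorted(subset)))
        return _plain_loso_kernel(self.orders[si], self.ds.X, self.subset_feats[si],
                                  self.subset_sizes[si], self.ds.subj, y,
                                  self.subj_start, self.n_subjects, int(k))

    def permute_labels(self, rng: np.random.Generator) -> np.ndarray:
        """Labels shuffled independently within each test (features untouched)."""
        y = self.ds.y.copy()
        for t in np.unique(self.ds.test):
            idx = np.where(self.ds.test == t)[0]
            y[idx] = y[idx[rng.permutation(len(idx))]]
        return y
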