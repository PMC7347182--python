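"""Nonparametric statistical evaluation of the labelled sEMG features.

Implements the descriptive layer of the analysis: subject-level per-period
feature medians, pairwise Wilcoxon signed-rank comparisons across the four
pain periods, Spearman rank inter-correlations (features vs. features and
vs. the ordinal period index), and the feature screening that feeds the
predictive model.

No multiple-testing correction is applied; raw p-values are reported.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import FEATURES
from .labelling import MODEL_PERIODS

__all__ = [
    "subject_period_medians", "wilcoxon_signed_rank", "pairwise_period_tests",
    "spearman_rho", "correlation_matrix", "feature_screening",
    "period_duration_summary", "median_profiles",
    "plot_period_durations", "plot_median_profiles",
]

#: The candidate set reported by the original analysis.
DEFAULT_CANDIDATES: Tuple[str, ...] = ("corrms", "corwl", "levwl", "orbwl")

PERIOD_INDEX: Dict[str, int] = {p: i + 1 for i, p in enumerate(MODEL_PERIODS)}


def subject_period_medians(labelled: pd.DataFrame,
                           features: Sequence[str] = FEATURES) -> pd.DataFrame:
    """Median of each standardized feature per (subject, period P1-P4).

    Rows of all of a subject's tests are pooled before the median.  Subject x
    period cells with no underlying rows are omitted.
    """
    df = labelled[labelled["period"].isin(MODEL_PERIODS)]
    out = (df.groupby(["subject_id", "period"], observed=True)[list(features)]
             .median().reset_index())
    out["period"] = out["period"].astype(str)
    return out


def wilcoxon_signed_rank(paired_a, paired_b, alternative: str = "two-sided",
                         ) -> Tuple[float, float]:
    """Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped (Wilcoxon's original procedure); the exact
    null distribution is used for effective n <= 25 (falling back to the
    normal approximation when tied ranks make the exact distribution
    unavailable), and the continuity-corrected normal approximation above.
    Returns ``(W, p)`` where W is the smaller signed-rank sum.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on ties under 'exact'
        try:
            res = sps.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                               correction=True, method=method)
        except ValueError:
            res = sps.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                               correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


PERIOD_PAIRS: Tuple[Tuple[str, str], ...] = tuple(itertools.combinations(MODEL_PERIODS, 2))


def pairwise_period_tests(median_table: pd.DataFrame,
                          features: Sequence[str] = FEATURES,
                          min_subjects: int = 6) -> pd.DataFrame:
    """Wilcoxon signed-rank p-values for every feature and period pair.

    Only subjects present in both periods of a pair contribute; cells with
    fewer than ``min_subjects`` common subjects are NaN.  Returns a
    10-feature x 6-pair grid.
    """
    wide = median_table.set_index(["subject_id", "period"])
    grid = pd.DataFrame(index=list(features),
                        columns=[f"{a} vs {b}" for a, b in PERIOD_PAIRS], dtype=float)
    for a, b in PERIOD_PAIRS:
        col = f"{a} vs {b}"
        for feat in features:
            sub_a = wide.xs(a, level="period")[feat]
            sub_b = wide.xs(b, level="period")[feat]
            common = sub_a.index.intersection(sub_b.index)
            if len(common) < min_subjects:
                grid.loc[feat, col] = np.nan
                continue
            _, p = wilcoxon_signed_rank(sub_a.loc[common].to_numpy(),
                                        sub_b.loc[common].to_numpy())
            grid.loc[feat, col] = p
    return grid


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> NaN, reported as missing
        rho = sps.spearmanr(x, y).statistic
    return float(rho)  # NaN when either vector has zero rank variance


def correlation_matrix(labelled: pd.DataFrame,
                       features: Sequence[str] = FEATURES) -> pd.DataFrame:
    """Spearman correlations among features and with the period index (P1-P4 rows)."""
    df = labelled[labelled["period"].isin(MODEL_PERIODS)]
    cols = {"period_index": df["period"].map(PERIOD_INDEX).to_numpy(dtype=float)}
    for feat in features:
        cols[feat] = df[feat].to_numpy(dtype=float)
    frame = pd.DataFrame(cols)
    return frame.corr(method="spearman")


def feature_screening(labelled: pd.DataFrame = None, corr: pd.DataFrame = None,
                      mode: str = "fixed", redundancy_threshold: float = 0.80,
                      max_features: int = 4) -> Tuple[str, ...]:
    """Choose the candidate features for the predictive model.

    ``mode="fixed"`` (default) returns the reported candidate set
    {corrms, corwl, levwl, orbwl}.  ``mode="auto"`` ranks features by
    |rho| against the period index and greedily drops any feature whose
    pairwise |rho| with an already-kept, better-ranked feature exceeds the
    redundancy threshold, keeping at most ``max_features``.
    """
    if mode == "fixed":
        return DEFAULT_CANDIDATES
    if mode != "auto":
        raise ValueError(f"unknown screening mode {mode!r}")
    if corr is None:
        if labelled is None:
            raise ValueError("auto mode needs labelled rows or a correlation matrix")
        corr = correlation_matrix(labelled)
    period_corr = corr.loc[list(FEATURES), "period_index"].abs().sort_values(ascending=False)
    kept: list[str] = []
    for feat in period_corr.index:
        if len(kept) >= max_features:
            break
        if any(abs(corr.loc[feat, other]) > redundancy_threshold for other in kept):
            continue
        kept.append(feat)
    if not kept:  # degenerate matrix: fall back to the top-ranked feature
        kept = [period_corr.index[0]]
    return tuple(kept)


# ---------------------------------------------------------------------------
# descriptive summaries and plots

def period_duration_summary(manifest: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each period's length (seconds), overall and per stimulus."""
    from .labelling import compute_periods

    rows = []
    for _, r in manifest.iterrows():
        b = compute_periods(r["t1"], r["t2"], r["t3"], test_id=r["test_id"])
        rows.append({"stimulus_type": r["stimulus_type"],
                     "P0": b.t1 - b.t0, "P1": b.t1split - b.t1, "P2": b.t2 - b.t1split,
                     "P3": b.t2split - b.t2, "P4": b.t3 - b.t2split})
    per_test = pd.DataFrame(rows)
    summaries = []
    for name, df in [("All", per_test)] + [
            (s.capitalize(), per_test[per_test["stimulus_type"] == s])
            for s in per_test["stimulus_type"].unique()]:
        for period in ("P0", "P1", "P2", "P3", "P4"):
            summaries.append({"group": name, "period": period,
                              "mean_s": df[period].mean(), "sd_s": df[period].std()})
    return pd.DataFrame(summaries)


def median_profiles(labelled: pd.DataFrame,
                    features: Sequence[str] = FEATURES) -> pd.DataFrame:
    """Grand median of each standardized feature per period P0-P4."""
    return (labelled.groupby("period", observed=True)[list(features)]
                    .median().reset_index())


def plot_period_durations(manifest: pd.DataFrame, ax=None):
    """Bar chart of mean period durations with SD whiskers, per stimulus group."""
    import matplotlib.pyplot as plt

    summary = period_duration_summary(manifest)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups = summary["group"].unique()
    periods = ("P0", "P1", "P2", "P3", "P4")
    width = 0.8 / len(groups)
    for gi, group in enumerate(groups):
        sub = summary[summary["group"] == group].set_index("period").loc[list(periods)]
        xs = np.arange(len(periods)) + gi * width
        ax.bar(xs, sub["mean_s"], width=width, yerr=sub["sd_s"], capsize=3, label=group)
    ax.set_xticks(np.arange(len(periods)) + 0.4 - width / 2)
    ax.set_xticklabels(periods)
    ax.set_ylabel("duration (s)")
    ax.legend()
    return ax


def plot_median_profiles(labelled: pd.DataFrame, features: Sequence[str] = FEATURES, ax=None):
    """Median standardized feature value across periods P0-P4, one line per feature."""
    import matplotlib.pyplot as plt

    prof = median_profiles(labelled, features).set_index("period")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for feat in features:
        ax.plot(prof.index.astype(str), prof[feat], marker="o", label=feat)
    ax.set_ylabel("median standardized feature")
    ax.legend(ncol=2, fontsize=8)
    return ax
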