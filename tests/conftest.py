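"""Shared fixtures: tiny cohorts for unit tests, calibrated runs for the
full-pipeline checks, and small synthetic labelled tables for the model."""

from __future__ import annotations

import matplotlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import painemg

matplotlib.use("Agg")
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from painemg._engine import NeighborEngine, build_dataset
from painemg.model import final_loso_evaluation, nested_loso_cv, select_final_model
from painemg.stats import correlation_matrix, pairwise_period_tests, subject_period_medians


def tiny_config(seed: int = 7, **kw) -> painemg.CohortConfig:
    defaults = dict(
        n_subjects=4, tests_per_subject=2, n_excluded_tests=0,
        duration_params={
            "heat": painemg.DurationParams(16.0, 4.0, 14.0, 4.0),
            "electrical": painemg.DurationParams(14.0, 4.0, 12.0, 4.0),
        },
        seed=seed,
    )
    defaults.update(kw)
    return painemg.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return painemg.generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_labelled(tiny_cohort):
    feat = painemg.preprocess_cohort(tiny_cohort)
    lab = painemg.label_table(feat, tiny_cohort.manifest)
    std, _ = painemg.standardize_labelled(lab)
    return std


def make_labelled(n_subjects: int, rows_per_period: int, rng: np.random.Generator,
                  signal: float = 0.0, features=("corwl", "levwl"),
                  tests_per_subject: int = 2) -> pd.DataFrame:
    """Directly built labelled table: feature = signal * period_index + noise."""
    rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        for t in range(tests_per_subject):
            tid = f"{sid}_T{t + 1}"
            time = 0
            for pi, period in enumerate(painemg.MODEL_PERIODS, start=1):
                for _ in range(rows_per_period):
                    row = {"subject_id": sid, "test_id": tid, "time_s": float(time),
                           "period": period}
                    for f in features:
                        row[f] = signal * pi + rng.normal()
                    rows.append(row)
                    time += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full-scale calibrated runs, shared across the acceptance-level checks

N_CALIBRATION_SEEDS = 5


@pytest.fixture(scope="session")
def calibrated_runs():
    """Full pipeline on the default cohort for several seeds.

    Returns per-seed summaries plus (for the first seed) the labelled table
    and neighbor engine, reused by the permutation-significance check.
    """
    runs = []
    keep = {}
    config = painemg.ModelConfig()
    for seed in range(1, N_CALIBRATION_SEEDS + 1):
        cohort = painemg.generate_cohort(painemg.CohortConfig(seed=seed))
        feat = painemg.preprocess_cohort(cohort)
        lab = painemg.label_table(feat, cohort.manifest)
        std, _ = painemg.standardize_labelled(lab)
        engine = NeighborEngine(build_dataset(std, config.candidate_features),
                                config.k_grid)
        cv = nested_loso_cv(std, config, engine=engine)
        subset, k = select_final_model(cv)
        _, final_mean = final_loso_evaluation(std, subset, k, config, engine=engine)
        corr = correlation_matrix(std)
        period_rho = corr.loc[list(painemg.FEATURES), "period_index"].abs()
        grid = pairwise_period_tests(subject_period_medians(std))
        durations = cohort.manifest["t3"] - cohort.manifest["t1"]
        runs.append(dict(
            seed=seed,
            n_tests=len(cohort.tests),
            mean_duration=float(durations.mean()),
            sd_duration=float(durations.std()),
            aggregate=cv.aggregate,
            final_mean=final_mean,
            final_subset=subset,
            final_k=k,
            top_feature=period_rho.idxmax(),
            corwl_p2p3_p=float(grid.loc["corwl", "P2 vs P3"]),
        ))
        if seed == 1:
            keep = {"labelled": std, "engine": engine}
    return {"runs": runs, **keep}


# ---------------------------------------------------------------------------
# scaled-down null cohorts (all pain-response gains zero)

def null_config(seed: int) -> painemg.CohortConfig:
    envelope = painemg.EnvelopeParams(
        base_gains={m: 0.0 for m in painemg.MUSCLES})
    return painemg.CohortConfig(
        n_subjects=10, tests_per_subject=2, n_excluded_tests=0,
        duration_params={
            "heat": painemg.DurationParams(20.0, 6.0, 18.0, 6.0),
            "electrical": painemg.DurationParams(20.0, 6.0, 18.0, 6.0),
        },
        envelope=envelope, seed=seed)


@pytest.fixture(scope="session")
def null_runs():
    """Nested-CV aggregate and a 19-permutation p-value per null cohort."""
    config = painemg.ModelConfig(n_permutations=19)
    out = []
    for seed in range(101, 121):
        cohort = painemg.generate_cohort(null_config(seed))
        feat = painemg.preprocess_cohort(cohort)
        lab = painemg.label_table(feat, cohort.manifest)
        std, _ = painemg.standardize_labelled(lab)
        engine = NeighborEngine(build_dataset(std, config.candidate_features),
                                config.k_grid)
        res = painemg.permutation_test(std, config, engine=engine,
                                       rng=np.random.default_rng(seed))
        out.append(dict(seed=seed, aggregate=res.observed, p=res.p_value))
    return out
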