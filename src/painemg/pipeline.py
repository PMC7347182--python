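"""Reproducible end-to-end runs with file artifacts.

``run_pipeline`` ties the stages together:

``simulate`` -> ``preprocess`` -> ``label`` -> ``stats`` -> ``train-eval``
-> ``permtest``

Stages must form a prefix of that order; each stage reads only prior-stage
outputs, and a run directory carries a config echo (including the seed) so
that a rerun reproduces every artifact.  All tables are delimited text with
a header row, floats at six significant digits.

The single run seed is expanded into independent substreams per stage, so
e.g. enlarging the permutation count never perturbs cohort generation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import labelling, model, stats
from .config import RunConfig, save_run_config

__all__ = ["STAGES", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "label", "stats", "train-eval", "permtest")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    pass


def _check_stages(stages: Sequence[str]) -> list[str]:
    stages = list(stages)
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    if ordered != list(STAGES[: len(ordered)]):
        missing = [s for s in STAGES[: len(ordered)] if s not in stages]
        raise PipelineError(
            f"stages must be a contiguous prefix of {STAGES}; run {missing} first")
    return ordered


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(f"missing artifact {path.name}: run stage {producer!r} first")
    return path


def run_pipeline(config: RunConfig, out_dir, stages: Sequence[str] = STAGES,
                 n_permutations: Optional[int] = None) -> Dict:
    """Run the requested stage prefix, writing artifacts under ``out_dir``.

    Returns the summary report (also written as ``summary.json``) collecting
    the headline numbers of whichever stages ran.
    """
    config.validate()
    ordered = _check_stages(stages)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_run_config(config, out / "run_config.yaml")

    seed_root = np.random.SeedSequence(config.cohort.seed)
    cohort_seed, perm_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_root.spawn(2)]
    summary: Dict = {"seed": config.cohort.seed, "stages": ordered, "inputs": {}}

    if "simulate" in ordered:
        cfg = config.cohort
        cfg = type(cfg)(**{**cfg.__dict__, "seed": cohort_seed})
        cohort = cohort_mod.generate_cohort(cfg)
        manifest_path = cohort_mod.write_cohort(cohort, out)
        durations = cohort.manifest["t3"] - cohort.manifest["t1"]
        summary["n_tests"] = int(len(cohort.tests))
        summary["mean_duration_s"] = round(float(durations.mean()), 2)
        summary["sd_duration_s"] = round(float(durations.std()), 2)
        logger.info("simulate: %d tests written", len(cohort.tests))

    if "preprocess" in ordered:
        from .preprocessing import preprocess_cohort
        manifest_path = _require(out / "manifest.csv", "simulate")
        summary["inputs"]["manifest.csv"] = _file_hash(manifest_path)
        cohort = cohort_mod.read_cohort(manifest_path)
        features = preprocess_cohort(cohort, config.preprocessing)
        features.to_csv(out / "features_raw.csv", index=False, float_format=_FLOAT_FMT)

    if "label" in ordered:
        feat_path = _require(out / "features_raw.csv", "preprocess")
        summary["inputs"]["features_raw.csv"] = _file_hash(feat_path)
        features = pd.read_csv(feat_path)
        manifest = pd.read_csv(out / "manifest.csv")
        labelled = labelling.label_table(features, manifest)
        labelled, scale = labelling.standardize_labelled(labelled)
        labelled.to_csv(out / "features_labelled.csv", index=False, float_format=_FLOAT_FMT)
        scale.to_csv(out / "standardization.csv", index=False, float_format=_FLOAT_FMT)
        summary["n_labelled_rows"] = int(len(labelled))

    labelled_df = None

    def _load_labelled() -> pd.DataFrame:
        nonlocal labelled_df
        if labelled_df is None:
            path = _require(out / "features_labelled.csv", "label")
            summary["inputs"]["features_labelled.csv"] = _file_hash(path)
            labelled_df = pd.read_csv(path)
            labelled_df["period"] = pd.Categorical(
                labelled_df["period"], categories=list(labelling.PERIODS), ordered=True)
        return labelled_df

    if "stats" in ordered:
        labelled = _load_labelled()
        medians = stats.subject_period_medians(labelled)
        medians.to_csv(out / "subject_period_medians.csv", index=False, float_format=_FLOAT_FMT)
        grid = stats.pairwise_period_tests(medians)
        grid.to_csv(out / "wilcoxon_grid.csv", float_format=_FLOAT_FMT)
        corr = stats.correlation_matrix(labelled)
        corr.to_csv(out / "spearman_matrix.csv", float_format=_FLOAT_FMT)
        summary["top_period_correlation"] = (
            corr.loc[list(stats.FEATURES), "period_index"].abs().idxmax())

    if "train-eval" in ordered:
        labelled = _load_labelled()
        cv = model.nested_loso_cv(labelled, config.model)
        folds = cv.folds.copy()
        folds["features"] = folds["features"].map(lambda f: "+".join(f))
        folds.to_csv(out / "nested_cv_folds.csv", index=False, float_format=_FLOAT_FMT)
        subset, k = model.select_final_model(cv)
        per_subject, final_mean = model.final_loso_evaluation(
            labelled, subset, k, config.model)
        per_subject.to_csv(out / "final_per_subject.csv", index=False, float_format=_FLOAT_FMT)
        summary["meta_c_index"] = round(cv.aggregate, 4)
        summary["final_features"] = list(subset)
        summary["final_k"] = int(k)
        summary["final_c_index"] = round(final_mean, 4)

    if "permtest" in ordered:
        labelled = _load_labelled()
        B = n_permutations if n_permutations is not None else config.model.n_permutations
        res = model.permutation_test(labelled, config.model, n_permutations=B,
                                     rng=np.random.default_rng(perm_seed))
        pd.DataFrame({"null_c_index": res.null_distribution}).to_csv(
            out / "permutation_null.csv", index=False, float_format=_FLOAT_FMT)
        summary["permutation_p"] = round(res.p_value, 6)
        summary["permutation_observed"] = round(res.observed, 4)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
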