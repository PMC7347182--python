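"""Period definitions anchored to the self-report timestamps.

Each test's events — stimulus start t1, pain threshold t2, pain tolerance
t3 — define five periods.  The threshold and tolerance intervals are halved
(floor of the half-width) to give four ordinal pain-intensity strata:

======  ====================
period  time limits
======  ====================
P0      [t0, t1)    with t0 = t1 - 30
P1      [t1, t1split]      t1split = t1 + floor((t2 - t1) / 2)
P2      (t1split, t2)
P3      [t2, t2split]      t2split = t2 + floor((t3 - t2) / 2)
P4      (t2split, t3]
======  ====================

P0 is the no-pain baseline and is excluded from statistics and modelling;
P1 < P2 < P3 < P4 are the ordinal output classes.  Feature rows are assigned
by their window-start time; rows outside [t0, t3] are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List

import pandas as pd

__all__ = ["PeriodBoundaries", "PERIODS", "MODEL_PERIODS", "compute_periods",
           "label_rows", "label_table", "standardize_labelled"]

logger = logging.getLogger(__name__)

PERIODS: tuple = ("P0", "P1", "P2", "P3", "P4")
MODEL_PERIODS: tuple = ("P1", "P2", "P3", "P4")


@dataclass(frozen=True)
class PeriodBoundaries:
    t0: float
    t1: float
    t1split: float
    t2: float
    t2split: float
    t3: float


def compute_periods(t1: float, t2: float, t3: float, test_id: str = "?") -> PeriodBoundaries:
    """Derive the period boundaries from one test's event timestamps."""
    if not (t1 < t2 < t3):
        raise ValueError(
            f"test {test_id}: event ordering t1 < t2 < t3 violated: ({t1}, {t2}, {t3})")
    return PeriodBoundaries(
        t0=t1 - 30.0,
        t1=t1,
        t1split=t1 + math.floor((t2 - t1) / 2.0),
        t2=t2,
        t2split=t2 + math.floor((t3 - t2) / 2.0),
        t3=t3,
    )


def label_rows(feature_times: Iterable[float], boundaries: PeriodBoundaries) -> List[str]:
    """Label each row time with its period, or ``"outside"``.

    Open/closed interval endpoints follow the table above exactly, so every
    time in [t0, t3] receives exactly one label.
    """
    b = boundaries
    labels = []
    for t in feature_times:
        if b.t0 <= t < b.t1:
            labels.append("P0")
        elif b.t1 <= t <= b.t1split:
            labels.append("P1")
        elif b.t1split < t < b.t2:
            labels.append("P2")
        elif b.t2 <= t <= b.t2split:
            labels.append("P3")
        elif b.t2split < t <= b.t3:
            labels.append("P4")
        else:
            labels.append("outside")
    return labels


def label_table(features: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Attach period labels to a cohort feature table and drop outside rows.

    Tests that do not contribute at least one row to each of P1-P4 are
    excluded (logged), since the ordinal model needs every class observable
    within a test.
    """
    events = manifest.set_index("test_id")[["t1", "t2", "t3"]]
    out_frames = []
    for test_id, group in features.groupby("test_id", sort=False):
        t1, t2, t3 = events.loc[test_id]
        boundaries = compute_periods(t1, t2, t3, test_id=test_id)
        labels = label_rows(group["time_s"].to_numpy(), boundaries)
        group = group.assign(period=labels)
        group = group[group["period"] != "outside"]
        present = set(group["period"])
        if not set(MODEL_PERIODS) <= present:
            missing = sorted(set(MODEL_PERIODS) - present)
            logger.warning("excluding test %s: no rows in period(s) %s", test_id, missing)
            continue
        out_frames.append(group)
    if not out_frames:
        raise ValueError("no test retained after labelling")
    out = pd.concat(out_frames, ignore_index=True)
    out["period"] = pd.Categorical(out["period"], categories=list(PERIODS), ordered=True)
    return out


def standardize_labelled(labelled: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-test z-scoring over the labelled rows (P0 included)."""
    from .preprocessing import zscore_standardize

    frames, stats = [], []
    for test_id, group in labelled.groupby("test_id", sort=False):
        std, st = zscore_standardize(group)
        st.insert(0, "test_id", test_id)
        frames.append(std)
        stats.append(st)
    out = pd.concat(frames, ignore_index=True)
    out["period"] = pd.Categorical(out["period"], categories=list(PERIODS), ordered=True)
    return out, pd.concat(stats, ignore_index=True)
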