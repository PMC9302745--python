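"""Scoring observed-data calls against the absolute-data oracle.

The oracle's calls on absolute counts define "true" differential abundance;
a method's calls on the observed (fixed-depth) counts are scored against
them as a confusion matrix, summarized by sensitivity TP/(TP+FN) and
specificity TN/(TN+FP) = 1 - false positive rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AccuracyRecord:
    dataset_id: str
    method: str
    tp: int
    fp: int
    tn: int
    fn: int
    policy: str = "lenient"
    settings: tuple = ()

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else np.nan

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else np.nan

    @property
    def fp_count(self) -> int:
        return self.fp

    def as_row(self) -> dict:
        return {
            "dataset_id": self.dataset_id, "method": self.method,
            "policy": self.policy, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fp_count": self.fp_count,
            "settings": ";".join(self.settings),
        }


def confusion(oracle_calls: np.ndarray, observed_calls: np.ndarray,
              dataset_id: str = "", method: str = "",
              policy: str = "lenient",
              settings: Sequence[str] = ()) -> AccuracyRecord:
    """Confusion counts of observed calls against oracle calls."""
    o = np.asarray(oracle_calls, dtype=bool)
    c = np.asarray(observed_calls, dtype=bool)
    if o.shape != c.shape:
        raise ValueError("call vectors must have equal length")
    return AccuracyRecord(
        dataset_id=dataset_id, method=method, policy=policy,
        settings=tuple(settings),
        tp=int(np.sum(o & c)), fp=int(np.sum(~o & c)),
        tn=int(np.sum(~o & ~c)), fn=int(np.sum(o & ~c)),
    )


def records_frame(records: Iterable[AccuracyRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


def aggregate(records: pd.DataFrame,
              group_by: Sequence[str] = ("method",)) -> pd.DataFrame:
    """Median accuracy and low-specificity prevalence per group.

    Per group: median sensitivity (undefined values excluded), median
    specificity, percent of records with specificity below 0.95 and below
    0.5, and the median false-positive count.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    rows = []
    for key, grp in records.groupby(list(group_by)):
        if len(grp) == 0:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"empty group {key}; omitted")
            continue
        key = key if isinstance(key, tuple) else (key,)
        spec = grp["specificity"].dropna()
        rows.append({
            **dict(zip(group_by, key)),
            "n": len(grp),
            "median_sensitivity": grp["sensitivity"].median(),
            "median_specificity": spec.median(),
            "pct_below_95_specificity": 100.0 * (spec < 0.95).mean(),
            "pct_below_50_specificity": 100.0 * (spec < 0.5).mean(),
            "median_fp_count": grp["fp_count"].median(),
        })
    return pd.DataFrame(rows)


def classify_setting(P: int, a_level: int, n_a_levels: int = 5) -> tuple:
    """Partially overlapping study-setting labels from grid-level parameters.

    ``a_level`` indexes the perturbation-scale grid level (0 = lowest).
    Microbial: P <= 1000 at the top perturbation level.  Bulk: P = 5000 at
    the lower levels.  Cell: P >= 1000 at the middle levels.  A data set may
    carry several labels (or none).
    """
    top = n_a_levels - 1
    labels = []
    if P <= 1000 and a_level == top:
        labels.append("Microbial")
    if P >= 1000 and 1 <= a_level <= n_a_levels - 2:
        labels.append("Cell")
    if P == 5000 and a_level <= 1:
        labels.append("Bulk")
    return tuple(labels)


def correlate_characteristics(records: pd.DataFrame,
                              features: pd.DataFrame,
                              feature_cols: Optional[Sequence[str]] = None
                              ) -> pd.DataFrame:
    """Spearman correlation of each signature feature with accuracy.

    ``records`` and ``features`` are joined on ``dataset_id``; each feature
    column is rank-correlated (tie-corrected) against sensitivity and
    specificity pooled over methods.  Constant columns yield NaN and are
    flagged.
    """
    merged = records.merge(features, on="dataset_id", how="inner")
    if feature_cols is None:
        feature_cols = [c for c in features.columns if c != "dataset_id"]
    rows = []
    for col in feature_cols:
        row = {"feature": col}
        for target in ("sensitivity", "specificity"):
            sub = merged[[col, target]].dropna()
            if len(sub) < 3 or sub[col].nunique() < 2 or sub[target].nunique() < 2:
                row[f"rho_{target}"] = np.nan
                row[f"defined_{target}"] = False
            else:
                row[f"rho_{target}"] = stats.spearmanr(sub[col],
                                                       sub[target]).statistic
                row[f"defined_{target}"] = True
        rows.append(row)
    return pd.DataFrame(rows)
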