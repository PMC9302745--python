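"""Random-forest meta-models predicting per-method accuracy from signatures.

For each differential-abundance method and each accuracy target (sensitivity
or specificity) a random-forest regressor is trained on the signature
vectors of simulated data sets, with an 80/20 train/holdout split.  Reports
carry the holdout R-squared, normalized gain-style importances (total
impurity decrease), and per-tree-quantile predictive intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .signatures import SIGNATURE_REGISTRY


@dataclass(frozen=True)
class PredictorSpec:
    method: str
    target: str  # "sensitivity" or "specificity"
    n_trees: int = 500
    max_features: str | float = 1.0
    split_seed: int = 0
    train_fraction: float = 0.8

    def __post_init__(self):
        if self.target not in ("sensitivity", "specificity"):
            raise ValueError("target must be sensitivity or specificity")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_trees < 50:
            raise ValueError("n_trees must be >= 50")


@dataclass
class PredictionReport:
    method: str
    target: str
    r2_holdout: float
    n_train: int
    n_holdout: int
    importance: Dict[str, float] = field(default_factory=dict)


@dataclass
class FittedPredictor:
    spec: PredictorSpec
    model: RandomForestRegressor
    feature_names: list
    report: PredictionReport


def _design(signatures: pd.DataFrame,
            feature_names: Optional[Sequence[str]] = None):
    if feature_names is None:
        registry = [n for n, _ in SIGNATURE_REGISTRY]
        feature_names = [c for c in registry if c in signatures.columns]
    missing = [c for c in feature_names if c not in signatures.columns]
    if missing:
        raise ValueError(f"signature columns missing: {missing}")
    return signatures[list(feature_names)].to_numpy(float), list(feature_names)


def train_predictor(signatures: pd.DataFrame, accuracy_records: pd.DataFrame,
                    spec: PredictorSpec,
                    feature_names: Optional[Sequence[str]] = None
                    ) -> FittedPredictor:
    """Train one per-method accuracy regressor and score it on the holdout.

    ``signatures`` must carry a ``dataset_id`` column plus registry features;
    ``accuracy_records`` a ``dataset_id``, ``method`` and the target column.
    """
    recs = accuracy_records[accuracy_records["method"] == spec.method]
    joined = recs.merge(signatures, on="dataset_id", how="inner")
    joined = joined.dropna(subset=[spec.target])
    if len(joined) < 50:
        raise ValueError("need >= 50 joined rows to train a meta-model")
    y = joined[spec.target].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate constant target")
    X, feature_names = _design(joined, feature_names)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=spec.train_fraction, random_state=spec.split_seed)
    model = RandomForestRegressor(
        n_estimators=spec.n_trees, max_features=spec.max_features,
        random_state=spec.split_seed, n_jobs=1)
    model.fit(X_tr, y_tr)

    pred = model.predict(X_te)
    sse = float(np.sum((y_te - pred) ** 2))
    sst = float(np.sum((y_te - y_te.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    report = PredictionReport(
        method=spec.method, target=spec.target, r2_holdout=r2,
        n_train=len(y_tr), n_holdout=len(y_te),
        importance=gain_importance(model, feature_names))
    return FittedPredictor(spec=spec, model=model,
                           feature_names=feature_names, report=report)


def gain_importance(model: RandomForestRegressor,
                    feature_names: Sequence[str]) -> Dict[str, float]:
    """Gain-style importances (total impurity decrease), normalized to sum 1."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return dict(zip(feature_names, imp))


def predict_with_intervals(fitted: FittedPredictor,
                           signatures: pd.DataFrame) -> pd.DataFrame:
    """Ensemble-mean predictions with 50% and 90% per-tree-quantile bands.

    Bands are the 25/75 and 5/95 percentiles of the individual trees'
    predictions, clipped to [0, 1]; the 50% band is nested in the 90% band
    by construction.
    """
    X, _ = _design(signatures, fitted.feature_names)
    per_tree = np.stack([t.predict(X) for t in fitted.model.estimators_])
    point = per_tree.mean(axis=0)
    q = np.percentile(per_tree, [5, 25, 75, 95], axis=0)
    out = pd.DataFrame({
        "point": np.clip(point, 0, 1),
        "lo90": np.clip(q[0], 0, 1), "lo50": np.clip(q[1], 0, 1),
        "hi50": np.clip(q[2], 0, 1), "hi90": np.clip(q[3], 0, 1),
    })
    if "dataset_id" in signatures.columns:
        out.insert(0, "dataset_id", signatures["dataset_id"].to_numpy())
    return out


def train_all(signatures: pd.DataFrame, accuracy_records: pd.DataFrame,
              methods: Sequence[str], split_seed: int = 0,
              n_trees: int = 500) -> pd.DataFrame:
    """Train method x {sensitivity, specificity} models; tabulated R-squared."""
    rows = []
    for method in methods:
        for target in ("sensitivity", "specificity"):
            spec = PredictorSpec(method=method, target=target,
                                 n_trees=n_trees, split_seed=split_seed)
            fitted = train_predictor(signatures, accuracy_records, spec)
            top = sorted(fitted.report.importance.items(),
                         key=lambda kv: -kv[1])[:5]
            rows.append({
                "method": method, "target": target,
                "r2_holdout": fitted.report.r2_holdout,
                "n_train": fitted.report.n_train,
                "n_holdout": fitted.report.n_holdout,
                "top_features": ";".join(name for name, _ in top),
            })
    return pd.DataFrame(rows)
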