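"""Readers and writers for count matrices, labels, truth and configs.

Count matrices are features x samples.  TSV files carry a header row of
sample IDs and a first column of feature IDs; MatrixMarket output writes a
``.mtx`` with sidecar ``.features.tsv`` / ``.samples.tsv`` files.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .simulate import CorrelationSpec, PairedCountData, SimulationConfig


def write_counts_tsv(path, counts: np.ndarray,
                     feature_ids=None, sample_ids=None) -> None:
    counts = np.asarray(counts)
    P, n = counts.shape
    feature_ids = (feature_ids if feature_ids is not None
                   else [f"feature_{i}" for i in range(P)])
    sample_ids = (sample_ids if sample_ids is not None
                  else [f"sample_{j}" for j in range(n)])
    pd.DataFrame(counts, index=feature_ids, columns=sample_ids).to_csv(
        path, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> Tuple[np.ndarray, list, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index), list(df.columns)


def write_counts_mtx(path, counts: np.ndarray,
                     feature_ids=None, sample_ids=None) -> None:
    path = Path(path)
    counts = np.asarray(counts)
    P, n = counts.shape
    spio.mmwrite(path, sparse.csr_matrix(counts))
    feature_ids = (feature_ids if feature_ids is not None
                   else [f"feature_{i}" for i in range(P)])
    sample_ids = (sample_ids if sample_ids is not None
                  else [f"sample_{j}" for j in range(n)])
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    pd.Series(feature_ids).to_csv(stem.with_suffix(".features.tsv"),
                                  sep="\t", index=False, header=False)
    pd.Series(sample_ids).to_csv(stem.with_suffix(".samples.tsv"),
                                 sep="\t", index=False, header=False)


def read_counts_mtx(path) -> Tuple[np.ndarray, list, list]:
    path = Path(path)
    counts = np.asarray(spio.mmread(path).todense())
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    features = list(pd.read_csv(stem.with_suffix(".features.tsv"),
                                sep="\t", header=None)[0])
    samples = list(pd.read_csv(stem.with_suffix(".samples.tsv"),
                               sep="\t", header=None)[0])
    return counts, features, samples


def write_labels_tsv(path, condition: np.ndarray, sample_ids=None) -> None:
    condition = np.asarray(condition)
    sample_ids = (sample_ids if sample_ids is not None
                  else [f"sample_{j}" for j in range(condition.size)])
    pd.DataFrame({"sample_id": sample_ids,
                  "condition": condition}).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["condition"].to_numpy()


def write_truth_tsv(path, truth: np.ndarray, feature_ids=None) -> None:
    truth = np.asarray(truth, dtype=bool)
    feature_ids = (feature_ids if feature_ids is not None
                   else [f"feature_{i}" for i in range(truth.size)])
    pd.DataFrame({"feature_id": feature_ids,
                  "differential": truth.astype(int)}).to_csv(
        path, sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["corr"] = asdict(config.corr)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    corr = d.pop("corr", None)
    if corr is not None:
        d["corr"] = CorrelationSpec(**corr)
    return SimulationConfig(**d)


def write_config(path, config: SimulationConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def write_dataset(out_dir, data: PairedCountData,
                  config: Optional[SimulationConfig] = None) -> None:
    """Write a simulated pair (Y, Z, labels, truth, config) under one directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(out_dir / "absolute_counts.tsv", data.Y)
    write_counts_tsv(out_dir / "observed_counts.tsv", data.Z)
    write_labels_tsv(out_dir / "condition.tsv", data.condition)
    write_truth_tsv(out_dir / "truth.tsv", data.truth)
    if config is not None:
        write_config(out_dir / "config.yaml", config)
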