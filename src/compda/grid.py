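"""Hyperparameter-grid orchestration: simulate, test, score, summarize.

The full grid crosses feature number P, proportion differential c, five
correlation presets, five perturbation-scale levels, three replicate-noise
levels and five paired (m, S) baseline levels: 3*5*5*5*3*5 = 5625 cells.
The numeric level values are this package's own calibration, chosen so the
realized data span the intended ranges of observed-data characteristics
(percent zeros from near zero to above 80%, total-abundance fold changes
from ~1 up to several-fold, and realized detectable differential abundance
well below the parameterized proportion); see docs/methods.md.

A reduced preset (a uniform subsample of the full grid) is the desk-scale
surface used by the analysis drivers, tests and the acceptance script.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import da_tests, metrics, signatures
from .da_tests import LENIENT, STRINGENT, CallPolicy
from .simulate import CorrelationSpec, SimulationConfig, simulate_dataset

# --- canonical level values -------------------------------------------------

P_LEVELS_FULL = (100, 1000, 5000)
C_LEVELS = (0.2, 0.3, 0.5, 0.7, 0.9)

#: five paired (m, S) baseline levels, low to high abundance and spread
MS_LEVELS = ((2.5, 0.75), (3.5, 1.25), (4.5, 1.75), (5.5, 2.25), (6.5, 2.75))

#: perturbation variance a as a proportion of the log mean abundance m
A_FRAC_LEVELS = (0.1, 0.2, 0.4, 0.7, 1.0)

#: replicate-noise (per-sample scale multiplier) standard deviations
G_LEVELS = (0.05, 0.2, 0.4)

#: five correlation presets: independent features at one extreme, a block of
#: 50% strongly positively correlated features at the other
CORR_PRESETS: Tuple[CorrelationSpec, ...] = (
    CorrelationSpec(kind="identity"),
    CorrelationSpec(kind="dense-positive", strength=0.3, frac_correlated=0.2),
    CorrelationSpec(kind="dense-positive", strength=0.5, frac_correlated=0.3),
    CorrelationSpec(kind="dense-positive", strength=0.7, frac_correlated=0.4),
    CorrelationSpec(kind="dense-positive", strength=0.9, frac_correlated=0.5),
)


@dataclass(frozen=True)
class GridSpec:
    """Level lists whose Cartesian product defines the simulation grid."""

    P_levels: Sequence[int] = P_LEVELS_FULL
    c_levels: Sequence[float] = C_LEVELS
    ms_levels: Sequence[Tuple[float, float]] = MS_LEVELS
    a_frac_levels: Sequence[float] = A_FRAC_LEVELS
    g_levels: Sequence[float] = G_LEVELS
    corr_presets: Sequence[CorrelationSpec] = CORR_PRESETS
    root_seed: int = 0
    n_cells: Optional[int] = None  # uniform subsample; None = full product

    def __post_init__(self):
        for name in ("P_levels", "c_levels", "ms_levels", "a_frac_levels",
                     "g_levels", "corr_presets"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")


@dataclass(frozen=True)
class Cell:
    """One grid cell: a simulation config plus its grid-level coordinates."""

    cell_id: str
    config: SimulationConfig
    a_level: int
    levels: Dict[str, int] = field(default_factory=dict, compare=False)

    @property
    def settings(self) -> Tuple[str, ...]:
        return metrics.classify_setting(self.config.P, self.a_level)


def _cell_seed(root_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(root_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def expand_grid(spec: GridSpec) -> List[Cell]:
    """Deterministic list of cells: full product, optionally subsampled.

    Subsampling (``n_cells`` set) draws cells uniformly without replacement
    from the product using the root seed, so every hyperparameter level stays
    represented in proportion.
    """
    combos = []
    for iP, P in enumerate(spec.P_levels):
        for ic, c in enumerate(spec.c_levels):
            for icorr, corr in enumerate(spec.corr_presets):
                for ia, a_frac in enumerate(spec.a_frac_levels):
                    for ig, g in enumerate(spec.g_levels):
                        for ims, (m, S) in enumerate(spec.ms_levels):
                            combos.append((iP, ic, icorr, ia, ig, ims,
                                           P, c, corr, a_frac, g, m, S))
    if spec.n_cells is not None and spec.n_cells < len(combos):
        rng = np.random.default_rng(np.random.SeedSequence(
            spec.root_seed, spawn_key=(0xC311,)))
        pick = np.sort(rng.choice(len(combos), spec.n_cells, replace=False))
        combos = [combos[i] for i in pick]

    cells = []
    for idx, (iP, ic, icorr, ia, ig, ims, P, c, corr, a_frac, g, m, S) \
            in enumerate(combos):
        config = SimulationConfig(
            P=P, m=m, S=S, corr=corr, a=a_frac * m, c=c, g=g,
            seed=_cell_seed(spec.root_seed, idx))
        cells.append(Cell(
            cell_id=f"cell{idx:05d}", config=config, a_level=ia,
            levels={"P": iP, "c": ic, "corr": icorr, "a": ia, "g": ig,
                    "ms": ims}))
    return cells


def run_cell(cell: Cell,
             methods: Sequence[str] = da_tests.ANALOG_METHODS + ("total_glm",),
             policies: Dict[str, CallPolicy] = None,
             n_mc: int = 128) -> Tuple[List[metrics.AccuracyRecord],
                                       Dict[str, float]]:
    """Simulate one cell, run the oracle and every method, score and featurize.

    Returns accuracy records for each (method, policy) pair and the signature
    vector of the observed counts.  Fully deterministic given the cell seed.
    """
    if policies is None:
        policies = {"lenient": LENIENT, "stringent": STRINGENT}
    data = simulate_dataset(cell.config)

    oracle = da_tests.nb_glm_test(data.Y, data.condition)
    oracle_calls = {name: da_tests.call_features(oracle, pol)
                    for name, pol in policies.items()}

    records = []
    for j, method in enumerate(methods):
        rng = np.random.default_rng(np.random.SeedSequence(
            cell.config.seed, spawn_key=(1, j)))
        with warnings.catch_warnings():
            # estimator fallbacks are flagged in their outputs; a sweep
            # should not drown the log in per-cell warnings
            warnings.simplefilter("ignore", UserWarning)
            result = da_tests.run_method(data.Z, data.condition, method,
                                         rng=rng, n_mc=n_mc)
        for pol_name, pol in policies.items():
            calls = da_tests.call_features(result, pol)
            records.append(metrics.confusion(
                oracle_calls[pol_name], calls, dataset_id=cell.cell_id,
                method=method, policy=pol_name, settings=cell.settings))

    sig = {"dataset_id": cell.cell_id,
           **signatures.compute_signatures(data.Z, data.condition)}
    return records, sig


def sweep(cells: Sequence[Cell], out_dir: Optional[Path] = None,
          methods: Sequence[str] = da_tests.ANALOG_METHODS + ("total_glm",),
          n_mc: int = 128, resume: bool = True,
          progress: bool = False) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run many cells; optionally checkpoint per-cell CSV rows for resume.

    Returns ``(records, signatures)`` data frames.  With ``out_dir`` set, a
    manifest records completed cells so an interrupted sweep restarts where
    it stopped and yields the same final record set.
    """
    manifest_path = records_path = sig_path = None
    done = set()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.jsonl"
        records_path = out_dir / "records.csv"
        sig_path = out_dir / "signatures.csv"
        if resume and manifest_path.exists():
            for line in manifest_path.read_text().splitlines():
                entry = json.loads(line)
                if entry.get("status") == "ok":
                    done.add(entry["cell_id"])

    rec_rows, sig_rows = [], []
    for cell in cells:
        if cell.cell_id in done:
            continue
        t0 = time.time()
        try:
            records, sig = run_cell(cell, methods=methods, n_mc=n_mc)
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            if manifest_path is not None:
                with open(manifest_path, "a") as fh:
                    fh.write(json.dumps({
                        "cell_id": cell.cell_id, "status": "failed",
                        "error": repr(exc)}) + "\n")
            continue
        rows = [r.as_row() for r in records]
        rec_rows.extend(rows)
        sig_rows.append(sig)
        if out_dir is not None:
            pd.DataFrame(rows).to_csv(
                records_path, mode="a", index=False,
                header=not records_path.exists())
            pd.DataFrame([sig]).to_csv(
                sig_path, mode="a", index=False, header=not sig_path.exists())
            with open(manifest_path, "a") as fh:
                fh.write(json.dumps({
                    "cell_id": cell.cell_id, "status": "ok",
                    "seed": cell.config.seed,
                    "walltime_s": round(time.time() - t0, 3)}) + "\n")
        if progress:
            print(f"{cell.cell_id} done in {time.time() - t0:.1f}s")

    if out_dir is not None and done:
        records = pd.read_csv(records_path)
        records["settings"] = records["settings"].fillna("")
        sigs = pd.read_csv(sig_path)
        return records, sigs
    return pd.DataFrame(rec_rows), pd.DataFrame(sig_rows)


def reduced_grid(root_seed: int = 0, n_cells: int = 300) -> GridSpec:
    """The desk-scale preset: the full grid, uniformly subsampled.

    Every hyperparameter level (including P = 5000) stays represented in
    proportion; only the number of cells is reduced.
    """
    return GridSpec(root_seed=root_seed, n_cells=n_cells)


def _explode_settings(records: pd.DataFrame) -> pd.DataFrame:
    rec = records.copy()
    rec["settings"] = rec["settings"].fillna("")
    rec = rec[rec["settings"] != ""]
    rec = rec.assign(setting=rec["settings"].str.split(";")).explode("setting")
    return rec


def make_report(records: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Accuracy summary tables for both calling policies.

    ``by_setting_lenient`` / ``by_setting_stringent`` follow the
    setting-by-method layout (median and thresholded specificity);
    ``overall`` pools the five method analogs per policy.
    """
    out = {}
    for pol in ("lenient", "stringent"):
        sub = records[(records["policy"] == pol)
                      & records["method"].isin(da_tests.ANALOG_METHODS)]
        if len(sub) == 0:
            continue
        exploded = _explode_settings(sub)
        if len(exploded):
            out[f"by_setting_{pol}"] = metrics.aggregate(
                exploded, group_by=("setting", "method"))
        out[f"by_method_{pol}"] = metrics.aggregate(sub, group_by=("method",))
        out.setdefault("overall", pd.DataFrame())
        overall_row = {
            "policy": pol, "n": len(sub),
            "median_sensitivity": sub["sensitivity"].median(),
            "median_specificity": sub["specificity"].median(),
            "median_fpr_pct": 100.0 * (1.0 - sub["specificity"]).median(),
        }
        out["overall"] = pd.concat(
            [out["overall"], pd.DataFrame([overall_row])], ignore_index=True)
    return out
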