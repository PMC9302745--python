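"""Summary "signatures" of observed relative-count data.

These are per-data-set statistics computed from the observed counts and the
condition labels alone — sparsity, evenness, the shape of the pairwise
feature-correlation distribution, and the prevalence and spread of apparent
feature-level change — used downstream to predict how well
differential-abundance calls on observed counts will track calls on absolute
counts.  The registry is this package's own documented feature set.

All features are deterministic for a given matrix: the correlation
statistics use a feature subsample drawn with a fixed internal seed when P
exceeds ``corr_subsample``.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from scipy import stats

PSEUDO = 0.5
LN2 = np.log(2.0)

_QUANTS = (10, 25, 50, 75, 90)

#: (name, one-line definition) in stable order
SIGNATURE_REGISTRY: List[Tuple[str, str]] = [
    ("prop_zero", "fraction of zero entries in Z"),
    ("prop_one", "fraction of entries equal to 1 in Z"),
    ("prop_zero_cond1", "fraction of zero entries among condition-1 samples"),
    ("prop_zero_cond2", "fraction of zero entries among condition-2 samples"),
    ("dropout_change", "prop_zero_cond2 - prop_zero_cond1"),
    ("prop_one_cond1", "fraction of one-entries among condition-1 samples"),
    ("prop_one_cond2", "fraction of one-entries among condition-2 samples"),
    ("prop_feature_any_zero", "fraction of features with >= 1 zero entry"),
    ("prop_feature_allzero_cond1",
     "fraction of features all-zero in condition 1"),
    ("prop_feature_allzero_cond2",
     "fraction of features all-zero in condition 2"),
    ("richness_change",
     "change in fraction of features detected (non-all-zero), cond2 - cond1"),
    ("corr_mean", "mean off-diagonal CLR feature correlation (subsampled)"),
    ("corr_sd", "sd of off-diagonal CLR feature correlations"),
    ("corr_skew",
     "adjusted Fisher-Pearson skewness of the CLR correlation distribution"),
    ("prop_corr_strong", "fraction of |correlation| > 0.5 off-diagonals"),
    ("mean_log_cond1", "mean log2(Z+0.5), condition 1"),
    ("mean_log_cond2", "mean log2(Z+0.5), condition 2"),
    ("sd_log_cond1", "sd of log2(Z+0.5), condition 1"),
    ("sd_log_cond2", "sd of log2(Z+0.5), condition 2"),
    *[(f"q{q}_log_cond{k}",
       f"{q}th percentile of log2(Z+0.5), condition {k}")
      for k in (1, 2) for q in _QUANTS],
    ("evenness_cond1", "Pielou evenness of the mean composition, condition 1"),
    ("evenness_cond2", "Pielou evenness of the mean composition, condition 2"),
    ("evenness_change", "evenness_cond2 - evenness_cond1"),
    ("top1pct_share_cond1",
     "share of counts in the top 1% of features, condition 1"),
    ("top1pct_share_cond2",
     "share of counts in the top 1% of features, condition 2"),
    ("top5pct_share_cond1",
     "share of counts in the top 5% of features, condition 1"),
    ("top5pct_share_cond2",
     "share of counts in the top 5% of features, condition 2"),
    ("max_share_cond1", "largest single-feature share, condition 1"),
    ("max_share_cond2", "largest single-feature share, condition 2"),
    ("mean_delta_log", "mean per-feature change in log2 counts, cond2 - cond1"),
    ("sd_delta_log", "sd of the per-feature change in log2 counts"),
    ("mad_delta_log", "median absolute deviation of the change in log2 counts"),
    ("skew_delta_log", "skewness of the change in log2 counts"),
    ("prop_large_increase",
     "fraction of features with (delta log2 - mean delta) >= +1"),
    ("prop_large_decrease",
     "fraction of features with (delta log2 - mean delta) <= -1"),
    ("prop_large_change", "prop_large_increase + prop_large_decrease"),
    ("total_fc", "ratio of mean observed totals, condition 2 over condition 1"),
    ("cv_depth", "coefficient of variation of observed per-sample totals"),
    ("median_feature_mean", "median per-feature mean count"),
    ("prop_feature_mean_below_1", "fraction of features with mean count < 1"),
    ("log_n_features", "log10 number of features"),
    ("n_samples", "number of samples"),
]


def signature_registry() -> List[Tuple[str, str]]:
    """The ordered (name, definition) registry of signature features."""
    return list(SIGNATURE_REGISTRY)


def _skewness(x: np.ndarray) -> float:
    """Adjusted Fisher-Pearson skewness (bias-corrected)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.std(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=False))


def _pielou(mean_counts: np.ndarray) -> float:
    pos = mean_counts[mean_counts > 0]
    if pos.size < 2:
        return 0.0
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum() / np.log(pos.size))


def _top_share(mean_counts: np.ndarray, frac: float) -> float:
    total = mean_counts.sum()
    if total <= 0:
        return 0.0
    k = max(1, int(np.ceil(frac * mean_counts.size)))
    return float(np.sort(mean_counts)[::-1][:k].sum() / total)


def compute_signatures(Z: np.ndarray, condition: np.ndarray,
                       corr_subsample: int = 500, seed: int = 0,
                       large_lfc: float = 1.0) -> Dict[str, float]:
    """Compute every registry feature for one observed count matrix.

    ``large_lfc`` is the log2 threshold (relative to the mean change) above
    which a feature counts toward the large-increase/decrease proportions.
    """
    Z = np.asarray(Z, dtype=float)
    condition = np.asarray(condition)
    groups = np.unique(condition)
    if len(groups) != 2:
        raise ValueError("two condition groups required")
    m1, m2 = condition == groups[0], condition == groups[1]
    P, n = Z.shape
    z1, z2 = Z[:, m1], Z[:, m2]

    sig: Dict[str, float] = {}
    sig["prop_zero"] = float((Z == 0).mean())
    sig["prop_one"] = float((Z == 1).mean())
    sig["prop_zero_cond1"] = float((z1 == 0).mean())
    sig["prop_zero_cond2"] = float((z2 == 0).mean())
    sig["dropout_change"] = sig["prop_zero_cond2"] - sig["prop_zero_cond1"]
    sig["prop_one_cond1"] = float((z1 == 1).mean())
    sig["prop_one_cond2"] = float((z2 == 1).mean())
    sig["prop_feature_any_zero"] = float((Z == 0).any(axis=1).mean())
    allz1 = (z1 == 0).all(axis=1)
    allz2 = (z2 == 0).all(axis=1)
    sig["prop_feature_allzero_cond1"] = float(allz1.mean())
    sig["prop_feature_allzero_cond2"] = float(allz2.mean())
    sig["richness_change"] = float((~allz2).mean() - (~allz1).mean())

    # pairwise CLR feature correlations on a seeded subsample
    rng = np.random.default_rng(seed)
    idx = (np.arange(P) if P <= corr_subsample
           else np.sort(rng.choice(P, corr_subsample, replace=False)))
    logz = np.log(Z[idx] + PSEUDO)
    clr = logz - logz.mean(axis=0, keepdims=True)
    sd = clr.std(axis=1)
    keep = sd > 0
    if keep.sum() >= 3:
        corr = np.corrcoef(clr[keep])
        off = corr[np.triu_indices(keep.sum(), k=1)]
        sig["corr_mean"] = float(off.mean())
        sig["corr_sd"] = float(off.std())
        sig["corr_skew"] = _skewness(off)
        sig["prop_corr_strong"] = float((np.abs(off) > 0.5).mean())
    else:
        sig["corr_mean"] = sig["corr_sd"] = 0.0
        sig["corr_skew"] = sig["prop_corr_strong"] = 0.0

    for name, zc in (("cond1", z1), ("cond2", z2)):
        lg = np.log2(zc + PSEUDO)
        sig[f"mean_log_{name}"] = float(lg.mean())
        sig[f"sd_log_{name}"] = float(lg.std())
        for q in _QUANTS:
            sig[f"q{q}_log_{name}"] = float(np.percentile(lg, q))
        mc = zc.mean(axis=1)
        sig[f"evenness_{name}"] = _pielou(mc)
        sig[f"top1pct_share_{name}"] = _top_share(mc, 0.01)
        sig[f"top5pct_share_{name}"] = _top_share(mc, 0.05)
        total = mc.sum()
        sig[f"max_share_{name}"] = float(mc.max() / total) if total > 0 else 0.0
    sig["evenness_change"] = sig["evenness_cond2"] - sig["evenness_cond1"]

    dl = np.log2(z2.mean(axis=1) + PSEUDO) - np.log2(z1.mean(axis=1) + PSEUDO)
    centered = dl - dl.mean()
    sig["mean_delta_log"] = float(dl.mean())
    sig["sd_delta_log"] = float(dl.std())
    sig["mad_delta_log"] = float(np.median(np.abs(dl - np.median(dl))))
    sig["skew_delta_log"] = _skewness(dl)
    sig["prop_large_increase"] = float((centered >= large_lfc).mean())
    sig["prop_large_decrease"] = float((centered <= -large_lfc).mean())
    sig["prop_large_change"] = (sig["prop_large_increase"]
                                + sig["prop_large_decrease"])

    totals = Z.sum(axis=0)
    t1, t2 = totals[m1].mean(), totals[m2].mean()
    sig["total_fc"] = float(t2 / t1) if t1 > 0 else np.nan
    sig["cv_depth"] = float(totals.std() / totals.mean())
    feat_mean = Z.mean(axis=1)
    sig["median_feature_mean"] = float(np.median(feat_mean))
    sig["prop_feature_mean_below_1"] = float((feat_mean < 1).mean())
    sig["log_n_features"] = float(np.log10(P))
    sig["n_samples"] = float(n)

    names = [name for name, _ in SIGNATURE_REGISTRY]
    assert set(sig) == set(names), "signature registry out of sync"
    return {name: sig[name] for name in names}
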