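"""Per-sample size-factor estimators.

Each strategy rescales observed per-sample abundances against a reference
quantity.  All estimators return strictly positive factors normalized to
geometric mean 1; any global constant cancels in two-group testing, so the
convention is harmless and makes strategies comparable.

Implemented strategies and the published procedures they follow:

- ``size_factors_total``          library-size (CPM-style) scaling
- ``size_factors_tmm``            trimmed mean of M-values (edgeR)
- ``size_factors_median_ratio``   median-of-ratios (DESeq2), with optional
                                  control features
- ``size_factors_deconvolution``  pooling and deconvolution (scran)
- ``size_factors_bias_correction``  sampling-fraction offsets (ANCOM-BC),
                                  simplified to an alternating trimmed-mean
                                  estimator

These are from-scratch implementations of the algorithmic cores, not calls
into the original packages; agreement with those packages is close but
approximate (e.g. the bias-correction estimator omits the original's
variance-component machinery).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as scipy_stats

PSEUDO = 0.5  # pseudo-count wherever a log of zero would otherwise occur


@dataclass
class SizeFactors:
    values: np.ndarray
    method: str
    reference: Optional[np.ndarray] = None  # control-feature indices, if used
    converged: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("size factors must be positive and finite")


def _geomean_one(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return values / np.exp(np.mean(np.log(values)))


def size_factors_total(Z: np.ndarray) -> SizeFactors:
    """Factors proportional to per-sample column totals."""
    Z = np.asarray(Z, dtype=float)
    totals = Z.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample must have a positive total count")
    return SizeFactors(_geomean_one(totals), "total")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              trim_M: float, trim_A: float) -> float:
    """TMM factor of one sample against the reference sample."""
    n_obs, n_ref = obs.sum(), ref.sum()
    shared = (obs > 0) & (ref > 0)
    if shared.sum() < 3:
        return np.nan
    o, r = obs[shared], ref[shared]
    p_o, p_r = o / n_obs, r / n_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * (np.log2(p_o) + np.log2(p_r))
    # asymptotic variance of M (delta method, binomial sampling)
    w = 1.0 / (1.0 / o - 1.0 / n_obs + 1.0 / r - 1.0 / n_ref)

    # double trim by rank: inner (1-2*trim_M) of M and (1-2*trim_A) of A
    def keep_core(x, trim):
        lo, hi = np.quantile(x, [trim, 1.0 - trim])
        return (x >= lo) & (x <= hi)

    keep = keep_core(M, trim_M) & keep_core(A, trim_A)
    if not keep.any():
        return np.nan
    return 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))


def size_factors_tmm(Z: np.ndarray, ref_sample: Optional[int] = None,
                     trim_M: float = 0.30, trim_A: float = 0.05) -> SizeFactors:
    """Trimmed-mean-of-M-values factors against an automatically chosen reference.

    The factors capture compositional correction only (they are computed on
    within-sample proportions), so a pure depth change leaves them at 1.
    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper quartile across samples.
    """
    Z = np.asarray(Z, dtype=float)
    totals = Z.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample must have a positive total count")
    uq = np.array([np.quantile(Z[:, i] / totals[i], 0.75)
                   for i in range(Z.shape[1])])
    if ref_sample is None:
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))
    ref = Z[:, ref_sample]

    factors = np.ones(Z.shape[1])
    for i in range(Z.shape[1]):
        if i == ref_sample:
            continue
        f = _tmm_pair(Z[:, i], ref, trim_M, trim_A)
        if np.isnan(f):
            warnings.warn("TMM: fewer than 3 shared positive features; "
                          "falling back to total-count factor")
            f = (totals[i] / totals[ref_sample])
        factors[i] = f
    return SizeFactors(_geomean_one(factors), "tmm")


def size_factors_median_ratio(Z: np.ndarray,
                              controls: Optional[Sequence[int]] = None
                              ) -> SizeFactors:
    """Median-of-ratios factors against a per-feature geometric-mean reference.

    Only features positive in every sample enter the reference; ``controls``
    restricts the reference to a user-supplied index set of putatively stable
    features (the control-feature mitigation).
    """
    Z = np.asarray(Z, dtype=float)
    idx = np.arange(Z.shape[0]) if controls is None else np.asarray(controls)
    sub = Z[idx]
    allpos = np.all(sub > 0, axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature is positive in all samples; filter low-abundance "
            "features (or widen the control set) before normalizing")
    sub = sub[allpos]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return SizeFactors(
        _geomean_one(factors), "median_ratio",
        reference=None if controls is None else idx[allpos])


def size_factors_deconvolution(Z: np.ndarray,
                               condition: Optional[np.ndarray] = None,
                               pool_sizes: Sequence[int] = (21, 26, 31, 36, 41),
                               min_mean: float = 0.1) -> SizeFactors:
    """Pooling-and-deconvolution factors, optionally grouped by condition.

    With ``condition`` given, factors are deconvolved within each condition
    against that condition's own average pseudo-sample (the groups play the
    role of clusters), and the groups are then linked by the median ratio of
    their pseudo-sample profiles.  Grouping keeps widespread between-
    condition change out of the within-group equations.
    """
    Z = np.asarray(Z, dtype=float)
    P, n = Z.shape
    totals = Z.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample must have a positive total count")

    if condition is not None:
        condition = np.asarray(condition)
        groups = np.unique(condition)
        factors = np.empty(n)
        pseudo = {}
        for grp in groups:
            mask = condition == grp
            sub = _deconvolve_one_group(Z[:, mask], pool_sizes, min_mean)
            factors[mask] = sub
            prop = (Z[:, mask] / totals[mask]).mean(axis=1)
            pseudo[grp] = prop
        # link groups: median ratio of pseudo-sample profiles vs first group
        base = pseudo[groups[0]]
        for grp in groups[1:]:
            mask = condition == grp
            both = (pseudo[grp] > 0) & (base > 0)
            if both.sum() >= 1:
                factors[mask] *= np.median(pseudo[grp][both] / base[both])
        factors = factors * totals
        return SizeFactors(_geomean_one(factors), "deconvolution")

    factors = _deconvolve_one_group(Z, pool_sizes, min_mean) * totals
    return SizeFactors(_geomean_one(factors), "deconvolution")


def _deconvolve_one_group(Z: np.ndarray, pool_sizes: Sequence[int],
                          min_mean: float) -> np.ndarray:
    """Proportion-scale deconvolution factors for one group of samples."""
    Z = np.asarray(Z, dtype=float)
    P, n = Z.shape
    totals = Z.sum(axis=0)

    sizes = [s for s in pool_sizes if 2 <= s <= n]
    if not sizes:  # shrink adaptively for small n
        lo = max(2, n // 4)
        hi = max(lo + 1, n - 1)
        sizes = sorted({int(round(s)) for s in np.linspace(lo, hi, 5)})

    # ring order: alternate smallest/largest library sizes for balanced pools
    order = np.argsort(totals)
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2:][::-1]

    scaled = Z / totals  # per-sample proportions
    ref = scaled.mean(axis=1)
    use = Z.mean(axis=1) >= min_mean  # drop near-zero-mean features
    if use.sum() < 1:
        use = ref > 0

    rows, rhs = [], []
    for s in sizes:
        for start in range(n):
            members = ring[(start + np.arange(s)) % n]
            pooled = scaled[use][:, members].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = pooled / ref[use]
            ratio = ratio[np.isfinite(ratio) & (ratio > 0)]
            if ratio.size == 0:
                continue
            row = np.zeros(n)
            row[members] = 1.0
            rows.append(row)
            rhs.append(np.median(ratio))
    # low-weight anchor fixing the overall scale
    anchor = np.full(n, 0.01)
    rows.append(anchor)
    rhs.append(0.01 * n)
    A = np.vstack(rows)
    b = np.asarray(rhs)

    try:
        theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        warnings.warn("deconvolution system singular; "
                      "falling back to median-of-ratios")
        return size_factors_median_ratio(Z).values / totals

    if np.any(theta <= 0):
        bad = theta <= 0
        floor = 0.1 * np.median(theta[~bad]) if (~bad).any() else 1.0
        theta_fixed = np.where(bad, floor, theta)
        # re-solve the positive part with floored factors moved to the RHS
        if (~bad).any():
            b2 = b - A[:, bad] @ theta_fixed[bad]
            sol, *_ = np.linalg.lstsq(A[:, ~bad], b2, rcond=None)
            theta_fixed[~bad] = np.where(sol > 0, sol, theta_fixed[~bad])
        theta = np.where(theta_fixed > 0, theta_fixed, floor)

    return theta  # proportion-scale factor; callers add depth back


def size_factors_bias_correction(Z: np.ndarray, condition: np.ndarray,
                                 trim: float = 0.2, tol: float = 1e-6,
                                 max_iter: int = 100) -> SizeFactors:
    """Sampling-fraction offsets estimated by alternating trimmed means.

    Model: log(Z[p, i] + 0.5) ~ feature-and-condition log mean + per-sample
    offset.  Offsets and log means are alternately re-estimated (the offset
    update is a trimmed mean over features of the residual log counts) until
    the offsets move by less than ``tol``.  The offset's additive
    identifiability is resolved by the geometric-mean-1 convention.
    """
    Z = np.asarray(Z, dtype=float)
    condition = np.asarray(condition)
    groups = np.unique(condition)
    if len(groups) != 2:
        raise ValueError("exactly two condition groups required")
    for grp in groups:
        if (condition == grp).sum() < 2:
            raise ValueError("each condition needs >= 2 samples")

    logz = np.log(Z + PSEUDO)
    n = Z.shape[1]
    offsets = np.zeros(n)
    converged = False
    for _ in range(max_iter):
        # global per-feature log means: the compositional shift between
        # conditions then lands in the residuals, where the trimmed mean
        # recovers it as long as most features are stable
        mu = np.mean(logz - offsets[None, :], axis=1)
        resid = logz - mu[:, None]
        new = scipy_stats.trim_mean(resid, trim, axis=0)
        new -= new.mean()  # additive identifiability
        if np.max(np.abs(new - offsets)) < tol:
            offsets = new
            converged = True
            break
        offsets = 0.5 * (offsets + new)  # damped update; the raw
        # alternation can cycle between trim assignments
    if not converged:
        warnings.warn("bias-correction offsets did not converge; "
                      "returning last iterate")
    return SizeFactors(_geomean_one(np.exp(offsets)), "bias_correction",
                       converged=converged)


STRATEGIES = {
    "total": size_factors_total,
    "tmm": size_factors_tmm,
    "median_ratio": size_factors_median_ratio,
    "deconvolution": size_factors_deconvolution,
    "bias_correction": size_factors_bias_correction,
}
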