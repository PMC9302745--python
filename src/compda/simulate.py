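"""Paired absolute/relative count simulator for differential-abundance benchmarking.

Generates two-condition count data in paired form: an "absolute" matrix ``Y``
whose column totals carry real scale information, and an "observed" matrix
``Z`` obtained by multinomial resampling of every sample to one fixed depth,
which deliberately destroys that scale information.  The generative chain is

1. baseline log mean abundances  theta1_p ~ Normal(m, S^2),
2. a feature correlation matrix  Omega ~ InverseWishart(df, Q), rescaled to
   unit diagonal,
3. correlated perturbed log means  theta2 ~ MVN(theta1, a * Omega),
4. a Bernoulli(c) subset of features takes the perturbed mean in condition 2
   (mu2 = exp(theta2)); all others keep mu1 = exp(theta1),
5. replicate counts  y_ip ~ NegBinomial(mean = mu_p * delta_i, size = d_abs)
   with a per-sample scale multiplier delta_i = max(0.1, Normal(1, g)),
6. one common observed depth  u ~ Uniform(depth_lo, depth_hi) and
   z_i ~ Multinomial(u, y_i / sum(y_i)) for every sample.

The negative binomial is parameterized by mean and size, variance
mu + mu^2/size; at the default size 1000 counts are barely overdispersed
relative to a Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import linalg
from scipy.linalg import lapack


@dataclass(frozen=True)
class CorrelationSpec:
    """Specification of the inverse-Wishart scale matrix for feature correlation.

    kind
        ``"identity"`` for independent features or ``"dense-positive"`` for a
        block of positively correlated features.
    df
        Inverse-Wishart degrees of freedom; must exceed P + 1.  ``None``
        defaults to ``P + 101``, which concentrates the draw around the scale
        matrix's correlation structure while leaving sampling variability.
    strength
        Off-diagonal value inside the correlated block (dense-positive only).
    frac_correlated
        Fraction of features in the correlated block, in [0, 0.5].
    """

    kind: str = "identity"
    df: Optional[int] = None
    strength: float = 0.0
    frac_correlated: float = 0.0

    def __post_init__(self):
        if self.kind not in ("identity", "dense-positive"):
            raise ValueError(f"unknown correlation kind {self.kind!r}")
        if not (0.0 <= self.frac_correlated <= 0.5):
            raise ValueError("frac_correlated must lie in [0, 0.5]")
        if not (0.0 <= self.strength < 1.0):
            raise ValueError("strength must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative hyperparameters of one simulated data set."""

    P: int
    m: float
    S: float
    corr: CorrelationSpec = field(default_factory=CorrelationSpec)
    a: float = 0.0
    c: float = 0.0
    g: float = 0.0
    R: int = 10
    d_abs: float = 1000.0
    depth_lo: float = 5_000.0
    depth_hi: float = 2_000_000.0
    seed: int = 0

    def __post_init__(self):
        if self.P < 2:
            raise ValueError("P must be >= 2")
        if not np.isfinite(self.m):
            raise ValueError("m must be finite")
        if self.S < 0:
            raise ValueError("S must be >= 0")
        if self.a < 0:
            raise ValueError("a must be >= 0")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("c must lie in [0, 1]")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.R < 2:
            raise ValueError("R must be >= 2")
        if self.d_abs <= 0:
            raise ValueError("d_abs must be > 0")
        if self.depth_lo > self.depth_hi:
            raise ValueError("depth_lo must be <= depth_hi")


@dataclass
class PairedCountData:
    """Absolute counts, their fixed-depth resample, and the generative truth."""

    Y: np.ndarray          # (P, 2R) absolute counts
    Z: np.ndarray          # (P, 2R) observed counts, fixed column totals
    condition: np.ndarray  # (2R,) labels 1 or 2
    truth: np.ndarray      # (P,) boolean differential flags
    mu1: np.ndarray        # (P,) condition-1 means
    mu2: np.ndarray        # (P,) condition-2 means
    depth: np.ndarray      # (2R,) realized observed totals (all equal)
    delta: Optional[np.ndarray] = None  # (2R,) per-sample scale multipliers

    @property
    def n_features(self) -> int:
        return self.Y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[1]


def draw_baseline_log_means(P: int, m: float, S: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw P i.i.d. Normal(m, S^2) baseline log mean abundances."""
    if P < 1:
        raise ValueError("P must be >= 1")
    if not np.isfinite(m):
        raise ValueError("m must be finite")
    if S < 0:
        raise ValueError("S must be >= 0")
    return rng.normal(m, S, size=P)


def _scale_matrix(P: int, corr: CorrelationSpec) -> np.ndarray:
    if corr.kind == "identity":
        return np.eye(P)
    k = int(round(corr.frac_correlated * P))
    Q = np.eye(P)
    if k >= 2:
        block = np.full((k, k), corr.strength)
        np.fill_diagonal(block, 1.0)
        Q[:k, :k] = block
    return Q


def build_correlation(P: int, corr: CorrelationSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw Omega ~ InverseWishart(df, Q) and rescale to a correlation matrix.

    The draw uses the Bartlett decomposition: with F F' = Q^{-1} and A a
    lower-triangular Bartlett factor, W = (F A)(F A)' ~ Wishart(df, Q^{-1})
    and Omega = W^{-1}.  Only O(P^3) triangular algebra is needed, which keeps
    large-P draws affordable.
    """
    df = corr.df if corr.df is not None else P + 101
    if df <= P + 1:
        raise ValueError(f"inverse-Wishart df must exceed P + 1 = {P + 1}")
    Q = _scale_matrix(P, corr)
    try:
        Lq = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded presets
        raise ValueError("scale matrix Q is not positive definite") from exc

    # Bartlett factor of Wishart(df, I)
    A = np.zeros((P, P))
    tril = np.tril_indices(P, k=-1)
    A[tril] = rng.standard_normal(len(tril[0]))
    A[np.diag_indices(P)] = np.sqrt(rng.chisquare(df - np.arange(P)))

    # F with F F' = Q^{-1}: F = inv(Lq)'  (since Q^{-1} = Lq^{-T} Lq^{-1})
    F = linalg.solve_triangular(Lq, np.eye(P), lower=True).T
    B = F @ A                       # W = B B'
    C = np.linalg.inv(B)            # Omega = W^{-1} = C' C
    omega = C.T @ C
    d = np.sqrt(np.diag(omega))
    omega /= np.outer(d, d)
    np.fill_diagonal(omega, 1.0)
    return omega


def _cs_sqrt_coeffs(k: int, rho: float):
    """Coefficients (a, b) with (a*I + b*11') being the symmetric square root
    of the compound-symmetry matrix (1-rho)*I + rho*11' of size k."""
    s1 = np.sqrt(1.0 - rho)
    s2 = np.sqrt(1.0 - rho + k * rho)
    return s1, (s2 - s1) / k


def draw_correlated_perturbation(theta1: np.ndarray, corr: CorrelationSpec,
                                 a: float, rng: np.random.Generator
                                 ) -> np.ndarray:
    """One MVN(theta1, a * Omega) draw with Omega an inverse-Wishart
    correlation matrix, without materializing Omega.

    Same distribution as ``build_correlation`` followed by
    ``perturb_log_means``, but restructured for large P.  With the Bartlett
    factor A of Wishart(df, I) and F the symmetric square root of Q^{-1}
    (closed form for the compound-symmetry block presets), Omega = C'C for
    C = A^{-1} F^{-1}; the draw needs one triangular inversion plus O(P^2)
    products, so P = 5000 stays affordable.
    """
    P = theta1.size
    df = corr.df if corr.df is not None else P + 101
    if df <= P + 1:
        raise ValueError(f"inverse-Wishart df must exceed P + 1 = {P + 1}")
    if a < 0:
        raise ValueError("a must be >= 0")
    if a == 0:
        return theta1.copy()
    k = (int(round(corr.frac_correlated * P))
         if corr.kind == "dense-positive" else 0)
    if k < 2:
        k = 0

    A = np.zeros((P, P))
    tril = np.tril_indices(P, k=-1)
    A[tril] = rng.standard_normal(len(tril[0]))
    A[np.diag_indices(P)] = np.sqrt(rng.chisquare(df - np.arange(P)))
    M, info = lapack.dtrtri(A, lower=1)
    if info != 0:  # pragma: no cover - chi-square diagonal is positive
        raise np.linalg.LinAlgError("Bartlett factor inversion failed")
    del A

    col_norms2 = np.einsum("ij,ij->j", M, M)
    w = rng.standard_normal(P)
    u = M.T @ w
    if k:
        # F^{-1} = Q^{1/2}: compound-symmetry square root on the block
        ap, bp = _cs_sqrt_coeffs(k, corr.strength)
        s = M[:, :k].sum(axis=1)               # M @ 1_block
        dots = M.T @ s                          # m_i' s for every column
        d = col_norms2.copy()
        d[:k] = (ap * ap * col_norms2[:k] + 2 * ap * bp * dots[:k]
                 + bp * bp * (s @ s))
        v = u.copy()
        v[:k] = ap * u[:k] + bp * u[:k].sum()
    else:
        d = col_norms2
        v = u
    return theta1 + np.sqrt(a) * v / np.sqrt(d)


def perturb_log_means(theta1: np.ndarray, omega: np.ndarray, a: float,
                      rng: np.random.Generator) -> np.ndarray:
    """One MVN(theta1, a * Omega) draw of perturbed log means."""
    theta1 = np.asarray(theta1, dtype=float)
    if omega.shape != (theta1.size, theta1.size):
        raise ValueError("Omega dimension does not match theta1")
    if a < 0:
        raise ValueError("a must be >= 0")
    if a == 0:
        return theta1.copy()
    L = np.linalg.cholesky(omega)
    return theta1 + np.sqrt(a) * (L @ rng.standard_normal(theta1.size))


def select_differential(theta1: np.ndarray, theta2: np.ndarray, c: float,
                        rng: np.random.Generator):
    """Bernoulli(c) selection of differential features and their mean vectors.

    Returns ``(truth, mu1, mu2)`` with mu1 = exp(theta1) everywhere and
    mu2 = exp(theta2) only where truth holds (exp(theta1) otherwise).
    """
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.shape != theta2.shape:
        raise ValueError("theta1 and theta2 must have the same shape")
    if not (0.0 <= c <= 1.0):
        raise ValueError("c must lie in [0, 1]")
    truth = rng.random(theta1.size) < c
    mu1 = np.exp(theta1)
    mu2 = np.where(truth, np.exp(theta2), mu1)
    return truth, mu1, mu2


def draw_sample_multiplier(g: float, rng: np.random.Generator) -> float:
    """One per-sample scale multiplier delta = max(0.1, Normal(1, g))."""
    if g < 0:
        raise ValueError("g must be >= 0")
    return max(0.1, rng.normal(1.0, g))


def draw_absolute_counts(mu: np.ndarray, delta: float, d_abs: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Independent NB(mean = mu * delta, size = d_abs) draws for one sample."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    if d_abs <= 0:
        raise ValueError("d_abs must be > 0")
    mean = mu * delta
    p = d_abs / (d_abs + mean)
    return rng.negative_binomial(d_abs, p)


def draw_observed_depth(depth_lo: float, depth_hi: float,
                        rng: np.random.Generator) -> int:
    """One integer-rounded Uniform(depth_lo, depth_hi) observed depth."""
    if depth_lo > depth_hi:
        raise ValueError("depth_lo must be <= depth_hi")
    return int(round(rng.uniform(depth_lo, depth_hi)))


def multinomial_resample(y: np.ndarray, u: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Multinomial(u, y / sum(y)) resample of one sample's counts."""
    y = np.asarray(y, dtype=float)
    total = y.sum()
    if total <= 0:
        raise ValueError("cannot resample an all-zero sample")
    if u < 1:
        raise ValueError("depth u must be >= 1")
    return rng.multinomial(int(u), y / total)


def simulate_dataset(config: SimulationConfig) -> PairedCountData:
    """Run the full generative chain for one configuration.

    The root seed is split hierarchically (one child stream per stage) so
    that the data set is reproducible bit-for-bit and sub-stage draws do not
    interact.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ("baseline", "correlation", "perturb", "truth",
            "multiplier", "counts", "depth", "resample")
    rngs = {k: np.random.Generator(np.random.PCG64(s))
            for k, s in zip(keys, ss.spawn(len(keys)))}

    theta1 = draw_baseline_log_means(config.P, config.m, config.S,
                                     rngs["baseline"])
    theta2 = draw_correlated_perturbation(theta1, config.corr, config.a,
                                          rngs["perturb"])
    truth, mu1, mu2 = select_differential(theta1, theta2, config.c,
                                          rngs["truth"])

    n = 2 * config.R
    condition = np.repeat([1, 2], config.R)
    delta = np.array([draw_sample_multiplier(config.g, rngs["multiplier"])
                      for _ in range(n)])
    Y = np.empty((config.P, n), dtype=np.int64)
    for i in range(n):
        mu = mu1 if condition[i] == 1 else mu2
        Y[:, i] = draw_absolute_counts(mu, delta[i], config.d_abs,
                                       rngs["counts"])

    u = draw_observed_depth(config.depth_lo, config.depth_hi, rngs["depth"])
    Z = np.empty_like(Y)
    for i in range(n):
        Z[:, i] = multinomial_resample(Y[:, i], u, rngs["resample"])

    return PairedCountData(
        Y=Y, Z=Z, condition=condition, truth=truth, mu1=mu1, mu2=mu2,
        depth=Z.sum(axis=0), delta=delta,
    )


def filter_low_abundance(Y: np.ndarray, Z: np.ndarray,
                         truth: Optional[np.ndarray] = None,
                         min_mean: float = 1.0):
    """Keep features whose mean count is >= min_mean in BOTH matrices.

    The boundary is inclusive: a feature averaging exactly ``min_mean`` in
    both tables is retained.  Returns ``(Y_f, Z_f, keep)`` or
    ``(Y_f, Z_f, truth_f, keep)`` when a truth vector is supplied.
    """
    Y = np.asarray(Y)
    Z = np.asarray(Z)
    if Y.shape[0] != Z.shape[0]:
        raise ValueError("Y and Z must share the feature dimension")
    keep = (Y.mean(axis=1) >= min_mean) & (Z.mean(axis=1) >= min_mean)
    if not keep.any():
        raise ValueError("low-abundance filter removed every feature")
    if truth is not None:
        return Y[keep], Z[keep], np.asarray(truth)[keep], keep
    return Y[keep], Z[keep], keep


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a new seed (grid plumbing convenience)."""
    return replace(config, seed=seed)
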