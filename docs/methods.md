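# Methods

`compda` quantifies how consistently differential-abundance (DA) calls made
on *relative* sequence counts — after per-sample rescaling — recover DA calls
made on *absolute* counts. All data are simulated, so the absolute
counts are known and the loss of scale information can be induced exactly.

## Generative model

For each data set, `P` features in two conditions with `R = 10` replicates
per condition:

1. Baseline log mean abundances `theta1_p ~ Normal(m, S^2)`.
2. A feature correlation matrix `Omega ~ InverseWishart(df, Q)`, rescaled
   to unit diagonal. `Q` is either the identity (independent features) or a
   compound-symmetry block covering a fraction of the features with a
   common positive off-diagonal (correlated perturbations).
3. Perturbed log means `theta2 ~ MVN(theta1, a * Omega)`; `a` tunes the
   perturbation variance.
4. Each feature is differential with probability `c`; for those features
   `mu2 = exp(theta2)`, otherwise `mu2 = mu1 = exp(theta1)`.
5. Absolute counts `y_ip ~ NegBinomial(mean = mu_p * delta_i, size = 1000)`
   (variance `mu + mu^2/1000` — barely overdispersed relative to Poisson),
   with per-sample scale noise `delta_i = max(0.1, Normal(1, g))`; `g` is a
   standard deviation.
6. One observed depth `u ~ Uniform(5000, 2 * 10^6)` shared by all samples
   of the data set, and `z_i ~ Multinomial(u, y_i / sum(y_i))`.

Step 6 is the crux: resampling every sample to the same depth destroys all
between-sample and between-condition information about total abundance, so
`Z` is compositional where `Y` is not. The per-sample multiplier `delta`
also cancels in the proportions, so replicate-level scale noise affects the
absolute table only.

Numerical notes. The MVN draw in step 3 never materializes `Omega` for
large `P`: with the Bartlett factor `A` of a `Wishart(df, I)` draw and the
closed-form symmetric square root of the compound-symmetry block of
`Q^{-1}`, `Omega = C'C` for `C = A^{-1} F^{-1}`, so a draw plus the exact
unit-diagonal rescaling needs one triangular inversion and a few `O(P^2)`
products (a `P = 5000` draw takes seconds). `build_correlation` exposes
the explicit matrix route; a test checks the two routes agree in
distribution. Default `df = P + 101` keeps the draw concentrated around
`Q`'s correlation structure while leaving visible sampling variability.
One root seed is split hierarchically per data set and per stage, so any
grid cell reproduces bit-for-bit in isolation.

## Grid levels

The full grid crosses `P ∈ {100, 1000, 5000}`, `c ∈ {0.2, 0.3, 0.5, 0.7,
0.9}`, five correlation presets (identity up to a 50% block at strength
0.9), five perturbation levels, three replicate-noise levels
`g ∈ {0.05, 0.2, 0.4}`, and five paired baseline levels
`(m, S) ∈ {(2.5, 0.75) … (6.5, 2.75)}` — 5625 cells. The perturbation
variance is specified as a proportion of the baseline log mean,
`a = f * m` with `f ∈ {0.1, 0.2, 0.4, 0.7, 1.0}`.

The numeric level values are this package's calibration choice. They were
chosen once so that realized data span the intended ranges of observed-data
characteristics — percent zeros from near 0 to above 80%, total-abundance
fold changes from ~1 up to more than ten-fold with both signs, and realized
*detectable* differential abundance well below the parameterized `c`
(many perturbations are small relative to replicate noise) — and were not
revisited afterwards.

Study-setting labels are assigned from grid levels: *Microbial* (`P ≤ 1000`
at the top perturbation level), *Bulk Transcriptomic* (`P = 5000` at the
two lowest levels), *Cell Transcriptomic* (`P ≥ 1000` at middle levels);
labels may overlap and many cells carry none.

The desk-scale preset used by the analysis drivers, tests and
`scripts/acceptance.py` is a uniform 300-cell subsample of the full
product (seeded, without replacement), keeping every level of every
hyperparameter represented in proportion. 300 cells keeps a complete run
in the minutes range on one CPU while leaving the pooled medians stable to
roughly ±0.02–0.04; grid-level summaries quoted from this preset carry
Monte-Carlo error of that order.

## Differential-abundance testing

One negative-binomial GLM engine serves all count-based methods: per
feature, counts are regressed on the two-level condition factor with a log
link and per-sample `log(size factor)` offsets. Because the model is
saturated, group means have closed-form (weighted) updates; per-feature
dispersion is estimated by Cox-Reid adjusted profile likelihood on a
log-spaced grid with parabolic refinement (floor `1e-8`), and the condition
coefficient is tested by a Wald statistic. All-zero features report
`p = 1`; a group with all-zero counts enters as half a count (flagged);
non-converged mean fits fall back to a Poisson fit (flagged). The engine
run on the absolute counts with unit size factors is the study's "oracle" —
its calls define true DA for scoring. Unit factors are deliberate: in
absolute counts the totals are signal, not nuisance.

The five published-package analogs differ only in how the observed counts
are rescaled — the operative difference between the tools they represent:

| analog | size factors |
|---|---|
| `total_glm` | column totals (library size; on fixed-depth data, no-op) |
| `tmm_glm` | trimmed mean of M-values × library size (edgeR-style) |
| `median_ratio_glm` | median-of-ratios vs geometric-mean reference (DESeq2-style), optional control features |
| `deconvolution_glm` | pooling/deconvolution within condition, groups linked by median ratio of pseudo-samples (scran-style) |
| `bias_correction_glm` | sampling-fraction log offsets by alternating trimmed means (ANCOM-BC-style) |
| `clr_mc` | none — CLR Dirichlet Monte-Carlo test (ALDEx2-style) |

All factor vectors are normalized to geometric mean 1 (any global constant
cancels in two-group testing). The TMM factor itself is depth-relative
(computed on within-sample proportions); the GLM offset composes it with
the library size, which coincides on fixed-depth data. The ANCOM-BC analog
is deliberately simplified: per-sample offsets are the trimmed mean (20%
per tail) of residual log counts around *global* per-feature log means,
alternated to convergence (tol `1e-6`, damped). Using global rather than
per-condition feature means is essential — with per-condition means the
between-condition component of the offset is unidentifiable and the method
degenerates to no rescaling; with global means the trimmed mean recovers
the compositional shift whenever most features are stable, which is the
assumption the original method also leans on. The scran analog groups by
condition (the spec of the original uses clusters; conditions play that
role here) so that widespread between-condition change stays out of the
within-group pooling equations.

`clr_mc` draws, per Monte-Carlo instance, per-sample proportions from
`Dirichlet(counts + 0.5)`, CLR-transforms them, applies Welch's t-test per
feature, adjusts within the instance by Benjamini-Hochberg, and averages
the adjusted values over 128 instances (the reported `q`); the effect is
the median across instances of the CLR group-mean difference in log2 units.

Calls use `q ≤ FDR` and `|log2FC| ≥` threshold: the lenient policy is
(0.05, 0), the stringent mitigation policy (0.01, 1), applied identically
to oracle and observed-data calls.

## Scoring and signatures

Observed-data calls are scored against oracle calls as TP/FP/TN/FN;
sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`. A cell with no oracle
positives has undefined sensitivity; it is recorded as missing and excluded
from medians. Aggregation reports per-group medians and the share of cells
below 95% and 50% specificity.

Each observed table is summarized by a 51-feature signature registry
(`compda.signatures`): sparsity (zero- and one-count fractions, per
condition and pooled), evenness and dominance of the mean composition,
per-condition log-abundance quantiles, the shape of the pairwise CLR
feature-correlation distribution (on a seeded subsample of ≤ 500 features;
skewness is the adjusted Fisher-Pearson statistic), and the spread and
prevalence of apparent feature-level change. "Large" fold changes are
departures of at least 1 log2 unit from the mean per-feature change — the
mean-centering matters because fixed-depth data pushes a common shift into
every feature when totals change. `total_fc` is identically 1 on simulated
observed data and is retained for user-supplied tables.

## Accuracy meta-models

Per method and per target (sensitivity, specificity), a random-forest
regressor maps signatures to accuracy: 500 trees, full greedy feature
search (`max_features = 1.0`, sklearn's regression default — with only ~50
features, per-split feature subsampling dilutes the search enough to fail
the basic leakage sanity check of learning a duplicated target), seeded
80/20 train/holdout split, R² on the holdout. Importances are gain-style
(total impurity decrease, normalized to sum 1). Predictive intervals are
per-tree quantiles (25/75 and 5/95, clipped to [0, 1]); they quantify
ensemble spread, not calibrated coverage, though empirical 50%-band
coverage on held-out synthetic data sits in the 30–70% range.

## What the simulation does and does not emulate

The generator reproduces the features that matter for compositional
distortion: correlated log-normal abundances, heavy-tailed perturbations
affecting a tunable share of features, near-Poisson counting noise,
replicate-level scale noise, and exact fixed-depth resampling. It does not
model sequencing error, PCR or GC bias, batch effects, UMIs, or
zero-inflation. Passing tests therefore show that the *rescaling logic* of
each method behaves as described under a clean compositional mechanism;
they do not certify behavior on real data, where normalization errors
interact with technical artifacts the simulator omits. The analogs
re-implement each method's core estimator, not the full published
packages (no empirical-Bayes dispersion shrinkage, independent filtering,
or outlier handling), so absolute accuracy numbers can differ from the
original tools by a few hundredths.

## Degenerate inputs and tie-breaks

Zero-total samples are rejected everywhere. TMM falls back to the
total-count factor when fewer than three features are positive in both
sample and reference. Median-of-ratios requires at least one feature
positive in all samples and advises filtering otherwise. Deconvolution
pool sizes shrink adaptively when there are fewer samples than the default
pool sizes; non-positive least-squares solutions are floored at 10% of the
median positive solution and the rest re-solved once. The low-abundance
filter keeps features with mean count ≥ 1 in *both* tables, boundary
inclusive.
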