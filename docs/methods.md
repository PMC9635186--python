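# Methods

## Problem

Quantitative structure–retention relationship (QSRR) modeling links numeric
molecular descriptors of analytes to their reversed-phase HPLC retention
factors `k = (t_R − t_0)/t_0` (dimensionless; `t_0` is the column dead time).
The package implements one specific local-model workflow for small antibiotic
panels — quinolone major microspecies across mobile-phase pH, and
sulfonamides across acetonitrile percentage:

1. variance-filter the descriptor fund (drop all-zero and constant columns);
2. screen for nonlinearity (APARP + Durbin–Watson) to justify a kernel model;
3. select descriptors with a binary firefly-algorithm (FFA) wrapper whose
   fitness is the cross-validated RMSE of an ε-SVR model;
4. fit the final RBF ε-SVR on the selected subset;
5. validate internally (LOO or leave-10%-out CV), externally (held-out test
   set), by Y-randomization (cRp²), and delimit the applicability domain
   (Williams plot, Hotelling T²).

The retention factors, train/test memberships and model predictions of the
two original studies are packaged as fixtures; their descriptor matrices
(MOE molecular mechanical descriptors) are proprietary and unpublished, so
end-to-end runs use the synthetic generator instead, and the published model
statistics are reproduced from the prediction tables in validation-only mode.

## Models and statistics

**ε-SVR.** The regression function is `f(x) = Σᵢ aᵢ K(sᵢ, x) + b` from the
standard ε-insensitive dual (residuals inside the ε-tube carry no loss; `C`
bounds each |dual coefficient|). Defaults mirror the study setup: RBF kernel
`K(u,v) = exp(−γ‖u−v‖²)`, `C = 1`, `ε = 0.01`. The kernel width the original
models used is not recoverable; the default is `γ = 1/p_selected` ("auto"),
exposed in `SVRConfig`. Descriptors are z-scored with training statistics
(train-fold statistics inside CV); raw descriptor scales differ by orders of
magnitude, which would otherwise dominate RBF distances. Zero-variance
columns inside a fold pass through unscaled rather than erroring. The dual is
solved by scikit-learn's libsvm binding (stopping tolerance 1e−6, below the
3-decimal data precision); prediction is an explicit kernel expansion over
stored support vectors, so models serialize to JSON and reload exactly.
Polynomial and sigmoid kernels are implemented but non-default.

**Firefly wrapper.** Fireflies live in `[0,1]^p`; a mask is decoded by
thresholding coordinates at 0.5 (deterministic, so the fitness landscape is
not artificially noisy), forcing the top coordinate on when a mask would be
empty, and keeping only the top-`max_descriptors` coordinates when a cap is
set. Movement toward each brighter firefly (lower RMSE_CV; ties to the lower
index) uses the canonical attractiveness `β(r) = β₀ e^(−γ_abs r²)` on the
Euclidean distance between continuous positions, plus `α·(u − ½)` uniform
randomization, clipped back to the unit box. The incumbent best firefly takes
only its randomization step, and the best mask ever evaluated is tracked
separately (elitism), making the best-fitness trace monotone. Fitness values
are cached by mask bit-pattern — the CV×SVR evaluation dominates cost, and on
converged swarms ~90% of evaluations are cache hits. Degenerate masks get
+∞ fitness rather than raising. Tuned profiles: 10 fireflies / 100
generations / α 0.10 (quinolone-sized) and 20 / 100 / α 0.15
(sulfonamide-sized), both with β₀ = 1, γ_abs = 0.01.

When `p` rivals `n_train` the pipeline (not the selector) imposes
`max_descriptors = n_train // 3`: the 0.5-threshold decode starts at ~p/2
bits, and without a cap the swarm cannot reach subsets small enough for the
hat-matrix applicability domain (which needs `n_train > p_selected + 1`).
The cap is consistent with the published model sizes (5 of 293 descriptors
at n=16; 2+1 of 113 at n=30).

**Validation metrics.** R² (calibration and prediction) and q² (CV) are
*squared Pearson correlations* between observed and predicted values; RMSE is
the root mean squared residual; ρ is Spearman's rank correlation (average
ranks on ties) measuring elution-order fidelity. The squared-Pearson
convention is pinned by recomputation: on the packaged quinolone CV column it
gives 0.808 as published, while `1 − PRESS/SS_tot` gives ≈0.715 and is
thereby excluded. Residual convention: `residual = predicted − experimental`
(verified against every packaged residual column at ±0.0015). Adjusted R²
uses the standard `1 − (1−R²)(n−1)/(n−p−1)`; note the published adjusted
values (0.926 at n=16, p=5; 0.896 at n=30, p=3) do not follow this formula
(which gives 0.897 / 0.888) and their derivation is unknown, so adjusted R²
is reported but never asserted against the published numbers.

Two further published values fail recomputation from the printed tables and
are documented rather than patched: the quinolone calibration ρ (printed
0.976; the 3-decimal table yields 0.994 — a rank-sum of 16 would be required
and the printed ranks give 4, so the original value must come from
full-precision predictions ordering the near-tied k ≈ 1.55–1.62 cluster
differently), and the sulfonamide no-outlier claim (see below). Metrics are
kept at full precision internally and rounded to 3 decimals only at
serialization; note that statistics recomputed from 3-dp tables can round
differently from the originals (0.8088 → "0.809" vs the published 0.808).

**Cross-validation.** LOO has exactly `n_train` folds. Leave-10%-out makes
one seeded random partition into disjoint folds of `⌈0.10·n⌉` (10 folds of 3
at n=30), covering each observation once; `n_repeats` is exposed for
sensitivity but defaults to 1 (the packaged CV columns contain one prediction
per observation). Standardization is recomputed inside each fold.

**Y-randomization.** Training responses are permuted (descriptors fixed) and
the protocol rerun; with `R²` the original statistic and `R_y²` the mean over
scrambled models, `cRp² = √R² · √(R² − R_y²)`, undefined (NaN + flag) when
the margin is negative. Both calibration-based and CV-based versions are
reported; the CV-based one is decisive since kernel models can memorize
scrambled training sets. Full-protocol mode (rerun selection each iteration)
is the default up to 20 iterations; above that a fixed-mask reduced-cost mode
is used and labeled in the report. Per-iteration seeds derive from the master
seed by counter.

**Applicability domain.** Leverage `h(x) = x̃ᵀ(X̃ᵀX̃)⁻¹x̃` on the
intercept-augmented, training-standardized selected descriptors (training
leverages are the hat diagonal, summing to p+1); warning threshold
`h* = 3(p+1)/n_train`, which reproduces both published thresholds exactly
(1.125 = 3·6/16, 0.4 = 3·4/30) and is the formula's validation.
Standardized residuals are `residual / SD(residuals)` (sample SD); the
Williams plot uses CV residuals for training rows and prediction residuals
for test rows, standardized jointly, with in-domain ⇔ `h ≤ h*` and `|z| ≤ 3`.
Test-point leverages use the training-only hat matrix. Hotelling
`T²(x) = (x−x̄)ᵀS⁻¹(x−x̄)` with critical value `p(n−1)/(n−p)·F(1−α; p, n−p)`.
On the packaged tables the quinolone residuals all sit within ±3 SD, but the
sulfonamide tables reach |z| ≈ 3.9–4.0 (the 30%-acetonitrile rows of
sulfachloropyrazine Na and sulfaclozine) under every standardization variant
tried, so the published claim that no compound falls outside ±3 SD is not
supported by the printed residuals; the package reports what it computes.

**Linearity screen.** For each screened descriptor the residuals of a
least-squares *linear* fit are ordered by that descriptor's value and tested
with `DW = Σ(eᵢ−eᵢ₋₁)²/Σeᵢ²` ∈ [0,4]; unmodeled curvature appears as
positive serial correlation (lower tail). The APARP series
`e + b_j x_j + c x_j²` from the quadratic-augmented fit is attached for
plotting. Which residual ordering the original screen used is unstated; the
linear-fit choice is the one that keeps the test calibrated under a true
linear model. P-values use the normal approximation with design-dependent
null moments (`E[d] = tr(MA)/(n−k)`); adequate at these n, where the exact
Imhof computation would change little. The verdict aggregates per-descriptor
tests by minimum Bonferroni-adjusted p at α = 0.05. When the multivariate
fit is infeasible (p ≥ n−2) each descriptor is screened univariately.

## Synthetic generator

The generator emulates the statistical shape of a descriptor-fund problem:
standard-normal descriptors in correlated blocks (one shared factor per
block; within-block correlation `block_correlation`, default block size 10),
a small planted informative set, and a smooth response. The default link is
an RBF mixture over the informative sub-vector (3 centers drawn from data
rows, ℓ = median pairwise distance) — chosen because the workflow's premise
is smoothly nonlinear retention surfaces, and because it makes
descriptor-recovery tests informative for an RBF-SVR learner without
guaranteeing success. Auto-drawn mixtures are affinely rescaled to a
retention-factor-like scale (mean 1.2, SD 0.5, matching the packaged k
tables), so `noise_sd` (default 0.05) is ~10% of the signal SD in k units;
explicitly supplied centers/weights are used raw. A linear link is available
for calibration tests. The optional mobile-phase covariate takes the three
acetonitrile levels {30, 45, 50}% scaled to [0,1] with a monotone decreasing
effect (−0.6 in k units over the range), mimicking faster elution at higher
organic modifier. Study-sized profiles: quinolone-like (n=21, p=293, 5
informative, 16/5 split) and sulfonamide-like (n=39, p=112+covariate, 2
informative + covariate, 30/9 split). Train/test splits stratify by response
quantile (one test draw per stratum), emulating equal retention-distribution
balance. Everything is deterministic given the seed.

What the generator does *not* emulate: real descriptor distributions (MOE
descriptors are heavy-tailed, discrete, and block-correlated by descriptor
family, not by adjacency), pH-dependent ionization equilibria, and
measurement error structure in `t_R`. Passing recovery benchmarks therefore
show the machinery works on data with the assumed structure, not that the
original chemical conclusions transfer.

## Benchmark conditions and problem sizes

Chosen once as desk-scale study conditions: planted-recovery benchmark
n=40, p=20, 3 informative, noise SD 0.05, 10 seeds, leave-10%-out fitness
(4-point folds; LOO would quadruple the fit count without changing the
question); Y-randomization signal case 20 full-protocol iterations on
n=40/p=12/3-informative, null case 10 seeds × 10 fixed-mask iterations on
descriptor-independent responses; DW calibration 1000 series of n=200, power
and calibration of the screen 50 seeds each at n=60/p=5. The published-table
recomputation is exact arithmetic on the packaged fixtures and asserted at
±0.0015 (one unit in the last printed decimal, since the inputs themselves
are 3-dp rounded).

## Known limitations

* The original models cannot be refit: descriptor matrices and the RBF width
  are unpublished. All published-number checks go through the prediction
  tables.
* The leave-10%-out partition is one seeded random split, not the (unstated)
  original one, so CV numbers on new data are seed-dependent; `n_repeats`
  averages partitions if desired.
* The DW p-value is a normal approximation; at n ≲ 20 its tail accuracy
  degrades (the screen requires n ≥ 6 and is meant for n in the tens).
* The cRp² calibration-based variant is lenient for kernel models; use the
  CV-based value.
* FFA selection is stochastic; only seed-fixed runs are reproducible, and the
  monotone best-fitness guarantee says nothing about global optimality.
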