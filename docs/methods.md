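# Methods

## Problem

In ultrahigh-dimensional binary-outcome studies (expression arrays with
10^5–10^6 probes and a few hundred samples), variable selection is done in
two stages: a *screen* that cuts the dimension to a workable size, then a
*model-building* step that picks the final sparse model. Screening by simply
keeping the K variables with the smallest marginal p-values ("random
filtering", RF_K) retains many spurious variables; downstream selection then
reports models in which a large fraction of the chosen variables are false.
This package implements and evaluates the alternative: screen with the
Benjamini–Hochberg (BH) step-up procedure at a chosen false-discovery-rate
level q, refine the screened set with iterative sure independence screening
(ISIS), and build the final model with penalized logistic regression (LASSO,
SCAD or MCP) tuned by 10-fold cross-validation. The claim under test is that
the realized false discovery proportion (FDP) of the *final* model stays at
or below q, at a modest cost in power, while RF screening inflates it badly.

## Components

### Marginal screening statistics

For each variable j we fit the two-parameter logistic model
logit P(y=1|x_j) = a + b x_j by Newton iterations, run simultaneously for
all P variables as vectorised array operations. The p-value is the
likelihood-ratio test against the intercept-only model (chi-square, 1 df);
Wald p-values are available via `statistic="wald"`. The LRT is used because
the ISIS ranking is also likelihood-based, so one computation serves both
screens. Coefficients are clamped at ±30: a marginally separating variable
has fitted probabilities within 10⁻¹³ of 0/1 at that magnitude, so the
clamp changes nothing numerically while preventing divergence. A constant
column gets p = 1.

### BH step-up selection

With ordered p-values p_(1) ≤ … ≤ p_(m), the cutoff rank is
k̂ = max{k : p_(k) ≤ k·q/m} and the k̂ smallest p-values are selected
(nothing when k̂ = 0). Bit-identical ties are broken by ascending variable
index so results are machine-independent. Selection is by value but
reported by original index, so it is invariant to input order. BH-adjusted
p-values are taken from `statsmodels.stats.multitest`. A `strict_gt1` flag
reproduces a stricter variant that rejects only when k̂ > 1; the default is
the standard k̂ ≥ 1 rule.

### Penalized logistic regression

The model minimises

    -(1/N) Σ_i [ y_i log p_i + (1-y_i) log(1-p_i) ] + Σ_j P_λ(β_j),
    p_i = expit(β₀ + x_i'β),

with P_λ one of

* LASSO: λ|β|
* SCAD (γ > 2, default 3.7): λ|β| on [0, λ]; the quadratic bridge
  (2γλ|β| − β² − λ²) / (2(γ−1)) on (λ, γλ]; constant λ²(γ+1)/2 beyond γλ
* MCP (γ > 1, default 3.0): λ|β| − β²/(2γ) up to γλ, then constant γλ²/2

The γ defaults are the conventional choices; only the domain constraints
are inherent to the penalties. The intercept is unpenalized. Variables are
standardized internally (mean 0, variance 1; the penalty applies on that
scale) and coefficients returned on the original scale, with the
center/scale stored on the results object.

Solver: outer iteratively-reweighted least squares, inner cyclic coordinate
descent on the weighted quadratic surrogate, compiled with numba. Full
sweeps establish the active set; cheap sweeps over the active coordinates
then iterate to tolerance (max absolute coefficient change < 1e-7, at most
100 outer iterations). IRLS weights are floored at 10⁻⁶ and probabilities
clipped at 10⁻¹⁰ in likelihood evaluations; standardized coefficients and
the intercept are clamped at ±30 as a separation guard (an unpenalized or
weakly penalized fit on separable data otherwise diverges).

Coordinate updates. For the LASSO the update is the soft threshold
S(z, λ)/v, with v the surrogate curvature at that coordinate. For SCAD/MCP
the one-dimensional problem (v/2)b² − zb + P_λ(b) is piecewise quadratic;
the solver evaluates every piece's stationary point and the piece
boundaries exactly. Two subtleties drive the design:

* With logistic weights, v ≤ 0.25 can fall below the penalty concavity
  (1/γ for MCP, 1/(γ−1) for SCAD), so the textbook closed-form interior
  update is invalid and the *global* one-dimensional minimiser becomes
  discontinuous in z — it can jump from 0 to ≈γλ. Under IRLS reweighting
  that discontinuity makes coordinates flip-flop indefinitely.
* The path solver therefore uses a hysteresis rule: a coefficient at zero
  leaves it only when zero stops being stationary (|z| > λ), and a nonzero
  coefficient returns to zero only when zero is stationary and beats the
  best nonzero candidate. Every move weakly decreases the surrogate, the
  null model is exact at λ ≥ λ_max, and cycling is eliminated. The
  standalone `coordinate_minimizer` keeps the exact global rule (with a
  grid-search fallback, and a warning, for the invalid MCP branch), so the
  two conventions are both available and separately tested.

An outer-step safeguard halves the step toward the previous iterate if the
penalized objective increased, making the objective non-increasing across
outer iterations for all families (for the convex LASSO case this is a
tested invariant).

Regularization path and CV. λ_max = max_j |(1/N) Σ_i x_ij (y_i − ȳ)| on the
standardized scale is the smallest λ with an all-zero slope solution (the
penalty derivative at 0⁺ is λ for all three families). The default grid is
40 log-spaced values down to 0.02·λ_max, fitted with warm starts; for the
folded-concave families the warm-started descent from λ_max defines which
stationary point is returned. Single-λ fits warm-start along a short
internal path for the same reason. Cross-validation uses class-stratified
folds (10 by default), pooled held-out binomial deviance as the loss
(misclassification and AUROC losses behind a flag), and resolves ties
toward the larger λ, i.e. the sparser model.

### ISIS

d = ⌊N / (4 ln N)⌋ (natural log, floored, clamped below at 1; both base
and rounding are config-overridable since the defining expression fixes
neither). The loop:

1. rank candidates by marginal logistic likelihood, keep the top d → Î₁;
2. CV-tuned penalized fit on Î₁; its support is M̂₁;
3. rank the remaining candidates by the likelihood of the logistic model on
   M̂_l ∪ {j} — the conditioned coefficients are re-estimated jointly with
   each candidate (an offset variant that freezes them is behind a flag);
   keep the top d → Î_{l+1};
4. CV-tuned penalized fit on Î_{l+1} ∪ M̂_l → M̂_{l+1};
5. stop when |M̂_l| = d, M̂_l = M̂_{l−1}, or after max_iter (default 10)
   iterations.

If a penalized fit returns more than d variables, the d largest by
standardized coefficient magnitude are kept and the loop stops under the
size-d rule, so |final_set| ≤ d always holds. The penalty family inside the
loop is the same as the final selection family, and λ is CV-tuned in every
inner fit (a fixed-λ mode exists). Conditional ties are broken by ascending
index.

### Pipeline and metrics

One pipeline run: marginal statistics on the training split only (the test
split never touches screening or selection) → screen → ISIS on the
surviving set → final CV-tuned penalized fit restricted to the ISIS output
→ AUROC of the fitted probabilities on the test split. An empty screen
yields the intercept-only model and AUROC 0.5 by construction. The final
model is the penalized fit itself — no post-selection unpenalized refit
(a refit variant is not part of the default pipeline).

Metrics cross the selected set against the true support over all P
variables: TP rate TP/(TP+FN), FP rate FP/(TN+FP), per-replicate FDP = V/R
with FDP = 0 when R = 0; the FDP average across replicates estimates the
FDR E[V/R | R>0]. The number of true variables surviving the *screen* is
recorded separately (the "# filter" column), before ISIS. AUROC is the
Mann–Whitney statistic (ties ½), computed from rank sums.

## Synthetic data generator

The generator emulates an ultrahigh-dimensional case-control expression
study. Covariates follow a stationary Gaussian AR(1) across the column
index: x₁ = z₁, x_j = ρ x_{j−1} + √(1−ρ²) z_j with z_j i.i.d. N(0,1),
giving unit variance and corr(x_k, x_l) = ρ^{|k−l|}. (The √(1−ρ²) factor
is the only scaling for which both stated properties hold.) The first
n_true = 25 coefficients are i.i.d. Uniform(−1.5, 2), the rest exactly
zero; the outcome is Bernoulli(expit(x'β)). Rows are generated one at a
time (vectorised in batches but consumed strictly in generation order) and
kept only while the drawn class's quota (450 cases / 450 controls) is open;
accepted rows are shuffled so classes are not block-ordered. The 600/300
train/test split is stratified by class by default (a flag restores the
simple random split). One master seed drives a study; replicate r and each
scenario within it use deterministically spawned child seeds.

What the generator does *not* emulate: probe-level measurement error,
non-Gaussian marginals, missing data, or correlation structures other than
AR(1) (a hook accepts any column process). Passing tests therefore show
correct behaviour of the procedures under the stated generating model, not
robustness to real microarray artefacts.

## Study conditions and problem sizes

The full-scale design (P = 100,000, 500 replicates) is a cluster-scale
computation. The packaged studies keep the generating model and sample
sizes and reduce the dimension and replicate count:

* BH-screened study: P = 2,000, ρ = 0.1, 25 true effects, 50 replicates,
  q ∈ {0.05, 0.20}, all three families.
* Filter-comparison study: P = 10,000, K = 100 (keeping 1% of variables,
  the same filtering fraction as K = 1,000 of 100,000), 20 replicates.

At reduced m the BH screen is *more* powerful (absolute TP rates are higher
than at full scale) and its realized FDP sits closer to the nominal q, so
the control statements are checked against the nominal level with a
one-sided 95% Monte-Carlo interval, and the filter comparison against the
"over 40% false" mark. Scenario contrasts are paired: every scenario in a
replicate sees the same data and split.

## Numerical choices and degenerate inputs

* Probability clipping 10⁻¹⁰; weight floor 10⁻⁶; coefficient clamp ±30
  (standardized scale) in all logistic fits.
* Constant columns: scale set to 1 in standardization, coefficient stays 0;
  an all-constant design raises on path construction.
* p-value ties: broken by ascending index everywhere (BH, top-K, ISIS
  ranking), making every selection deterministic.
* CV λ tie: larger λ. Folds: stratified; a class with fewer members than
  folds raises.
* FDP of an empty model is 0 (R = 0 convention).
* A failed replicate-scenario in a study is logged and recorded in the
  per-replicate table with `failed=True`, never silently dropped.

## Known limitations

* The folded-concave fits are stationary points selected by the warm-start
  path convention; other solvers may return different (equally valid)
  stationary points, especially with strongly correlated designs.
* The hysteresis coordinate rule keeps the zero solution when |z| ≤ λ even
  where the one-dimensional global minimum is nonzero (only possible when
  v < 1/γ); this matches the sparsity convention of standard path solvers
  but means the reported solution need not be a coordinate-wise global
  minimiser.
* Marginal screens inherit the usual SIS caveats: variables marginally
  uncorrelated with the outcome are invisible to step 1, and neighbours of
  true variables carry real marginal signal under AR(1), which is the
  mechanism inflating false discoveries at loose screening levels.
* No real-data preprocessing (normalisation, probe annotation) is
  included; inputs are plain numeric matrices.
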