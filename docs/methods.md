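# Methods

## Model

The package implements topological regression (TR) and its adaptive
variant (AdapToR). Both assume that structural similarity is
informative about response similarity: the regression is fitted between
distance matrices, not feature matrices. For training molecules
i = 1..N, structure anchors k = 1..K_s and response anchors k = 1..K_r,

    D_r = D_s W + 1 β + ε,

with D_s[i,k] the structure distance between molecule i and structure
anchor k, and D_r[i,k] = |t_i − t_k| the absolute response difference
to response anchor k. Stacking the intercept (D_s* = [1, D_s],
W* = [βᵀ, Wᵀ]ᵀ), the ridge estimate is the closed form
Ŵ* = (D_s*ᵀD_s* + λI)⁻¹D_s*ᵀD_r, computed by a symmetric
positive-definite solve rather than explicit inversion. The penalty is
applied to the full W* including the intercept row, exactly as the
objective ‖D_r − D_s*W*‖² + λ‖W*‖²_F states; a `penalize_intercept=False`
flag exposes the more common exempt-the-intercept convention but is off
by default. With λ = 0 the fit is ordinary least squares and requires a
full-rank design; a rank-deficient design raises a singularity error
advising λ > 0. An explicit `rank_deficient="minnorm"` policy returns
the Moore–Penrose (minimum-norm) least-squares solution instead — the
vanilla-TR baseline uses it because unregularized distance designs are
routinely ill-conditioned (distance columns are highly collinear), and
the baseline's numerical fragility is part of what the adaptive variant
is designed to fix.

### Distances

* ECFP4 (Morgan radius 2, folded to 2048 bits by default): Jaccard /
  Tanimoto distance 1 − |a∩b|/|a∪b|. Two all-zero bit vectors are
  assigned distance 0.
* MHFP6 (min-hash, radius 3, 2048 permutations): the fraction of hash
  positions that disagree — the standard unbiased estimator of the
  Jaccard distance of the underlying shingle sets. The MHFP encoder is
  seeded with a fixed constant so fingerprints are reproducible across
  processes.
* Response space: absolute difference of scalar responses. For
  multi-dimensional responses the intended extension (z-score each
  dimension, then Euclidean distance) is documented but outside the
  default path.

### Anchor selection

Response anchors (default K_r = 10) are chosen by k-means on the
training responses (10 restarts, seeded); within each cluster the
member closest to the center is taken, ties broken by lower molecule
id. This guarantees coverage of the response range and generalizes to
multi-dimensional responses.

Structure anchors grow adaptively. Step 1 uses a uniform random subset
of size K_a = round(0.15·N). At step p the regression rows and the
structure-distance columns are the current anchor set S_p (the fit is
an anchors-only regression; the remaining training samples act as a
held-out evaluation pool, consistent with treating them as unseen when
scoring errors). All training samples outside S_p are predicted and the
K_a with the largest absolute error — ties broken by molecule id — form
S*_p, giving S_{p+1} = S_p ∪ S*_p. After P = 4 steps the final set
holds round(0.6·N) molecules, matching the vanilla model's 60% anchor
budget. Anchors only accumulate; there is no pruning.

Early stopping is off by default (the production configuration uses a
fixed P = 4). When enabled, 10% of the training set is split off by
seed as validation; the loop stops once the per-step decrease in
validation NRMSE stays below `min_delta` (default 0.006) for `patience`
(default 2) consecutive steps.

### Reconstruction

Estimated response distances are clipped at zero (max(0, ·)) before
reconstruction. The RBF route uses Gaussian weights
u_k = exp(−γ d̂_k²); the bandwidth γ is configurable with default 1.0
(the canonical Gaussian choice; exposed because the original weighting
scheme's bandwidth is a free calibration). If all weights underflow,
the nearest anchor's response is returned with a warning. The output is
a convex combination, so it cannot leave [min t_k, max t_k].

The optimization route minimizes Σ_k (max(0, d̂_k) − |t − t_k|)² over
t. The objective is piecewise quadratic with breakpoints at the anchor
responses but not convex, so two solvers are provided. The `exact`
solver (default and reference) minimizes each segment's quadratic in
closed form, evaluates the clamped vertices and breakpoints, and
returns the global minimizer, resolving exact ties toward the smaller
t (a single anchor with d̂ > 0 has two global minima t₁ ± d̂; the
exact solver returns the smaller). The `nelder_mead` solver restarts
scipy's simplex method (xatol = fatol = 1e-6, maxiter 200) from every
anchor response plus the RBF estimate and keeps the best; the
multistart is necessary because a single start can stall in a local
minimum of the non-convex objective, and with degenerate multimodal
inputs it may legitimately return either global minimizer. No clamping
is applied, so the optimization route can extrapolate beyond the
anchor-response range.

### Metrics

NRMSE = RMSE / σ̂_y (equivalently √(Σ(y−ŷ)²/Σ(y−ȳ)²)), so the
mean-predictor null model scores exactly 1. Spearman's ρ uses the
rank-difference formula 1 − 6Σv²/(n(n²−1)) when all ranks are distinct;
with ties that formula is invalid, so the product-moment correlation of
mid-ranks is used instead (a documented deviation from the
distinct-rank formula, equal to it whenever there are no ties). Bias is
the slope of the residuals regressed on the observed responses,
Σ(y−ȳ)(y−ŷ)/Σ(y−ȳ)²; a geometrically equivalent formulation via the
centered-vector angle, ‖r_c‖·cos∠(y_c, r_c)/‖y_c‖, is provided as a
cross-check and agrees to ~1e-10. Constant observed responses make
every metric undefined and raise; constant predictions return 0 for
the two correlations (no rank/linear information) while NRMSE and bias
remain well-defined.

Cross-validation is drug-blind: molecule ids are shuffled once per
dataset by seed and split into disjoint test folds, so no compound
appears in more than one test fold and duplicated ids are rejected
outright. Wilcoxon signed-rank comparisons across models wrap
`scipy.stats.wilcoxon`.

### Ensembles and stacking

The ensemble draws member anchor fractions from Normal(0.6, 0.3)
clipped — not resampled — to [0.3, 0.9] (the simplest reading of the
stated range) and averages member predictions exactly. Members are
"enhanced" models: ridge + k-means response anchors + the chosen
reconstruction, i.e. everything except adaptive selection. Stacking
fits an unconstrained ordinary-least-squares combination with intercept
on a 10% seeded validation holdout; no nonnegativity or sum-to-one
constraint is imposed. Because of the intercept, stacking identical
imperfect members yields the best affine recalibration of the member
prediction rather than the member prediction itself; a member that
already fits the holdout exactly is reproduced exactly. Both
combination modes are also available across the step models retained
from adaptive selection.

### Bayesian verification

The optimization objective admits a hierarchical reading: anchor
responses t_k | t_n, τ²_k ~ Normal(t_n, τ²_k) with
τ²_k | d ~ Exponential(rate d²/2). The package verifies the two
checkable consequences numerically: (1) the marginal of t_k is
Laplace(t_n, 1/d), checked by Kolmogorov–Smirnov distance of mixture
draws against the closed-form Laplace CDF (< 0.01 at 10⁵ draws across
a (t_n, d) grid); (2) with a Normal(0, σ²) prior on t_n the full
conditional is Normal(u*, v*) with 1/v* = 1/σ² + Σ1/τ²_k and
u* = v*Σt_k/τ²_k, checked against a fine-grid quadrature of the product
density to 1e-6. The ridge-prior sub-hierarchy and the process-level
model for log d² are part of the same statistical story but are
point-estimated by the ridge fit itself; no sampler is provided for
them, since only the two proved results are verifiable claims. A
diagnostic routine reports the squared-loss minimizer next to the
posterior point estimate with τ²_k set to its conditional mean 2/d̂²;
note the limits of that identification: as d̂ → 0 the conditional mean
2/d̂² diverges, so the anchor's precision vanishes and u* tends to the
prior mean unless σ² is far larger than τ² — the two estimators answer
related but distinct questions and the demo carries no pass/fail.

## Synthetic data

The generator emulates the regime the method assumes, not real
chemistry. Each molecule is a latent point z ∈ [0,1]²; the response is
a smooth surface (a gentle diagonal gradient plus three Gaussian bumps,
multi-modal enough that one random anchor set underfits locally) plus
Normal(0, 0.05) noise on the unit scale, then rescaled to span (4, 8) —
the approximate range of NLOGGI50 values in large growth-inhibition
panels. Fingerprints are random-hyperplane bit codes of z (default 512
bits; enough that the Jaccard–latent-distance rank correlation is
stable, ~0.99 on random pairs), so structure distance is genuinely
informative about response distance. What the generator does *not*
emulate: discrete chemical series, activity cliffs, assay censoring,
multi-modal response distributions, or any SMILES-level structure —
passing tests on it show the machinery behaves as designed under the
method's own assumptions, not that the method performs at any
particular level on real screening data. A separate toy fixture
reproduces the four-anchor geometry (responses 4, 5, 6, 8; test
response 7; Gaussian sd-0.5 noise on the true distances 3, 2, 1, 1)
used to compare the two reconstruction routes.

## Problem sizes and numerical choices

Desk-scale defaults were chosen once: the model-comparison experiments
use N = 500 with 80/20 drug-blind splits over five generator seeds, the
toy comparison uses 2000 noise seeds, and the Monte-Carlo hierarchy
checks use 10⁵ draws per grid point — sizes at which every reported
ordering is stable across seeds while the whole suite runs in well
under a minute on one CPU. Seeds fan out from a single integer through
`numpy.random.SeedSequence` into named sub-streams (split / anchors /
k-means / noise), so components can be rerun independently yet
reproducibly; derived seeds are reduced below 2³¹. Linear systems use
`scipy.linalg.solve(assume_a="pos")` at solver-default tolerance; exact
reconstruction ties resolve to the smaller response; k-means ties to
the lower molecule id; error-ranking ties in adaptive selection to the
lower molecule id (stable and reproducible across platforms).

## Known limitations

* The RBF route cannot predict outside the anchor-response range by
  construction; the optimization route can, but both inherit the usual
  similarity-model caveat of degrading for test compounds far outside
  the training structure space.
* Responses are scalar throughout; the multi-dimensional extension is
  specified but not wired into the fitting path.
* Vanilla TR's minimum-norm OLS fallback resolves the rank-deficient
  fit deterministically but, like any pseudoinverse fit, is sensitive
  to the effective-rank cutoff on nearly singular designs.
* The model archive stores anchor fingerprints as JSON; compact for
  hundreds of anchors, not designed for million-compound anchor sets.
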