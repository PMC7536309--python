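# Methods

## Model

The classifier is a sequential, orthogonalized covariance-selection
regression with an LDA read-out, for K blocks of predictors measured on
the same samples.

1. **Pretreatment.** Each block is autoscaled column-wise: subtract the
   mean, divide by the n−1 standard deviation. Autoscaling can be fitted
   on all samples ("global", the pretreat-then-validate order used in
   the kind of study this emulates) or refitted inside every
   cross-validation training fold ("fold", the default, which is
   leakage-free). Both modes are exposed; results always record which
   was used.
2. **Stage 1.** CovSel on block 1 against the centred response
   y ∈ {0,1}ⁿ: pick argmax_j (x_jᵀ y_c)², deflate X and y_c by the
   projector I − v vᵀ/(vᵀv) of the picked column, repeat c₁ times.
   Ties break to the lowest column index; a column whose deflated
   squared norm falls below 10⁻²⁰ of its original is treated as spent
   and can no longer be picked.
3. **Stage k.** Block k and the centred response are orthogonalized
   against the matrix S of *all* previously selected columns using a
   pseudo-inverse of SᵀS with relative cutoff 10⁻¹², so collinear
   selections degrade gracefully; CovSel then runs on the orthogonalized
   block against the orthogonalized response. Stage coefficients B_k are
   ordinary least squares of the orthogonalized response on the stage's
   orthogonalized picks; columns annihilated by the orthogonalization
   (residual norm < 10⁻¹⁰ of original) are excluded from the regression
   and keep coefficient 0, so a block that merely duplicates earlier
   information contributes nothing rather than an unstable coefficient.
   If a stage's column space is exhausted before the requested count,
   the remaining picks are filled with the lowest-index unused columns
   at criterion 0; they are inert by the same rule.
4. **Prediction.** ŷ = Σ_k X_k,orth,sel B_k + intercept. Test samples
   are corrected with the *training* orthogonalization weights. The
   intercept is fitted (mean of y minus mean of the stage
   contributions); on centred inputs it reduces to the case fraction.
5. **LDA on ŷ.** One-dimensional Gaussian LDA: class means, pooled
   variance with the n−2 denominator, priors (empirical class
   frequencies by default; equal priors available), decision threshold
   where the two discriminant scores are equal. A sample exactly at the
   threshold is assigned to class 1.

## Validation

Repeated double cross-validation. The outer loop (default 21 groups =
leave-one-out at the default cohort size) holds out one segment; the
inner loop (default 5 groups) evaluates every candidate (block order ×
per-block complexity) by pooled misclassification count over inner folds
and returns the grid point with the smallest count, breaking ties toward
fewer total variables, then the earlier candidate order, then the
lexicographically smaller complexity tuple. The winning settings are
refitted on the full outer-training set and the held-out segment is
predicted. Defaults: 50 repetitions, complexities 0..4 per block with
the all-zero tuple excluded, all 6 block orders as candidates.

Partitions are stratified: within each class, shuffled members are dealt
round-robin to groups, so group sizes differ by at most one overall and
per class. Seeds follow a fixed ladder — base seed → per-repetition seed
(base + r, mod 2³¹−1) → partition draws from that repetition's
generator — so an `RdcvConfig` reproduces its `RdcvSummary`
bit-identically.

Figures of merit are the per-run class-wise correct-classification
rates and overall accuracy; the summary reports mean, SD (across
repetitions), min and max. The "± " spread is the SD across the 50
run-level rates. Selection frequency counts, per analyte, the outer
models (repetitions × segments) that selected it; modal block order is
the most frequent order across all outer models, and the modal
complexity is the most frequent tuple among models with that order,
reported in dataset block order.

The permutation test permutes the labels B times and recomputes the
accuracy with a single DCV run per permutation (running the full
repeated procedure per permutation would be ~50× the cost for no change
in the null's location); this granularity is recorded in the result.
The p-value uses the add-one rule, p = (1 + #{null ≥ observed})/(B + 1).

### Inner-loop grid enumeration

Because CovSel is greedy with deflation, the selection at complexity c
is the length-c prefix of the selection at any larger complexity, given
the same upstream picks. The inner search therefore walks a tree
branching on each block's complexity: each greedy pick's deflation
vector is the Gram–Schmidt residual of the picked column, the stage
contribution to ŷ grows by that rank-1 projection, and later blocks are
deflated by the same rank-1 updates. All leaves of a fold are classified
in one vectorized LDA pass. This is an exact reorganization of
evaluating every grid point with the canonical fitting path — asserted
by a test against a naive point-by-point oracle — and is what makes the
1,050-model default run take minutes rather than hours.

## Synthetic cohorts

The generator emulates a three-platform serum panel study:

- **Design.** 11 cases, 10 controls; blocks `amino_acids` (37 assayed /
  32 retained), `inflammation` (31 / 23), `mdv` (7 / 4); analyte names
  from the real panel vocabulary at these widths, systematic names
  otherwise. The 16 censor-designated analytes are written as fully
  below the detection limit, so the filtering step reproduces 75 → 59.
- **Signal.** Every variable is built on a standardized scale
  x = ρ·z + √(1−ρ²)·ε with z a per-sample latent factor shared by all
  blocks (inter-block correlation ρ², default ρ = 0.3) and ε unit
  Gaussian noise. The √(1−ρ²) weighting keeps the marginal variance at
  1 so that the planted effect δ — added to cases on this scale — is
  exactly the standardized mean shift, independent of ρ. Defaults:
  δ = 1.5 on five planted markers (phosphoethanolamine, tryptophan;
  IL1-ra, MIP-1β; NDUFS3), the panel shape of the motivating study.
- **Concentrations.** Lognormal by default: conc = exp(μ_j + 0.4·x)
  with per-analyte medians drawn from platform-plausible ranges
  (amino acids 10–300 µM, mediators 2–400 pg/mL, MDV 0.2–3 a.u.);
  a Gaussian family (conc = μ_j(1 + 0.15·x)) is available. The effect
  is placed before exponentiation so δ means the same thing in both
  families.
- **What it does not emulate.** Real covariance structure beyond one
  shared factor; age/sex covariates; assay-specific error models;
  partial (per-sample) censoring. Passing tests therefore demonstrate
  algorithmic correctness and statistical calibration, not performance
  on any real cohort.

## Problem sizes used in the checks

The default study design (50 × 21 models, full grid) runs once in the
arithmetic check and in the acceptance script. Stochastic calibration
checks use deliberately smaller configurations chosen once: the natural
block order and complexities 0..2 (which still cover the 2-2-1 optimum)
for null calibration (20 cohorts × 2-repetition rDCV), permutation
type-I error (50 cohorts, B = 19), and the ten-cohort recovery sweep
(10 repetitions each).

## A structural limit on per-cohort marker recovery

With mean-shift planting, the class-related components of all planted
variables are perfectly collinear (each equals δ·y plus noise), so once
stage 1 has captured the response direction, the *residual* covariance
of a later planted variable is ≈ δ(1−R²)·p(1−p), where R² is stage 1's
fit. At δ = 2 and n = 21 this is ≈ 0.17 — the same size as the expected
maximum noise covariance across a 23-column block (≈ 0.16). Later-stage
selection of the planted markers in any single 21-sample cohort is
therefore near a coin flip, and at larger δ the effect inverts: one
variable separates the classes perfectly and the parsimonious inner
loop (fewest-variables tie-break) suppresses the rest. The planted set
does dominate — in every cohort the most-selected analytes are planted,
and aggregated over ten cohorts the top five by total selection
frequency are exactly the five planted markers — but demanding the full
top-5 within every single small cohort exceeds what the method's
parsimony allows at these effect sizes. The test suite asserts both
faces: the aggregate recovery property (green) and the strict per-cohort
form (red, kept as an honest record).

## Known limitations

- Binary classification only; no multi-class extension.
- No imputation of censored values (filtering only).
- The inner-loop error is an unweighted misclassification count; with
  strongly unbalanced classes a weighted criterion would be preferable.
- At n ≈ 21 the figures of merit have wide spreads; the SD across
  repetitions understates the full sampling uncertainty of a single
  small cohort.
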