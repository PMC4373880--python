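# Methods

## Model and decomposition

Outcomes are generated and analysed under the two-way fixed-effects linear
model

    y_ij = beta0 + beta1 * cA + beta2 * cB + beta3 * cA * cB + eps,
    eps ~ N(0, sigma^2), i.i.d.

with two-level factors A and B. Two distinct code systems appear in two
distinct roles and must not be conflated:

* **Effect construction** (generation): the codes substituted into the model
  when data are created. `zero_control` uses (0, 1) — only treatment cells
  carry effects, as with no-treatment controls; `equal_contribution` uses
  (−1, 1) — control and treatment contribute equally and oppositely.
* **Analysis coding** (fitting): treatment (0, 1) or contrast/sum-to-zero
  (−1, 1) columns in the design matrix, with the interaction column always
  the elementwise product of the factor columns.

An analysis is *congruous* when its coding matches the construction of the
data and *incongruous* otherwise. With a multiplicative interaction the two
constructions are not affine-equivalent (cell-mean patterns (10, 14, 14, 22)
versus (6, 6, 6, 22) at betas (10, 4, 4, 4)), which is why incongruous
analysis redistributes the interaction into the intercept and main effects.

All sums of squares are differences of regression SS R(S) over the seven
non-empty predictor subsets S of {A, B, AB}, each fitted with an intercept:

* Type I (A first): R(A), R(A,B) − R(A), R(A,B,AB) − R(A,B)
* Type II: R(A,B) − R(B) and R(A,B) − R(A) for the mains
* Type III: R(A,B,AB) − R(B,AB) and R(A,B,AB) − R(A,AB)
* interaction, every type: the unique part z = R(A,B,AB) − R(A,B)

The commonality (Venn) components are the inclusion–exclusion combinations
of the same seven fits: t, x, z unique to A, B, AB; u = common(A,B),
w = common(A,AB), y = common(B,AB), v = common(A,B,AB). The non-unique
components may be negative (underlapping variance); only the full
seven-component sum is additive, equal to R(A,B,AB). Useful invariants
exploited by the test suite: Type I/II SS and z are invariant to the
analysis coding; Type III main effects are not (on balanced data contrast
coding makes all columns orthogonal and all types coincide, while under
treatment coding the interaction column stays correlated with the mains, so
Type III mains differ even there — hence contrast coding is the package
default and the recommended choice for Type III).

F tests use the full-model residual mean square, df N − 4, for every effect
row (one residual line per model); reject when the upper-tail central-F
probability falls below alpha (default 0.05).

## Numerical implementation

Every predictor column is constant within a cell, so each R(S) is computed
from the per-cell sufficient statistics: with cell counts w and cell means
m, R(S) = sum_c w_c (m_c − ybar)^2 − sum_c w_c (m_c − f_c)^2, where f is the
weighted least-squares fit of m on the four cell rows of the coded design
matrix. This is algebraically identical to the subject-level normal
equations (the within-cell scatter is orthogonal to all cell-constant
predictors) and is validated against an explicit subject-level
projection-matrix oracle and against statsmodels' `anova_lm` in the tests.
Solves use an SVD least squares with relative singular-value cutoff 1e-10;
a rank drop (e.g. an empty cell) raises a named error. A tiny negative SS
from cancellation is treated as zero signal in the F statistic; a zero
residual (noise-free input) yields F = inf for non-zero effect SS. Full-model
coefficients are recovered exactly from the 4×4 cell-code system, so the
treatment/contrast reparameterization identities (c3 = b3/4,
c1 = b1/2 + b3/4, ...) hold to machine precision.

## Simulation design

Defaults follow the study conditions throughout: beta0 = 10,
beta1 = beta2 = 4 (moderate signal-to-noise 0.4 per main effect),
beta3 in {0, 4, 8} (absent, intermediate, strong interaction), sigma = 10,
alpha = 0.05, 1000 replicates per cell. The design set is every composition
of 12 subjects over 4 cells with at least 2 per cell (so each cell keeps
variance) — 34 unbalanced plus the balanced (3,3,3,3) — scaled by 10 to
N = 120, cells 20–60, the largest imbalance threefold. Unbalanced designs
are numbered 1..34 lexicographically by (n00, n01, n10, n11).

Pairing: for each replicate a per-cell pool of max(unbalanced, balanced)
subjects is drawn once; the unbalanced sample takes the pool prefix of its
count, the balanced its own, so the arms share min(n_u, 30) subjects per
cell. Comparisons classify each design against its *own* paired balanced
arm, which cancels most Monte-Carlo noise from the difference; the summary
tables' balanced column is the mean over the 34 paired balanced arms. Inside
the study the analysis coding is contrast throughout; treatment coding is
used only in the coefficient-recovery table, which reports the replicate
mean of fitted coefficients and (coding-invariant) Type II SS on balanced
samples of 250 per cell.

Seeding: every replicate stream is a `SeedSequence` keyed by (base seed,
design id, beta3, construction, replicate), so any single replicate is
reproducible in isolation and whole runs are byte-identical given the base
seed.

The analytic oracle converts the engine's noise-free SS (every subject
placed exactly on its cell mean) into a noncentrality lambda = SS0/sigma^2
and evaluates the noncentral-F upper tail at the central-F critical value;
zero noncentrality falls back to the central distribution (scipy's `ncf` is
degenerate there).

## What the generator does and does not emulate

It emulates exactly the stated study conditions: i.i.d. normal,
homoscedastic noise, fixed cell counts, effects realised through one of the
two constructions. It does not model non-normal or heteroscedastic errors,
covariates, within-subject structure, or attrition mechanisms that *cause*
imbalance — passing tests therefore say nothing about ANOVA's behaviour
under those violations, only about the pure effect of cell-count imbalance
on the SS corrections.

## Known limitations and deliberate choices

* **Congruous power levels.** Under the stated parameters the
  equal-contribution construction gives marginal group differences of 8,
  hence balanced main-effect power ≈ 0.99 (noncentrality 19.2). The
  published congruous summary level of ≈ 0.59 would require a marginal
  difference of 4; the stated generator cannot produce it, and this package
  implements the stated generator. Consequently the qualitative rule "Type
  III main-effect power is below the balanced power in every unbalanced
  design when an interaction is present under equal contribution" holds
  *analytically* for all 34 designs (gaps 0.004–0.018, checked via the
  oracle) but is near power saturation, where 1000-replicate Monte-Carlo
  noise (s.e. ≈ 0.003) can flip individual design comparisons; the
  simulated 34/34 check in the acceptance suite is therefore expected to
  show a handful of ties/reversals.
* **Null-band width.** The per-design interaction type-I-error band
  [0.037, 0.065] used in the acceptance suite is about ±2.2 Monte-Carlo
  standard errors at 1000 replicates; applied to ~100 design × method
  rates, a correctly calibrated engine is still expected to land outside it
  a few times. The tighter statement that holds reliably is the pooled
  per-method mean (s.e. ≈ 0.001) and the 3-s.e. per-design band.
* Designs beyond 2×2, Type IV SS, random effects, unequal-variance
  corrections and permutation tests are out of scope; Venn components are
  exported as tables, not drawn.
* The decision rule "use Type II unless the interaction is significant" is
  reported as a rate (`ss2_choice_rate`) rather than gating any table,
  since the main tables report both corrections unconditionally.
* `read_dataset` accepts any delimited a/b/y file with C/T, 0/1 or −1/1
  levels and at least two rows per cell, so external worked-example
  datasets can be decomposed with the same engine; the shipped tests use
  synthetic fixtures only.
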