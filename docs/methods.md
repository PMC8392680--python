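# Methods

## Model

Presence/absence of a species over a grid of n cells is modelled as
independent Bernoulli draws with cell probability
`P_i = invlogit(α + Σ_j β_j x_ij)`. Fitting is maximum likelihood via
iteratively reweighted least squares (statsmodels' binomial GLM), with
convergence declared when the log-likelihood changes by less than 1e-10
(at most 100 iterations). Predictors are centered and scaled internally
for fitting; reported coefficients are back-transformed to the original
scale, under which the likelihood is invariant. The intercept-only model
has the closed-form solution `α = logit(n₁/n)` with every fitted
probability equal to the prevalence; the implementation is checked
against that closed form to 1e-8.

Because the MLE is the unique optimum of a concave likelihood, the choice
of optimizer is immaterial to the result; IRLS is used for speed and
determinism.

### Separation

Rare species on fine grids make complete or quasi-complete separation
plausible. A fit is flagged `converged = False` — but remains usable —
when statsmodels reports separation or when any coefficient exceeds 30
in absolute value on the standardized predictor scale (a logit of ±30
across one standard deviation of a predictor is far beyond anything
estimable from binary data). The stepwise search skips non-converged
candidate moves with a warning.

## Variable screening

**Stage 1 — correlation filter.** Within each predictor-set group (or
globally when no groups are supplied): while any retained pair has
|Pearson r| strictly above the threshold (default 0.8), the pair with the
largest |r| is resolved first and its member with the larger univariate
Rao score-test p-value is dropped. Ties in |r| are broken by input column
order of the pair, and p-value ties drop the later column in input order,
making the procedure deterministic. Zero-variance columns are removed
with a warning before filtering. Correlations are computed on raw
predictor values.

**Stage 2 — false discovery rate.** The V stage-1 survivors are ordered
by increasing p-value; rank I is retained up to the largest I with
`p(I) < I·(q/V)` (strict inequality), q = 0.05 by default. This is the
Benjamini–Hochberg step-up rule, and the implementation is
oracle-checked against statsmodels' `multipletests` on random p-vectors.

The univariate screen uses Rao's score test of adding one variable to the
intercept-only model, `U²/I` with `U = Σ x_i (y_i − ȳ)` and
`I = ȳ(1−ȳ) Σ (x_i − x̄)²`, referred to χ²₁. Only the null model is ever
fitted, so screening many candidates is cheap; the closed form is
cross-checked against statsmodels' GLM score test.

## Stepwise trace and entropies

The stepwise search is *best single move per step*: from the current
model, every single-variable addition and deletion is refitted and the
move with the lowest AIC is accepted if it is strictly below the current
AIC (improvement threshold 0, ties by candidate input order); dropped
variables may re-enter later. Step numbering is 0-based with step 0 the
intercept-only model. An alternative reading of forward-backwards
selection purges all non-contributing variables after each forward step;
the single-move semantics was chosen because it yields exactly one
`+var`/`−var` action per step, which is the shape of the per-step record
this workflow is designed to produce.

Each step is annotated with:

- `H`, Shannon entropy (natural log) of `p_i = P_i/n₁`, using the
  continuity convention `0·ln 0 = 0`. Dividing by n₁ makes the vector sum
  to 1 at any MLE containing an intercept (the score equation forces
  `Σ P_i = n₁`); the sum is verified to 1e-3 and no re-normalization is
  applied beyond that check — inputs that are not MLE fitted
  probabilities are rejected rather than silently rescaled.
- `R`, fuzzy entropy of the favourability map,
  `Σ min(F, 1−F) / Σ max(F, 1−F)`. Favourability values are used
  untransformed. R = 1 iff every F = 0.5 (step 0); R = 0 iff every F is
  crisp 0/1.
- `cor_P`, `cor_F`: Pearson correlations of the step's probabilities and
  favourabilities with those of the final step. At step 0 the fitted
  values are constant, so both are reported as missing (NaN); numerically
  the IRLS fitted values of a constant model carry last-bit jitter, so a
  vector whose standard deviation is below 1e-10 (relative) is treated as
  constant. At the final step of a multi-step trace both are exactly 1 by
  construction; in the degenerate trace that contains only step 0 the
  missing-value convention takes precedence.

The efficient model is the one at the earliest step attaining the
minimum R (ties resolve to the earlier, more parsimonious step).

Favourability at probabilities exactly 0 or 1 (possible only for inputs
outside the open unit interval, e.g. under separation) maps to F = 0 or 1
with a boundary warning.

## Evaluation

Classification metrics (Cohen's kappa, sensitivity, specificity, CCR) use
the favourability threshold F ≥ 0.5, with ties counted as predicted
presence; by the favourability/prevalence duality this classifies a cell
as presence exactly when P ≥ prevalence. AUC is the rank-based
(Mann–Whitney) statistic with midrank ties, computed by scikit-learn and
identical for P and F since F is a monotone transform. The
Hosmer–Lemeshow test uses 10 fixed-width bins of 0.1 on the probability
scale (calibration concerns probabilities, not favourabilities); empty
bins are dropped rather than merged and degrees of freedom are
(nonempty bins) − 2, the convention for a test applied to fitted models.
With fewer than 3 nonempty bins the test is refused (df ≤ 0).

## Virtual-species generator

The generator emulates the structure of an atlas-grid modelling problem:
a few informative, spatially smooth environmental gradients; planted
high-correlation duplicates that the stage-1 filter must remove; and
pure-noise predictors that the FDR stage must screen out. Defaults are
the test-bench conditions used throughout: n = 5000 cells, three
informative gradients with standardized coefficients (1.0, −0.8, 0.6),
intercept −1 (prevalence ≈ 0.3, a moderately widespread species), five
noise predictors, and one duplicate of the strongest gradient at
r = 0.9.

Informative gradients are smooth functions (linear trend plus low-
frequency sinusoids plus local noise) of latent lattice coordinates,
standardized, and then mutually orthogonalized: the generator's contract
is that the *only* pairs above the 0.8 correlation threshold are the
planted duplicates, and independently drawn smooth surfaces on a shared
lattice can otherwise be strongly correlated by chance, which would
confound what a failed screen means. Duplicates are
`r·source + √(1−r²)·noise`, restandardized. Presence is drawn
independently per cell; the per-cell true probability is stored for
calibration tests. Degenerate draws (no presences or no absences) nudge
the intercept toward balance and redraw, failing after 10 attempts. All
randomness flows from one explicit integer seed; there is no global
random state.

What the generator does **not** emulate: spatial autocorrelation of the
residual presence process (draws are independent given the predictors),
real climate-surface marginals, survey effort or detection error, and
coordinate-system geometry. Passing tests therefore demonstrate the
correctness of the statistics and of variable recovery under the stated
generative model, not robustness to spatially autocorrelated or
imperfectly detected real atlas data.

## Problem sizes

The test suite runs its behavioural checks at the sizes that make their
guarantees meaningful while keeping the suite fast: oracle equivalence of
the stepwise move sequence on 20 random datasets with 4 candidates
(n = 300); Rao score type-I error over 1000 null replicates at n = 2000;
Hosmer–Lemeshow size over 500 replicates at n = 5000, simulated under the
fitted-model null (presence drawn from a correctly specified logistic
model, the model refit, HL applied to the fitted probabilities) because
the df = g − 2 convention presumes estimated parameters; and full-pipeline
recovery over 50 virtual species at n = 5000.

## Known limitations

- Only the binomial-logit family; no penalization, no spatial terms, no
  GAM-style smoothers.
- The stepwise search is greedy; it is oracle-equivalent to exhaustive
  single-move scoring, not to all-subsets selection.
- Shannon entropy values are comparable only across models on the same
  number of cells (maximum ln n); fuzzy entropy is the commensurable
  quantity.
- Atlas cells must be complete rows; cells with missing predictor values
  are rejected at load, not imputed.
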