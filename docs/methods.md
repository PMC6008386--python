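# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## Data model

A `CountryPanel` is a countries × variables matrix with per-variable
metadata (category `food|derived|covariate|outcome`, sex, units). Outcome
variables are always sex-specific ASRs. Missing cells are NaN throughout;
nothing is zero-filled on read, because a missing food-balance cell and a
true zero supply are different facts. A flag-free design choice follows
from this: analyses declare their own missing-data policy
(pairwise-complete for correlations, listwise for multivariable fits,
mean imputation for factor extraction) and every result records the
number of countries actually used.

Yearly supply series are long tables `(country, item, year, supply_g,
protein_g, fat_g, energy_kcal)` restricted to 1961–2011. All supplies and
prevalences must be nonnegative; validation rejects violations rather
than repairing them.

## Derived dietary variables

Food-balance data report per-item supply, protein, fat and energy but not
carbohydrates. Carbohydrate (+alcohol) energy is therefore the residual
after subtracting protein energy at 4.1 kcal/g and fat energy at 9 kcal/g.
All derived shares build on this identity:

- `% CA energy = 100·(E − 4.1·P − 9·F)/E` for the total diet;
- subset carbohydrate shares apply the same residual per item and divide
  the item-sum by total energy — the only formula consistent with the
  fixed 4.1/9 constants when no food-composition table is available;
- plant-energy share is the named items' energy over total energy;
- the protein index is the dairy/wheat protein ratio. The numerator is
  whatever protein column the caller passes (dairy-aggregate by default
  in the shipped examples; a milk-only numerator is equally valid and the
  function does not hard-code either).

Negative energy residuals (protein+fat energy exceeding reported total)
are returned as-is with a warning, never clamped: clamping would hide
inconsistent inputs. A zero wheat-protein denominator yields a missing
value with a warning instead of an exception so one degenerate country
cannot abort a 100-variable screen.

Outcome burden shares aggregate ASRs across countries by the sum of
country rates by default (equivalently the unweighted mean — both ignore
population size, which country-level ASR comparisons do by design);
`weighting="mean"` is exposed for symmetry.

## Correlation screen

Pearson r uses the sample formula at full precision; the two-sided p
comes from `t = r·√(n−2)/√(1−r²)` on n−2 df. Spearman is exactly Pearson
on average ranks (ties averaged — the common convention). Rounding to 2
decimals happens only in presentation. In matrices, sex-specific
covariates (smoking, raised cholesterol) pair only with same-sex outcomes
when sex matching is on, reproducing the blank cells of sex-stratified
summary tables. Adjusted associations standardize all variables and fit
OLS (via statsmodels); rank-deficient designs fail loudly, naming the
collinear set.

No multiple-testing correction is applied by default, matching the
screening character of the design; the per-result p and n make any
correction reproducible downstream.

## Factor analysis

Principal-component extraction on the correlation matrix, unrotated:
eigendecompose R, report loadings `v_j·√λ_j`, percent variance
`100·λ_j/p`, and country scores as standardized data projected on the
unit eigenvectors (so score variance equals λ_j). Missing values are
mean-imputed per variable before standardization because listwise
deletion across ~100 variables would annihilate a 39-row panel. The sign
of each factor is fixed by making its largest-|loading| entry positive —
eigendecompositions are sign-ambiguous and this convention makes output
identical across runs and LAPACK builds. Tiny negative eigenvalues within
`1e-8·λ_max` are clipped to zero; anything more negative is a hard error
(the input was not a correlation matrix).

## Penalized ensemble

All methods minimize

    ‖y − Xβ‖²/(2n) + λ·(α‖β‖₁ + (1−α)‖β‖²/2)

on predictor columns standardized to mean 0, SD 1 (population SDs, so
diag(X'X/n)=1) and a standardized outcome. Standardization is not
optional: the top-5 statistic ranks coefficients by magnitude, which is
meaningless across raw units. Ridge is α=0 (closed-form solve; paths via
one eigendecomposition of X'X/n), LASSO is α=1, elastic net defaults to
α=0.5. LASSO/enet use cyclic coordinate descent with soft-thresholding on
precomputed Gram products, warm-started along the descending λ path;
convergence when the largest coefficient change in a sweep is below 1e-8.
Direct fits raise a hard error (never a silent partial fit) after 100 000
sweeps; path fits first retry a stuck grid point at a ×100-relaxed
tolerance with a logged warning — near-degenerate designs such as
bootstrap resamples with p ≥ n leave a flat solution valley at small λ
where coefficient changes crawl, and 1e-6 precision is ample for
magnitude ranking — and error only if that also fails.

λ grids are 100 log-spaced points from `λ_max = max|X'y|/n / α` (KKT
zeroing threshold; α floored at 0.001 for ridge so the top stays finite)
down to `min_ratio·max|X'y|/n`. Two deliberate choices here:

- the grid floor is defined on the α=1 scale for every method. Dividing
  the floor by the α-floor as well (as glmnet effectively does for ridge)
  leaves the whole ridge grid in heavily-shrunk territory, where ridge
  coefficient ranking degenerates to marginal-correlation ranking and
  penalty selection pins to the grid boundary;
- `min_ratio` is 1e-4 when rows outnumber predictors and 1e-2 otherwise:
  with p ≥ n the ℓ1 problem has no unique solution as λ→0 and coordinate
  descent converges arbitrarily slowly there, so the grid stops short of
  that regime (the glmnet `lambda.min.ratio` convention).

Cross-validation (k=10 by default) standardizes each training fold on its
own statistics and evaluates on the transformed held-out fold; the SE per
λ is the across-fold SD of fold MSEs over √k. Bootstrap treatment draws B
row resamples with replacement (B=500 by default), fits the full path per
resample, scores out-of-bag rows, and averages coefficient vectors per λ;
resamples leaving a predictor constant are redrawn and logged. The
"optimal" rule takes argmin of the mean error curve; "parsimonious" takes
the largest λ within one SE of the minimum — the standard operational
reading of "best balance between error and number of predictors". For
ridge, where nothing is exactly zero, a predictor counts as selected when
its |β| exceeds 1e-3 of the largest.

The bootstrap's selected coefficient vector is the λ-wise mean evaluated
at the chosen λ (average-then-select); select-then-average (each
resample's coefficients at its own out-of-bag-optimal λ, then averaged)
is available behind `select_then_average`. Averaging before selecting
keeps the error curve and the reported vector consistent and is the
stability-selection-flavoured default.

The battery is the exact cross product {ridge, lasso, enet} ×
{cross-validation, bootstrap} × {optimal, parsimonious}: 12 models, 6
optimal. Top-5 ranking breaks |β| ties lexicographically by variable name
with a logged warning — arbitrary, but deterministic, which matters more.
Sign labels are positive/negative when all counted models agree, "mixed"
otherwise.

## Temporal profiles and the slope test

Outcomes are referenced to detection year 2012. For each year, the
profile correlates that single year's supplies with the fixed outcome
across countries (≥3 countries per year; unusable years dropped with a
warning). The peak is the maximum signed r by default — profiles are
framed for positively associated exposures, where the peak marks the most
aetiologically relevant lag — with max-|r| behind a flag. The long-series
(1961–2011) variant takes an explicit country-subset list rather than a
hard-coded one.

The parallelism test fits a least-squares line to each r-vs-year series
and refers `(b₁−b₂)/√(se₁²+se₂²)` to a t distribution with n₁+n₂−4 df —
the standard two-line slope-homogeneity test; the specific published
variant behind this design is not documented, so the textbook form is an
explicit assumption here. High p ⇒ parallel trends ⇒ long-term
collinearity between the exposures. This inverts the usual significance
reading, and the API exposes it as `parallel(level=0.05)`, true when
p > 0.05. Under the null of equal slopes the p-value is uniform (checked
by simulation, KS distance over 1000 replicates).

## Synthetic data generator

The generator emulates the statistical skeleton the analysis assumes, not
real food magnitudes:

- k=3 latent country factors (standard normal). Food item j loads on
  factor `j mod 3` with |loading| 0.45 — positive for the first half of
  the items (the "animal" block), negative for the second (the "plant"
  block), mimicking the affluence polarity of European diets — plus
  idiosyncratic noise (SD 0.9).
- covariates ride on factor 1 with fixed correlations (GDP 0.8, raised
  cholesterol ~0.75, etc.), placed on plausible scales.
- one outcome carries planted standardized effects (1.0, 0.9, −0.9) on
  three items in distinct factor blocks; remaining outcomes follow an
  affluence gradient (0.6 on factor 1) plus noise. Outcome noise SD is
  0.3, i.e. planted marginal correlations near 0.6 and a multivariable
  R² near 0.9 — strong-signal territory, consistent with the r ≈ 0.8
  headline correlations this literature reports, and the regime in which
  a selection-frequency ensemble is expected to separate planted from
  merely collinear variables. Under these defaults the planted variables
  strictly out-count every null variable in the top-5 table in ≈80% of
  panels; the remaining panels almost always fail by a *tie* — some null
  proxy saturates all 12 models — which is the honest face of ecological
  collinearity at n=39.
- supplies map to g/day as `mean·(1 + 0.3·z)` with item means drawn in
  15–160 g/day, clipped at zero (clip rate logged; spread automatically
  halved if it exceeds 1%).
- yearly series follow a stationary AR(1) (coefficient 0.6, relative SD
  0.08) around the panel mean, with optional linear trend. Per-item
  nutrient fractions are drawn once and energy density is built as
  `4.1·protein_frac + 9·fat_frac + carb_density`, so the energy residual
  identity holds by construction. An optional temporal signal blends one
  item's single-year supplies toward the outcome pattern on a common
  scale, planting an exact peak-correlation year.

What the generator does **not** emulate: population-weighted aggregation,
realistic item-level covariance beyond the block structure, measurement
error correlated with affluence, or secular dietary transitions. Passing
recovery tests on these panels therefore demonstrates that the machinery
identifies planted structure under the assumed model — not that the
design recovers causal effects from real ecological data.

## Problem sizes and tolerances in tests

The test-suite and verification-script sizes are chosen to make every
stochastic claim cheap to re-derive: 20 synthetic panels at the reference
conditions (39 × 68) with 100 bootstrap resamples per battery for the
recovery rate (the library default of B=500 changes counts only
marginally; 100 is this package's reporting size), 1000 replicates for
slope-test calibration, 200 for correlation-null envelopes. Solver
exactness is asserted against exhaustive grid oracles at 1e-6 on
3-predictor toys, against closed forms at 1e-8–1e-10, and against
scikit-learn's coordinate descent at 1e-5 (an independent implementation
of the same objective). Determinism is bit-for-bit under a fixed seed for
the generator, the battery, and the CLI outputs.

## Known limitations

- Factor extraction is unrotated PC extraction; percent-variance figures
  from rotated or principal-axis solutions will differ.
- The parsimonious rule for ridge still selects a λ by the one-SE rule;
  "number of predictors" for ridge is threshold-based, not exact.
- The bootstrap error curve uses out-of-bag MSE; with n=39, OOB sets are
  small and the curve is noisier than its cross-validation counterpart.
- Peak-lag detection reports the argmax year only; no changepoint or
  distributed-lag modelling is attempted.
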