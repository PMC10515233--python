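# Methods

## Model

The partial credit model (PCM) treats each item *i* as an ordered
sequence of category steps: for a person at θ (logits),

P(X_i = x | θ) ∝ exp Σ_{k≤x} (θ − δ_{ik}),   x = 0…m_i,

with the empty sum for x = 0. The step thresholds δ_{ik} need not be
increasing; a decreasing pair ("disordered thresholds") is legal in the
model and is exactly what the response-category check looks for. The
item *location* is the mean of its thresholds.

## Conditional maximum likelihood

Item estimation conditions on each person's raw score R = Σ x_i, the
sufficient statistic for θ. Writing β_{ix} = Σ_{k≤x} δ_{ik} and
ε_{ix} = exp(−β_{ix}), the probability of a response pattern given its
total score r over observed items S is Π ε_{i,x_i} / γ_r(S), where
γ_r(S) is the elementary symmetric function — the sum of Π ε over all
patterns in S with total r. The γ are computed by item-by-item
convolution **in log space** (logaddexp), which is stable for arbitrary
threshold magnitudes; the gradient uses the classic observed-minus-
expected form with leave-one-item-out γ tables.

Persons with extreme raw scores (0 or maximum over their observed
items) contribute a constant to the conditional likelihood and are
excluded from estimation; persons are grouped by observed-item subset,
so missing responses (assumed MCAR/ignorable) are handled exactly
rather than imputed.

**Identification.** The conditional likelihood is exactly flat along
β_{ix} → β_{ix} + c·x (a rigid shift of all item locations). We pin the
metric by the convention Σ_i location_i = 0, enforced through a
quadratic penalty on (Σ locations)². Because the likelihood is exactly
constant along that ray, the penalised optimum satisfies the constraint
exactly and no other direction is biased — an exact reformulation, not
a ridge approximation. A BFGS iteration with the analytic gradient runs
on the per-person-scaled objective (default gradient tolerance 1e-8,
200 iterations; a gradient norm above 1e-4 raises a convergence error
naming the norm). Standard errors come from the observed information
(central differences of the analytic gradient); they are conditional on
the sum-to-zero constraint.

**Null categories.** A category with zero observations makes the
corresponding β inestimable, so each item's observed categories are
relabelled consecutively (equivalent to collapsing a null category into
its lower neighbour); the recoding is recorded on the results object
and in the pipeline run log.

## Person estimation

Default is Warm's weighted likelihood estimate (WLE), maximising
ℓ(θ) + ½ log TI(θ); its estimating equation is
r − E[R|θ] + TI′(θ)/(2·TI(θ)) = 0, with TI′ the sum of third central
category moments. WLE is finite at extreme scores, which matters
because extreme persons must appear in targeting displays and coverage
percentages. Plain ML (infinite at the extremes) is available for
comparison. SE(θ̂) = TI(θ̂)^{−1/2}. Because the raw score is sufficient,
estimation runs once per (item-subset, raw-score) group.

## Item fit

Residuals standardize each response against PCM moments. Two bases are
offered:

* **conditional** (default for fit statistics): moments of X_i given
  the person's raw score, from the ESF tables. These are the moments
  the conditional likelihood actually constrains; the resulting mean
  squares are centred at 1 under the model.
* **theta**: moments at the WLE θ̂. This is the conventional basis for
  residual PCA and Q3 screening and the default there. It is *not*
  used for the mean squares because locating each person absorbs
  roughly one degree of freedom per person, deflating MSQ visibly
  below 1 (we measured 0.83–0.99 under the generating model at
  n = 2000 with 14 items).

Outfit is the unweighted mean of z² per item; infit weights by the
conditional variance, Σ(x−E)²/ΣVar. ZSTD uses the Wilson–Hilferty
cube-root transform with the model-based variance built from fourth
central moments: outfit q² = Σ(C/W²)/N² − 1/N, infit
q² = Σ(C − W²)/(ΣW)², ZSTD = (MSQ^{1/3} − 1)(3/q) + q/3. Screening
bounds (MSQ 0.7–1.3, |ZSTD| ≤ 2) are **inclusive**: a value exactly on
the bound is not flagged. Because ZSTD magnitudes grow with n, the
subsampling protocol averages ZSTD over k random subsamples (default
k = 40 of n = 300) with item parameters held fixed from the full fit
(refitting per subsample is available via `refit=True`); with fixed
parameters the per-person moments are subsample-invariant, so the
implementation computes the residual matrix once and resamples rows.

## Dimensionality

Eigendecomposition of the item × item Pearson correlation matrix of
standardized (theta-basis) residuals, pairwise-complete over missing
entries. Eigenvalues sum to the item count; first-contrast loadings are
the leading eigenvector scaled by √λ₁, oriented so the largest loading
is positive — their signs separate the item clusters of a secondary
dimension. Residual pair correlations (Yen's Q3 convention) are
screened against the *relative* cutoff mean(all pairs) + 0.2; because
residual correlations are negatively biased on average (the fitted
dimension is removed), an absolute cutoff would be miscalibrated. The
verdict is multidimensional iff λ₁ ≥ 2.0 or any pair exceeds the
cutoff, with the triggering values listed.

## Differential item functioning

Two-group DIF fits the PCM by CML within each group, equates the
metrics by forcing the mean location of an anchor item set to agree,
and sizes DIF as the absolute anchored location difference (cutoff
0.5 logits). The anchor starts as all items and is purified (flagged
items removed, at most 3 rounds). The global invariance test is a
likelihood-ratio chi-square of group-specific versus joint item
parameters (df = free item parameters). For ordered covariates, all
cuts leaving ≥ 50 persons per side are scanned with this statistic and
the winner's p-value is Bonferroni-corrected for the number of
candidate cuts — a one-level stand-in for model-based recursive
partitioning, adequate when one split per covariate is of interest
(the trees in applied reports rarely go deeper); its p-value is not
numerically comparable to a tree's parameter-instability test. Age
dichotomisations at 31 and 20 years ship as presets.

## Targeting and reliability

Targeting reports means/SDs of the person WLE distribution and of the
item locations, plus histograms of persons and pooled step thresholds
on one logit axis (Wright-map style). The step parameters δ themselves
are used as threshold locations (not Thurstonian thresholds); callers
can substitute their own.

Reliability is conditional: TI(θ) = Σ Var(X_i|θ) over a θ grid
([−6, 6] step 0.01, widened to cover all person estimates), and
PSI(θ) = 1 − 1/TI(θ), clipped at 0 below TI = 1. The profile reports
the interval(s) where PSI clears the threshold (endpoints linearly
interpolated between grid points), the percentages of persons inside /
above / below (extreme persons included via their finite WLE
locations), and the percentages beyond the most extreme thresholds. No
single-number reliability coefficient is computed — the information
function is a property of the items, not of a particular sample.

## Score conversion

For a completely answered item subset the raw score determines the
measure: interior scores solve E[R|θ] = r by bracketed root-finding
(tolerance 1e-10; the solution is unique by strict monotonicity of the
expected score), which coincides with ML scoring; the extreme scores 0
and max are located by WLE so the table stays finite. SE = TI(θ)^{−1/2}.
Tables are built per named subset (e.g. `negative7`) and only apply to
complete response patterns.

## Synthetic data

The generator draws PCM responses category-wise from each person's
trait value, with: a normal person distribution; an optional two-trait
structure (bivariate normal, unit SDs scaled by the person SD,
correlation ρ; each item answers exactly one trait — the minimal
structure matching a two-wording-cluster instrument); group-specific
item-location shifts applied to the thresholds before sampling (DIF);
and MCAR missingness (each person keeps at least one response). Person
covariates mimic a university-student sample: age ⌊N(28.8, 8.2²)⌉
clipped to 18–65, 67.2 % female. The `pss_like_preset` fixes the study
geometry: 793 persons, 14 five-category items split 7 negative / 7
positive across two traits (default ρ = 0.5), persons ~ N(0.88, 1.57²),
item locations spread over −0.7…1.7 logits with steps at ±0.4 and ±1.2
around each location.

What the generator does **not** emulate: response styles, informative
missingness, local dependence beyond the two-trait structure, or
discrete/skewed person distributions. Passing recovery tests on this
generator therefore validates the estimation and screening machinery,
not the behaviour of any particular field sample.

## Numerical and design notes

* ESFs and category probabilities are computed in log space throughout;
  thresholds of magnitude several hundred logits remain finite.
* Parameter-recovery checks use the preset at ρ = 1.0: with ρ < 1 the
  unidimensional PCM is deliberately misspecified and its thresholds
  need not converge to the generating values.
* Root-finding brackets for person estimation start at ±15 logits and
  expand geometrically if the score function has not changed sign.
* Reverse-coding policy: for combined-scale analyses the positively
  worded items are reverse-coded (x → m − x) so all items point in the
  distress direction; subscale analyses keep raw orientation. Both are
  switchable (`reverse_code_positives` in the run config).
* PSS-10/PSS-4 item memberships follow the standard published short
  forms; they are presets, not data-derived.
* Simulation sizes in the test suite (n = 2000 for recovery/null
  checks, n = 300–1000 for pipeline smoke tests, 40×300 for the
  subsample protocol) were chosen to keep Monte-Carlo error well below
  the tolerances being asserted.

## Known limitations

* CML handles only the Rasch family: no discrimination parameters, no
  MML or Bayesian estimation, no multidimensional fitting (the
  dimensionality stage *screens*; it does not fit a two-factor model).
* The LR split search examines one covariate at a time, one level deep.
* Fit-statistic null distributions are approximated by the
  Wilson–Hilferty transform, not bootstrapped.
* Q3 correlations use pairwise-complete residuals; with heavy
  missingness the correlation matrix can be non-PSD (eigenvalues are
  reported as computed).
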