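# Methods

`prevmap` estimates small-area (municipal) prevalence of chronic diseases
from administrative predictors in three steps: individual disease
probabilities are predicted by L1-penalized logistic regression fitted on a
diagnosed training subset; the predicted probabilities are averaged per
municipality; and the municipal averages are optionally age-standardized
and grouped into septiles for mapping. Internal validity is assessed by an
outer cross-validation loop that compares out-of-fold municipal estimates
with registry-observed prevalence through a weighted percentage error and
by the AUC of the pooled out-of-fold predictions.

## Model and estimation

For disease *d* and individual *i* with predictor vector *x<sub>i</sub>*,

> logit P(y<sub>i</sub> = 1) = β₀ + x<sub>i</sub>ᵀβ,

fitted by maximizing the penalized average log-likelihood with an L1
penalty λ‖β‖₁ (intercept unpenalized). Municipal prevalence is

> P<sub>m</sub> = (1/n<sub>m</sub>) Σ<sub>i∈m</sub> p̂<sub>i</sub>,

the average of predicted probabilities over all residents of municipality
*m*, which conserves expected case counts under aggregation to any
regional level.

### Solver

The path solver (`prevmap._solver`) is proximal Newton with cyclic
coordinate descent, in the style of the standard coordinate-descent
packages for penalized GLMs: predictors are standardized internally
(penalty applies on the standardized scale; coefficients are reported on
the input scale), fits are warm-started along a decreasing
geometric grid of 100 lambdas from the critical value that zeroes every
slope down to a fraction `lambda_min_ratio` (default 0.01) of it, and
screening uses the sequential strong rule with a full
Karush–Kuhn–Tucker pass admitting any screened-out violator. Convergence
is declared on the true KKT stationarity conditions, default tolerance
1e-7 (so fitted paths satisfy stationarity by construction); fold fits
inside cross-validation use 1e-5, since the misclassification curve is
insensitive at that scale. Quadratic approximations floor the probability
weights at 1e-5 and clip linear predictors at ±30, the usual safeguards
near separation. Constant columns are kept in the design but frozen at
zero coefficient.

### Shrinkage-parameter rule

λ is chosen from the 10-fold cross-validated misclassification curve
(classification threshold 0.5, stratified folds) as the larger-model of
two candidates: (a) the largest λ whose mean error is within one standard
error of the minimum (SE = sd over folds / √k), and (b) the largest λ
whose fit retains at least 10 nonzero predictors. Whichever candidate fit
has **more** nonzero predictors is selected; ties go to the larger λ. When
no grid point reaches 10 predictors (e.g. the age/gender model has only
3 columns) the smallest grid λ is used with a warning — effectively a
near-unpenalized fit, which is the natural meaning of an age/gender-only
model. The 0.5 threshold and "largest λ within one SE" reading are the
conventional definitions; stratification protects rare outcomes.

## Predictor sets (model variants)

* `age_gender` — age/100, (age/100)², female (3 columns).
* `medication_only` — the retained ATC3 dispensing indicators, plain.
* `sociodemographic_only` — every level of each categorical covariate as
  its own indicator (no reference cell dropped; the unpenalized intercept
  plus L1 penalty absorbs the induced collinearity), degree 1–3
  polynomials of the income and wealth percentile scores, the female
  indicator, the two age terms, and the interaction of every base column
  with both age terms.
* `complete` — socio-demographic and ATC blocks together, all interacted
  with the age terms.

Ages and percentile scores are divided by 100 before powers and products:
unscaled cubics of percentiles (up to 10⁶) would destabilize the penalized
solver, and the L1 penalty is not scale-invariant. Coefficients are
reported on this rescaled basis. Interactions are taken with age terms
only, never between socio-demographic variables or between drug groups.
ATC3 codes dispensed to 50 or fewer persons in the population are excluded
from the predictor set. Column counts are a deterministic function of the
schema; no fixed total is targeted, since the count depends on the
configured levels and retained codes.

## Small-area estimation

Age standardization is direct. Ages are grouped into 15 half-open bands:
under-20, five-year bands [20,25) … [80,85), and 85-plus. Each individual
receives weight w<sub>i</sub> = (reference share of their band) /
(municipality share of their band), and the standardized prevalence is
Σw<sub>i</sub>p̂<sub>i</sub>/Σw<sub>i</sub> within the municipality —
algebraically identical to band-wise direct standardization when every
band is occupied. The national population is the default reference. If a
band is empty in a municipality, the reference shares over its occupied
bands are renormalized (equivalent to dropping the band from the standard
for that municipality) and a warning is logged; a band occupied locally
but absent from the reference is an error. The weighted form
Σwp̂/Σw is used rather than (1/n)Σwp̂ — identical when weights average to
one, and well-defined otherwise.

Municipalities are grouped into septiles (7 near-equal rank groups,
sizes differing by at most one) for map shading; ties are broken by
municipality id so labels are deterministic. Septiles are unweighted
municipality ranks, not population-weighted.

## Validation

Observed prevalence O<sub>m</sub> is the registry case share among a
municipality's training rows. The weighted percentage error is

> WPE = Σ<sub>m</sub> w<sub>m</sub> · e<sub>m</sub>,  e<sub>m</sub> = (P<sub>m</sub> − O<sub>m</sub>)/O<sub>m</sub>,

with weights proportional to training subpopulation size, renormalized to
sum to one over the included municipalities, and reported in percent. Only
municipalities with **more than 500** training persons enter (observed
prevalence is unstable or zero below that). The absolute-error form
|e<sub>m</sub>| is the default — an "error" reported as a positive
percentage — with the signed form retained for bias diagnosis; signed
WPE ≤ absolute WPE always, with equality only when all municipal errors
share a sign.

The outer validation loop splits training rows into 5 stratified folds by
individual; for each fold the entire procedure (path, internal 10-fold
CV, λ selection) is rerun on the remaining folds, and held-out rows
receive out-of-fold probabilities, so every training row is predicted
exactly once by a model that never saw it. AUC uses the Mann–Whitney rank
formulation with half-credit for ties.

## Synthetic-data generator

The generator (`prevmap.synthetic`) emulates a linked national
administrative extract: municipality membership with configurable size
dispersion, GP-practice clusters, an age mixture over the 15
standardization bands calibrated to a national mean age of 40.3 years,
categorical socio-demographics drawn at published national marginals
(marital status, ethnic group, immigrant generation, household type,
income source; columns that print to slightly over 100% from rounding are
renormalized), discrete-uniform income/wealth percentile scores 1–100
(a percentile score is uniform by definition; an optional latent-normal
municipality tilt is available), and binary ATC3 indicators.

Disease ground truth follows a logistic model with a Normal municipality
random effect on the logit scale. The source registries publish no
generative model; mirroring the analysis model keeps parameter recovery
well-posed and makes the municipal random-effect sd the single dial for
true geographic heterogeneity. Medication indicators are Bernoulli given
disease status: linked codes at `use_prob_diseased` vs `use_prob_healthy`,
noise codes at a background rate. The training subset is sampled by whole
GP practices (a registry covers entire practices), stopping when the
selected share is closest to the target fraction; simple random sampling
is available for variance comparisons. Diagnosis-code flagging implements
the union rule over GP (ICPC-1) and hospital (ICD-9/ICD-10) records with
prefix matching; code ranges such as I20–I25 are expanded to explicit
prefixes at load time.

Reference conditions (`benchmark_config`): 100,000 persons in 50
equal-sized municipalities, municipality random-effect sd 0.3, 30 ATC
codes of which 3 linked to the studied disease (use probability 0.7
diseased vs 0.05 background), training fraction 0.10 by cluster sampling
with 4 practices per municipality. A smaller `demo_config` (40,000
persons, two diseases) serves the command-line demo.

What the generator does **not** emulate: record-linkage failure and
hospital under-registration, multi-year longitudinal structure (a single
cross-section is generated; the real registries collapse a decade of
history into one cross-section), within-municipality prescriber
variation, and spatial correlation between neighboring municipalities.
Passing tests therefore demonstrate correctness of the estimation
machinery and recovery under the stated generative model, not performance
on real registry data.

## Numerical and design choices

* One master seed; every stochastic stage derives an independent named
  stream from it, so components are individually reproducible and outer
  folds are shared across model variants (paired comparisons).
* Age bands are half-open on integer ages; the boundary convention is
  ours to fix.
* WPE weights are renormalized after the >500 filter so they always sum
  to one.
* The λ-rule tie at equal nonzero counts resolves to the larger λ.
* Evaluation against generative truth (synthetic data only) uses no
  training-size filter: the filter exists because observed O_m can be
  zero in small training subsets, which cannot happen for the generative
  truth of a 2,000-person municipality at the prevalences studied.
* Validation tests run the full procedure at reduced problem sizes
  (thousands of rows, tens of predictors) chosen so the whole suite runs
  on a laptop; the reference-condition comparison of model variants uses
  the full 100,000-person configuration for 20 seeded replicates.

## Known limitations

* Misclassification error at threshold 0.5 is insensitive for very rare
  outcomes; the ≥10-predictor branch of the λ rule exists precisely to
  keep such models from collapsing to the null.
* Municipalities without training rows receive model estimates but cannot
  enter the WPE; cluster (practice) sampling concentrates training data
  in a subset of municipalities.
* No spatial smoothing: estimates borrow no strength across neighboring
  municipalities by design, so the method measures what the individual
  predictors alone can localize.
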