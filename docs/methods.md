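# Methods

`carabidfa` implements a three-layer analysis of ground-beetle (Carabidae)
responses to forest management — from assemblage composition, through
species-level trait models, down to individual-level developmental
instability. This note documents the statistical procedures, the synthetic
data model behind every parameter-recovery test, the numerical choices, and
the known limitations.

## The three layers

### Layer 1 — assemblage ordination

Species composition is related to environmental constraints by **partial
canonical correspondence analysis** (pCCA). With `P` the abundance matrix
scaled to sum 1, row weights `r` (sample totals) and column weights `c`
(species totals), the standardized chi-square contribution matrix is

    Q̄ = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2},

whose total sum of squares is the inertia. Covariables (collection month as
categorical dummies, air temperature as a continuous term) are removed by
weighted projection of both `Q̄` and the constraints off the covariable
span; the canonical eigenvalues are the squared singular values of the
projection of the residual `Q̄` onto the residual constraint span. A dense
generalized-eigenproblem oracle and scikit-bio's unpartialled CCA verify the
eigenvalues in the test suite to 1e-8.

Abundances are `ln(y+1)`-transformed and **rare species downweighted** by
the classical frequency-threshold rule: a species occurring in `f` samples
is weighted `min(1, f/(f_max/5))`.

Significance uses a **restricted Monte Carlo permutation test**: samples
form site-level time series over the six 25-day collection periods, and
each permutation applies an independent random cyclic shift to each site's
series (the zero shift is in the permutation set, so
`p = (1+#{F* ≥ F})/(1+n_perm) > 0`). This conditions inference on all
between-site structure. Consequence worth knowing: a predictor that is
constant within sites (e.g. a treatment dummy) is invariant under every
permutation and gets `p = 1` — such block-level effects are reported but
untestable under this scheme, and the synthetic gradient therefore carries
a genuine month-to-month component (see below).

**Forward selection** greedily adds the candidate with the largest
conditional (extra) explained variation given the covariables and the
already-selected set, tests it with restricted permutations at its point of
entry, and reports every candidate; Benjamini–Hochberg FDR adjustment runs
across the candidate list. Because "explained variation" can mean raw or
small-sample-adjusted shares, both are reported (`explained_fraction`,
`explained_adjusted` with the Ezekiel correction).

Trait summaries are passively projected: **CWM** (`Σ p_si x_i`) per sample
and **Rao's quadratic entropy** (`Q_s = Σ_ij d_ij p_si p_sj`; with unit
distances it reduces to Gini–Simpson `1 − Σp²`). Projection arrows are
weighted least-squares coefficients of the centered summary on the LC site
scores and do not touch the eigen-structure.

### Layer 2 — trait screening and head-width models

A trait enters modelling only after screening: **measurement error** via the
Palmer–Strobeck sides × individuals two-way mixed ANOVA on the two replicate
photographs per side — the side × individual mean square carries the
asymmetry signal, the residual mean square the digitising error, and the
signal is *resolvable* only when `MS_{S×I}/MS_err` is significant;
**treatment variability** (one-way ANOVA); **normality among individuals**
(Shapiro–Wilk); and an ecological-relevance allowlist (not computable from
the data). The `%ME` statistic is the measurement-error share of the
replicate-averaged side-difference variance,
`100·(σ²_e/m)/(σ²_{S×I} + σ²_e/m)`.

Outliers are masked by **iterative Grubbs testing** (two-sided, α = 0.05 per
species per trait): repeatedly remove the single most extreme value while
the Grubbs statistic exceeds its critical value. The mask is returned; data
are never mutated.

Head width is modelled in a **prestep** (full fixed-effects fit of wing-morph
score, sex and body size; candidates with Wald p > 0.05 dropped), then a
**REML mixed model** with treatment and the retained predictors as fixed
effects and random intercepts for collection month and
replicate-within-individual, summarised by a Wald chi-squared table and
Nakagawa marginal/conditional pseudo-R². Wing morphology is an ordinal
score treated as numeric (apterous 1, brachypterous 2, macropterous 3).

The **Bayesian head-width model** extends the design with per-treatment
wing-morph slopes and reports conditional effects on a wing-morph 1..3 ×
treatment grid.

### Layer 3 — fluctuating asymmetry

The per-individual index is the size-standardized signed asymmetry with the
cohort directional-asymmetry term removed:

    s_i = (R_i − L_i) / (0.5 (L_i + R_i)),   FA_i = s_i − (1/N) Σ_j s_j,

computed on replicate-averaged sides over the `N` individuals of a species ×
trait cohort (minimum N = 5). The cohort mean of `FA` is zero by
construction; `s` is dimensionless, antisymmetric under side swap and
invariant to unit changes — all asserted to 1e-12 in the tests. Models of
"FA size" use `|FA|` by default, with `FA²` and signed switches available.

The **gate battery** classifies each cohort:

| gate | statistic | flag |
|---|---|---|
| measurement error | sides × individuals ANOVA `MS_{S×I}/MS_err` | not significant → `ME_dominated` |
| antisymmetry | one-sided platykurtosis test on `s` | excess kurtosis significantly < 0 |
| directional asymmetry | one-sample t of the *uncorrected* `s` vs 0 | two-sided p < α |
| size dependence | regression ANOVA of `|R−L|` on right-elytron length | p < α (annotates, does not exclude) |

Verdict precedence is `ME_dominated > antisymmetry > DA > size_dependent >
true_FA`; only `true_FA` and `size_dependent` cohorts (the latter with body
size as covariate) proceed. The DA test must run on uncorrected `s` — on
the corrected index it is identically zero, and a guard test asserts this.

Downstream models: a treatment mixed model (month and
replicate-within-individual random intercepts; Wald chi-squared; Tukey
LS-means via the studentized-range distribution on model-based means), the
staged interaction sequence (wing-morph × sex, treatment × wing-morph, then
the combined model with sex × treatment) with median-centered Levene
variance checks, **Kendall's W** concordance across ≥ 3 true-FA traits of a
species (tie-corrected, `χ² = m(n−1)W`, Bonferroni across species), and a
**Bayesian FA–environment model** whose fixed effects are the
Layer-1-selected environmental variables (defaulting to Formica activity,
Collembola activity, litter, canopy openness, herb cover, air temperature
and soil moisture), standardized, with month, replicate-within-individual
and sex as group effects.

## Bayesian machinery

Both Bayesian stages are Gaussian-likelihood linear models with Gaussian
priors, with two interchangeable backends:

* **conjugate** (default): the response is standardized and the model is the
  Normal–Inverse-Gamma family, `β|σ² ~ N(0, σ²·diag(τ²))`,
  `σ² ~ Inv-Gamma(2, 0.5)`; prior scales are τ = 2.5 on standardized fixed
  coefficients, 10 on the intercept and 1 on group-effect blocks (ridge-style
  partial pooling at fixed scale). Posterior draws are exact i.i.d. samples
  from the closed-form posterior, organised into 4 chains of
  `iterations/2` draws each (3000 iterations for the head-width model, 4000
  for the environment model, mirroring the sampling configuration the
  analysis is specified with).
* **emcee**: affine-invariant ensemble MCMC on the same likelihood with
  fixed-scale priors; used as an independent cross-check in the tests.

Diagnostics come from arviz: per-parameter split R-hat and bulk ESS
(thresholds 1.01 for Layer 2; 1.2 for the environment model, whose verdict
is advisory — results are emitted flagged, never suppressed), PSIS-LOO, and
the percentage of observations with Pareto-k ≤ 0.7 as the predictive
reliability figure. An effect is *significant* when its central 95%
credible interval excludes zero; `prob_direction` reports the posterior
mass on the dominant sign.

Coefficients are reported on the standardized scale throughout — the
convention for comparable effect sizes across predictors.

## Synthetic data model

The generator is the ground truth for every recovery experiment. For a
bilateral trait the signed side difference of individual *i* is

    R − L = (δ + FA_i + A_i) · (1 + γ·z_i),

with `FA_i ~ N(0, σ_FA²)` (fluctuating asymmetry), `δ` the directional
shift, `A_i = ±a` a symmetric two-point antisymmetry mixture (excess
kurtosis −2a⁴/(σ²+a²)², i.e. −2 in the pure case), `γ` the size-dependence
slope on the body-size z-score, and independent `N(0, σ_ME²)` replicate
noise per side per photograph. Trait size scales allometrically as
`base·(body/median)^slope`; negative lengths are resampled (truncation).
Useful moments: `E[R−L] = δ`; `Var(R−L) = σ_FA² + a² + 2σ_ME²` for
single-replicate sides and `σ_FA² + a² + σ_ME²` after averaging the two
replicates per side (each averaged side contributes σ_ME²/2).

The **archetype card** (one pure component per class, all others near zero)
uses scales realistic for ~0.4 mm antennal/palp segments: σ_FA = 12 µm,
σ_ME = 2 µm, δ = 2σ_FA, a = 25 µm, γ = 0.6; cohorts of 60 individuals.
Because the paper-scale effect sizes of the asymmetry components are not
published, these are repo choices, fixed once. Note an inherent property of
the gating design: a pure-FA cohort is correctly labelled only when three
independent α = 0.05 gates all stay silent, so its expected recovery is
0.95³ ≈ 85.7% — the per-class recovery of `true_FA` necessarily sits close
to that value; the other classes sit near 90–95%.

The **community generator** draws Poisson abundances from Gaussian niche
responses on a latent open-canopy gradient (clearing +1, ecotone 0,
control −1, plus a month-to-month within-site component of SD 0.4
emulating seasonal variation; without that component the cyclic-shift
permutation test would have nothing it is allowed to disturb). Environment
variables couple to the gradient with fixed signs (herbs +, canopy openness
+ in clearings, litter −, …). `association = 0` severs all env–species
coupling and is the null for calibration. Samples are 6 sites × 6 periods
= 36; 26 background species plus the four focal taxa.

The study design is emulated as 3 treatments × paired transects × 6
periods × 2 sexes, wing morphs drawn A/B/M with probabilities
0.25/0.35/0.40, body size log-normal (median 5 mm, CV 8% — right-elytron
scale of small carabids). What the generator does **not** emulate: trap
capture processes and phenology, spatial autocorrelation beyond the site ×
month blocks, inter-trait correlation of FA within individuals, and
non-Gaussian measurement error. Passing recovery tests therefore show the
estimators work under the declared model, not that real data satisfy it.

## Numerical choices

* Aliased (rank-deficient) constraint columns are dropped after weighted
  centering/partialling with a warning (SVD rank tolerance 1e-10 relative).
* Variance components estimated at ≤ 1e-6 × residual variance mark a
  singular mixed fit; the term is dropped and the model refit, degrading to
  OLS when none remain (which also makes the OLS limit exact). The REML
  surface is nearly flat close to a zero component and gradient optimizers
  can stall at spurious points, so Powell and the default optimizer are
  raced and the higher restricted likelihood kept.
* scipy's Anscombe–Glynn kurtosis transform loses the statistic's sign for
  extreme platykurtosis (cube root of a negative ratio); the antisymmetry
  test restores the sign from the sample excess kurtosis relative to its
  null expectation −6/(n+1) before taking the one-sided p.
* The median-centered Levene test is conservative in small samples
  (empirical level ≈ 0.043 at 4 × 60 under normality); the calibration
  experiment therefore evaluates it at group sizes (4 × 100) where the
  asymptotic test operates at its nominal level.
* Permutation p-values live on the lattice `{1/(n+1), …, 1}`; cyclic-shift
  draws are independent per block and per permutation.
* Grubbs masking breaks ties on the first index and always terminates;
  zero-variance and n < 3 inputs are identity masks.
* All generators and samplers are pure functions of (spec, seed); a run
  seed fans out to CRC-keyed per-stage child seeds so stages are
  independently reproducible.

## Problem sizes

Default experiment sizes: archetype recovery 5 classes × 200 cohorts of 60;
calibration 500 null replicates per test (250 for the permutation test,
each with 99 permutations on 36 × 8 communities); slope recovery 200
replicates at n = 300; credible-interval coverage 100 replicates at n = 80;
ordination oracle 20 random ≤ 6 × 6 matrices. These sizes put Monte Carlo
error comfortably inside the tolerance bands while keeping a full
verification run around a minute on one core.

## Limitations and open interpretation points

* The index formula's "quadratic transformation" of the corrected FA is
  ambiguous in the source methodology; the index is computed as printed
  (signed, mean-centered) and the magnitude transform for "FA size" models
  defaults to `|FA|`, with `FA²` available.
* Whether the DA t-test should use `s` or raw `R − L` is not specified;
  `s` is used, consistent with the index definition.
* Antisymmetry has no stated detection method in the source; the one-sided
  platykurtosis test is the standard diagnostic and the generator's
  two-point mixture provides its closed-form target.
* The gate precedence order is a package decision; the categories are
  listed without an order in the source methodology.
* Treatment-level (block-constant) constraints are untestable under
  within-block cyclic shifts (p ≡ 1); their conditional contributions are
  still reported.
* "Grass coverage" and herb cover are treated as the same variable.
* R-hat "below 1.0" is unattainable (R-hat ≥ 1 asymptotically); 1.01 is
  used for Layer 2 and the stated 1.2 for Layer 3.
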