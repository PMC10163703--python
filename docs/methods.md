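# Methods

## Outcome model and assumptions

All analyses assume a positive outcome whose logarithm is normally
distributed given exposure and covariates,

    log Y = α₀ + Σⱼ αⱼ zⱼ + f(d) + ε,   ε ~ N(0, σ²),  f(0) = 0,

with additive covariate effects. Under additivity the benchmark dose —
the solution of f(d) = log(1 − BMR), i.e. a BMR-fraction reduction of the
geometric mean of Y — does not depend on the covariate values, which is what
makes a single regulatory number possible. Outcomes are stored
log-transformed throughout; the CSV reader performs the transformation and
logs it. Raw-scale modelling and quantal endpoints are out of scope.

Doses are non-negative concentrations (ng/mL). For four-column PFAS data
the single-exposure models act on the summed concentration (the equal-weight
index); the mixtures module generalises this.

## Dose-response families

* **linear** f(d) = β·d and **piecewise** f(d) = β₁·min(d,d₀) + β₂·(d−d₀)₊
  are linear in their parameters. The piecewise break d₀ is fixed in
  advance (default: median observed dose), and the function is defined at
  d₀ by continuity (both branches agree there).
* **K-power** f(d) = β·d^K with K ≥ 1. For fixed K the model is linear in
  β, so K is profiled: a 141-point grid on [1, 15] followed by a bounded
  scalar minimisation around the grid optimum (xatol 1e−9). The regressor
  is internally scaled by the maximum dose to keep the design conditioned at
  large K. K̂ < 1 + 1e−6 is snapped to 1 and flagged (`boundary_K`), where
  the model coincides with the linear fit.
* **hockey stick** f(d) = β·(d−γ)₊. The threshold is profiled over a
  deterministic grid of 200 points spanning [0, 95th dose percentile]; at
  each candidate the model is OLS in β. The *global* grid minimiser is
  returned — local search is known to stop in local minima of this
  non-concave profile — with numerical ties (relative RSS within 1e−9)
  broken toward the smaller threshold. `is_boundary` flags a minimiser at
  or below the smallest observed dose, where every γ gives the identical
  (linear-model) fit because the intercept absorbs −βγ.

  A caveat documented deliberately: on data that are truly linear, the
  global minimiser is often *not* in that flat region. For γ between the
  two smallest doses the hockey model equals a linear model with the lowest
  design point moved to γ, so some interior threshold strictly improves the
  RSS whenever the low-dose residuals happen to favour it — roughly half
  the time per candidate. Threshold estimation is intrinsically unstable
  when the data carry no threshold information; this is the reason the
  hockey stick is not recommended for benchmark use here, and why its
  bootstrap BMDL falls back to the linear limit at the boundary (below).

## BMD expressions

Closed forms, each returning NaN with a diagnostic (never a silent number)
when the fitted slope is not adverse:

* linear: log(1−BMR)/β (β < 0);
* hockey: γ + log(1−BMR)/β (β < 0);
* K-power: (log(1−BMR)/β)^(1/K) (β < 0);
* piecewise: log(1−BMR)/β₁ when β₁ < 0 and that value is ≤ d₀; otherwise
  d₀ + (log(1−BMR) − β₁·d₀)/β₂ when β₂ < 0. This is forced by solving
  f(d) = log(1−BMR) segment by segment; the unit tests check every family
  against an independent root-finding oracle on f.

## BMDL methods

**Closed form** (linear and piecewise only). A pointwise one-sided lower
confidence limit for f(d) is LC(d) = ĉ(d)ᵀβ̂ − t(df, 1−α)·se(ĉ(d)ᵀβ̂), with
ĉ(d) the f-regressor vector at dose d and the covariance taken from the
df-corrected OLS fit; the BMDL is the smallest d with LC(d) = log(1−BMR)
(vectorised scan for the first crossing, then Brent root-finding in the
bracketing cell; expanding upper bound, NaN with a flag if LC never
crosses). For the linear family this reduces to
log(1−BMR)/[β̂ − t(df, 95%)·se(β̂)], whose coverage is exactly 1 − α at any
sample size because (β̂ − β)/se is exactly t-distributed. The t percentile,
not the normal, is used throughout.

**Profile likelihood** (any family). The model is reparametrised so the
BMD is a parameter: fixing a candidate BMD = b pins the linear f-coefficient
through f(b) = log(1−BMR), leaving OLS in the remaining parameters (for the
piecewise family via a modified regressor; for K-power and hockey with an
inner 1-D search over the shape parameter). The BMDL is the smallest b whose
deviance 2[logL(θ̂) − logLₚ(b)] = n·log(RSSₚ(b)/RSŜ) is at the χ²₁ 90th
percentile (2.7055; the one-sided 95% limit inverts a two-sided 90%
region), located by halving below the BMD estimate to bracket the cut-off
and Brent's method inside the bracket (relative tolerance 1e−10, tighter
than needed). The defining equation is verified in tests: the deviance at
the returned BMDL equals 2.7055 to 1e−3.

**Parametric bootstrap** (any family). Outcomes are re-simulated at the
observed doses and covariates from the fitted Gaussian model (ML variance),
the model is refitted, and the BMDL is the empirical α-percentile (linear
interpolation) of the BMD estimates. Replicates with an undefined BMD enter
as +∞ — conservative for a lower percentile and rank-preserving — and are
counted; more than 50% undefined makes the BMDL itself undefined. For a
hockey fit whose threshold sits at the boundary the bootstrap runs under the
linear model with a diagnostic flag, rather than resampling an unidentified
threshold. Identical data and seed give bit-identical results.

**Model retention.** Models within 2 AIC units of the best AIC among models
with a *defined* BMDL are retained; the reported BMDL is the smallest
retained one. Undefined-BMDL models are excluded with a logged note.

## Likelihood and parameter-count conventions

logL is the Gaussian likelihood at the ML variance σ̂² = RSS/n (for grouped
data, Σ n_g r_g²/K with the group-size log-weight term included), so AIC =
−2 logL + 2p is comparable across families. p counts all mean-structure
parameters — including the profiled K or γ — plus σ². Covariances for
t-based intervals use the unbiased variance RSS/df with df = n − (mean
parameters); for K-power and hockey they are conditional on the profiled
shape parameter.

## Summary (decile) data

Group means satisfy Ȳ_g = α + β·d̄_g + ε_g with ε_g ~ N(0, σ²/n_g), so the
linear (and, with the break at a group boundary, piecewise) parameters are
estimated without bias by WLS with weights n_g — at a larger variance, which
is why decile BMDLs tend to be lower than individual-data BMDLs. Grouping
is by stable dose ranking into K near-equal groups; boundaries are type-7
quantiles; group-mean covariates are carried as regressors (valid under the
additive linear model by the same algebra — the model allows p = 0, so
unadjusted decile analyses are the same code path). The noiseless-data
identity between summary and individual slopes is exact; with noise only
unbiasedness holds, since the individual OLS slope also uses within-group
dose variation. For nonlinear f the diagnostic |f(d̄_g) − mean_g f(d)|
quantifies the grouping bias driver; it is zero for linear f and shrinks as
K grows. The default piecewise break for decile data is the median group
boundary. Group means are formed on the log-outcome scale, consistent with
the outcome model.

## Mixture index

The index is 4·(w₁·PFOA + w₂·PFOS + w₃·PFHxS + w₄·PFNA) with non-negative
weights summing to one; equal weights recover the summed concentration
exactly (the index is built by an unrolled left-to-right sum so the equality
is bit-for-bit). Equal potency is tested by a likelihood-ratio test (df 3)
of the summed-index model against four free slopes; index adequacy by the
two-sided t-test of one compound added to the index model. Weights are
estimated by constraining the four exposure slopes to be non-positive
(box-constrained least squares, BVLS — exact at this size and verified in
tests against enumeration of all 2⁴ active sets), normalising
θ̂_k/Σθ̂, and averaging over 1000 nonparametric bootstrap resamples of
subjects (the parametric bootstrap is reserved for BMDL work). Replicates
with all slopes at zero carry no relative-potency information and are
dropped and counted (equal-weight imputation would bias toward the summed
index); >20% dropped raises a warning. With standardisation the exposures
are centred and scaled once on the original data and the weights are
reported on that scale, flagged — no back-transformation is applied, and
index benchmark results are conditional on fixed weights (their uncertainty
is not propagated, so those BMDLs may be optimistic).

## Synthetic cohorts and the coverage experiment

The generator draws four correlated log-normal exposures — the correlation
matrix applies on the log scale, where dependence of concentrations is
naturally modelled — with marginal medians (4.0, 15.0, 0.6, 1.0) ng/mL,
log-scale SD 0.5 and pairwise correlation 0.5; covariates are standard
normal; the outcome follows the model above. Presets: `faroese-like`
(n = 500, two covariates, β = −0.02 on the summed concentration, σ² = 1)
and `german-like` (n = 100, no covariates). These emulate the *structure*
of real cohorts — scale of concentrations, correlated mixtures, log-normal
outcome — not their actual values: real data have measurement error in
exposure, non-normal tails, informative covariate structure and missing
records, none of which are generated. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to those features. Mixture calibration tests use an
exchangeable variant (equal medians) because only under exchangeability is
the symmetric-weight expectation exactly ¼ per compound.

The coverage study holds doses and covariates fixed (drawn once), simulates
outcomes per replicate, refits, and counts a replicate as covered when
BMDL ≤ true BMD — the standard direction for a lower confidence limit, and
the only one under which the exactness of the closed-form linear limit
(coverage = 95% at any n) holds. An undefined BMDL counts as non-covering.
One master seed spawns independent per-replicate streams, so studies are
reproducible bit-for-bit. Problem sizes in the shipped tests and the
acceptance script (2000 replicates at n = 30 for the exactness check; 500
replicates for calibration suites; 200 for recovery checks) were chosen as
the smallest sizes at which binomial/Monte-Carlo error is decisive for the
claim being tested.

## Known limitations

* No measurement-error-in-dose or mixed-effects modelling; no deconvolution
  correcting the grouping bias of summary data.
* Profile-likelihood coverage for the K-power family is below nominal when
  the true K sits on the K = 1 boundary (standard likelihood asymptotics
  fail there); the tests demonstrate rather than fix this, and the linear
  model is the recommended fallback when K̂ = 1.
* Hockey-stick threshold estimates on threshold-free data are unstable by
  construction (see above); results from that family should be treated as
  exploratory.
* The closed-form exactness argument requires the model (and its Gaussian
  residuals) to be correctly specified.
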