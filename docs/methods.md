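# Methods

## The model

`idpower` estimates the statistical power of a population-based longitudinal
cohort study — 30,000 adults recruited at ages 45–85, followed for 21 years
with data-collection waves every 3 years — to detect the effect of a binary
environmental exposure, a binary genetic exposure, and their interaction on
the incidence of an age-related chronic disease.  The data-generating process
is an irreversible illness-death multistate model with three states: healthy
(1), diseased (2), dead (3).  The transition of interest is 1→2; 1→3 acts as
a competing risk.  Disease is treated as absorbing for counting purposes, so
the 2→3 transition never enters the likelihood or the event counts and is not
simulated.

Time is measured in years since age 45, the assumed onset of the aging-related
disease process.  A subject entering the cohort at age `45 + l` contributes a
left-truncated record: both latent waiting times are drawn conditionally on
exceeding `l`, which (by independence of the two latent times) conditions on
being alive and disease-free at entry.

Both cause-specific waiting times are Weibull.  With scale λ and shape ρ,

    f(w) = (ρ/λ)(w/λ)^(ρ-1) exp(-(w/λ)^ρ),    F(w) = 1 - exp(-(w/λ)^ρ),

and the left-truncated variants divide by the survival at `l`.  The hazard
(ρ/λ)(w/λ)^(ρ-1) is invariant under left truncation, which keeps the family
closed under delayed entry.  Sampling uses the conditional-survival inversion

    t = λ ( (l/λ)^ρ - ln(1-u) )^(1/ρ),   u ~ Uniform(0,1),

which is the exact inverse of the truncated CDF (and maps u=0 to l exactly).

### Covariates and frailty

The subject-level 1→2 hazard follows proportional hazards:

    h_i(t) = h_0(t) · exp(β_E x_E + β_G x_G + β_GxE x_E x_G + f_i) / c ,

where x_E, x_G are independent Bernoulli exposures, the β are log hazard
ratios, and f_i ~ Normal(0, σ²) is a log-normal frailty representing
unmeasured etiological determinants.  σ defaults to 0.585, which encodes a
10-fold ratio in baseline risk between individuals at the 97.5th and 2.5th
population percentiles (exp(2·1.96·0.585) ≈ 9.9).  The constant
c = E[exp(β·x + f)] (a closed-form sum over the four exposure cells times
exp(σ²/2)) calibrates the baseline so the population-average hazard equals
the published marginal Weibull hazard for the disease.  A multiplier m on a
Weibull hazard is equivalent to rescaling the scale parameter by m^(-1/ρ),
which is how the simulator implements it.

An alternative reading of the generating equations places exp(β·x + f)
multiplicatively on the scale parameter itself.  For shape ≠ 1 the two
readings differ (a scale multiplier e^f is a hazard multiplier e^(-ρf)).
The proportional-hazards reading is used here because the β are defined as
log hazard ratios and because the 10-fold-risk-ratio anchor for the frailty
standard deviation only holds on the hazard scale.  The package's estimates
are internally consistent under this reading; see "Known limitations" for
what this choice means for comparisons with externally published simulation
values.

### Disease presets

Published Weibull parameters (years since 45) estimated from Canadian
incidence and mortality:

| disease     | 1→2 scale | 1→2 shape | baseline prevalence |
|-------------|-----------|-----------|---------------------|
| diabetes    | 65        | 2.0       | 0.14                |
| dementia    | 48        | 5.6       | 0.02                |
| parkinsons  | 130       | 3.3       | 0.02                |

with the 1→3 transition fixed at scale 42, shape 4.3 for all diseases.
These are taken as given; refitting them from incidence tables is out of
scope.

### Observation and measurement

* **Entry ages** are uniform on [45, 85].  The source cohort is a stratified
  random sample whose age distribution is not published; uniform is the
  documented assumption, and expected event counts (hence power for
  slow-progressing diseases) are sensitive to it.
* **Loss to follow-up** is exponential with rate 0.005/year from entry.
* **Continuous scheme**: disease onset observed at its exact time if it
  precedes death, loss to follow-up and the 21-year end; otherwise the record
  is censored at that minimum.  Death and loss to follow-up are treated as
  exactly observed (registry-style ascertainment) under both schemes.
* **Panel scheme**: visits at entry and every Δ = 3 years; onset is recorded
  at the first visit at or after it, provided the subject is still under
  observation at that visit (strictly before death and loss to follow-up).
  The final wave falls exactly at the end of follow-up and still detects.
  Onset never detected before death/loss/study end leaves a censored record;
  there is no retrospective diagnosis.
* **Misclassification** is non-differential: each observed exposure is the
  truth flipped once per dataset with the configured rate (defaults in the
  study grid: 0.1 environmental, 0.01 genetic), independent of the outcome.
  True exposures drive event times; observed exposures enter the analysis.

### Analysis model

Each replicate dataset is fitted by maximum likelihood under a left-truncated
Weibull proportional-hazards model that deliberately **omits the frailty**
(the analyst cannot measure it):

    events:    log h_i(t_i) - (H_i(t_i) - H_i(l_i))
    censored:            - (H_i(t_i) - H_i(l_i))

with H_i(t) = exp(β·x_i) (t/λ0)^ρ.  Optimization is unconstrained in
(log λ0, log ρ, β), initialized from the exponential closed form
(ρ=1, λ0 = total risk time / events), using BFGS on the analytic gradient
followed by Newton polishing steps on a finite-difference Hessian (the NLL is
O(10⁴), so BFGS alone stalls at gradient norms ~1e-5; the polish reaches
~1e-11).  The covariance is the inverse observed information, with the
Hessian by central differences of the analytic gradient (step 1e-5 on the
transformed scale).  Panel-detected onsets enter as exact event times at the
visit date, as in the source analysis; no interval-censored likelihood is
used.  The shape parameter is always estimated, not fixed.

Per-coefficient inference is a two-sided Wald test, with strict inequality at
the critical value; a likelihood-ratio refit is available as a cross-check
and agrees with the Wald decision in ≥99% of moderately powered replicates.

### Power and minimum detectable hazard ratio

Power is the proportion of replicate datasets in which the Wald test rejects
at the scenario's α.  Replicate r of a run draws its RNG stream from
SeedSequence(master_seed, r), so runs are reproducible and different settings
evaluated with the same master seed share random numbers replicate-by-
replicate (common random numbers).  Fit failures are counted and excluded,
with a 1% failure budget per cell beyond which the cell errors out.

The MDHR is found by bisection on the hazard ratio over (1.0, 3.0] at a
target power of 80%, with common random numbers across bracket points,
reported rounded up to 0.01, and the sentinel ">3.00" when the bracket top is
underpowered.  Power is assumed monotone in the HR; the realised trace is
checked and violations beyond twice the Monte-Carlo standard error raise a
warning carrying the trace.  An optional sequential stop ends a bracket
point's replication early once a 99.9% Wilson interval excludes the target
power — the above/below decision is then already settled, and the saved
replicates do not change the bisection path.

Scan conventions: when scanning one main effect, the other hazard ratios are
1; when scanning the interaction, both main-effect hazard ratios are 1.5.
Significance levels follow the study grid: 0.05 for the environmental
exposure, 1e-4 and 5e-8 for the genetic exposure and the interaction.

The Schoenfeld comparator gives the conventional closed-form answer,
d = (z_{1-α/2} + z_pow)² / (p(1-p)(log HR)²) and its inversion
MDHR = exp((z_{1-α/2}+z_pow)/√(d·p(1-p))).  It assumes continuous
ascertainment, error-free covariates and a homogeneous population, so it
bounds the simulation MDHR from below on matched scenarios.  The expected
event counts fed to it in the published comparison are 6100 (diabetes), 4400
(dementia) and 420 (Parkinson's); the event count is always an explicit
input, never inferred silently.

## What the generator emulates — and what it does not

The simulator reproduces delayed entry, an increasing hazard of disease with
age, competing death, constant-rate attrition, panel detection, unmeasured
heterogeneity and non-differential exposure misclassification.  It does not
model time-varying exposures, reversible disease, informative censoring,
diagnostic error in the outcome, the 2→3 (post-disease mortality) transition,
or the sampling weights of a real stratified cohort.  Passing tests therefore
demonstrate correctness of the pipeline under these idealisations, not that a
particular real cohort attains the computed power.

## Numerical choices

* Truncated-CDF/quantile identities hold to 1e-9; survival-scale expm1/log1p
  forms avoid cancellation.
* Truncation beyond the numerical support (survival < 1e-12 at `l`) raises a
  degenerate-truncation error rather than returning infinities.
* Occupancy probabilities use adaptive quadrature (absolute tolerance 1e-8,
  configurable); the three probabilities are computed independently and sum
  to 1 within 1e-6.
* The expected-incidence quadrature route integrates over entry age
  (Gauss-Legendre), exposure cells, and frailty (16-node Gauss-Hermite), and
  agrees with the Monte-Carlo route within Monte-Carlo error — a standing
  dual-route consistency check.
* Constant covariate columns are dropped from optimization and flagged, as
  are exposure cells with zero events; records with t ≤ l are data errors,
  never silently dropped.

## Problem sizes used in the test suite

Monte-Carlo checks in the acceptance tests use the full 30,000-subject cohort
with scaled-down replication chosen as a desk-scale profile: 400 replicates
for the type-I-error check, 200 for the power anchors, 150 per bisection
point for the MDHR cells (with sequential stopping), and 40–80 replicates per
cell in the qualitative grid scans.  Monte-Carlo intervals are reported
alongside every estimate; the full-precision profile (1000 replicates, as in
the study grid) is the library default for production runs.

## Known limitations

* The entry-age distribution of the motivating cohort is not published;
  expected 21-year event counts under the uniform assumption are
  4.6k/5.6k/0.34k (diabetes/dementia/Parkinson's), the same order as — but
  not equal to — the published life-table-based 6.1k/4.4k/0.42k.
* The generating equations for the source study admit two frailty readings
  (hazard-scale vs scale-parameter placement) that are mutually inconsistent
  for shape ≠ 1, and its published simulation results are not jointly
  reproducible under either single reading.  This package commits to the
  internally consistent proportional-hazards reading throughout.  Simulation
  MDHRs and rare-disease power computed here consequently differ from some
  published simulation values (the package's conventional Schoenfeld values
  match the published ones exactly).
* Wald inference with very few exposed events (rare exposure × rare disease)
  is approximate; the likelihood-ratio cross-check is provided for such
  cells.
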