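# Scenario configuration schema

Scenario files are YAML (or JSON with a `.json` suffix).  Unknown keys at any
level are rejected with the offending field path.  Exactly one of `disease`
or `transitions` must be present.

```yaml
# one of the built-in presets: diabetes | dementia | parkinsons
disease: dementia

# ... or explicit Weibull parameters (years since age 45):
# transitions:
#   healthy_to_diseased: {scale: 48.0, shape: 5.6}
#   healthy_to_dead:     {scale: 42.0, shape: 4.3}

design:
  n_subjects: 30000
  entry_age_min: 45          # years; default 45
  entry_age_max: 85          # years; default 85
  entry_age_distribution: uniform   # only 'uniform' is supported
  followup_years: 21         # default 21
  visit_interval_years: 3    # a number of years, or the string 'continuous'
  ltfu_rate: 0.005           # loss-to-follow-up rate per year; default 0.005

exposures:
  prevalence_env: 0.1        # Bernoulli prevalence of the environmental exposure
  prevalence_gen: 0.1        # ... and the genetic exposure
  misclass_env: 0.1          # non-differential flip rate, in [0, 0.5); default 0
  misclass_gen: 0.01         # default 0

effects:                     # log hazard ratios on the 1->2 transition; default 0
  beta_env: 0.0              # the power/mdhr commands overwrite these per the
  beta_gen: 0.0              # scan conventions, so they matter mainly for
  beta_gxe: 0.0              # the `simulate` command

frailty:
  sd: 0.585                  # log-hazard sd of the Normal frailty; default 0.585

alpha: 0.05                  # significance level; 0.05 / 1e-4 / 5e-8 in the study grid

# optional: target marginal Weibull scale for 1->2 (defaults to the
# transition scale); the baseline hazard is calibrated against it
# population_scale_12: 48.0
```

The `power` and `mdhr` subcommands accept `--scheme {continuous,panel}` and
`--alpha` to override the config without editing it.  All randomness in a run
derives from `--seed`; the JSON manifest written next to each output records
the config digest and the derived per-cell seeds, and rerunning with the same
inputs reproduces every output byte-for-byte (finished cells in an existing
output CSV are skipped, which is also the resume mechanism).
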