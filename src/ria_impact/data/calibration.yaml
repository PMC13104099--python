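# Versioned default calibration of the synthetic corpus generator.
#
# Domain-level issue rates are conditional on a trial reaching the domain
# and reproduce the observed frequencies of a 206-trial COVID-19 drug-trial
# corpus screened with the six-domain integrity assessment (e.g. ~26% of
# registration-domain assessments end in exclusion, ~45% of ethics-domain
# assessments in "awaiting classification").  Awaiting-level issues share a
# latent "documentation quality" factor: a well-documented trial (fraction
# below) raises no awaiting-level issue in any domain, a poorly documented
# one carries each domain's rate inflated by 1/(1 - well_documented_fraction)
# so every per-domain marginal rate is preserved while issues co-occur
# within trials, as observed.
calibration_version: 1
n_reviews: 23
cochrane_fraction: 0.565          # 13 of 23 reviews
trials_per_review:
  dist: negative_binomial
  mean: 10.3
  dispersion: 3.0
  minimum: 3
arm_size:                         # participants per arm
  dist: lognormal
  mu: 4.382                       # log(80): median trial ~160 participants
  sigma: 1.39                     # total-size IQR spans roughly 78-506
  minimum: 10
  maximum: 4000
control_risk: 0.25                # baseline event risk (mortality-like)
true_log_effect: -0.105360516     # log(0.9): modest protective effect
well_documented_fraction: 0.37
issue_prevalence:                 # per domain: {exclude, awaiting, non_rct}
  1: {exclude: 0.039, awaiting: 0.010, non_rct: 0.0}
  2: {exclude: 0.258, awaiting: 0.141, non_rct: 0.0505}
  3: {exclude: 0.0,   awaiting: 0.453, non_rct: 0.0}
  4: {exclude: 0.0,   awaiting: 0.058, non_rct: 0.0}
  5: {exclude: 0.0,   awaiting: 0.204, non_rct: 0.0073}
  6: {exclude: 0.0,   awaiting: 0.206, non_rct: 0.0}
assessor_profiles:                # rows: true no-concern / awaiting / exclude
  beginner:                       # over-assigns awaiting, misses little
    - [0.70, 0.28, 0.02]
    - [0.05, 0.90, 0.05]
    - [0.02, 0.13, 0.85]
  intermediate:
    - [0.85, 0.13, 0.02]
    - [0.08, 0.87, 0.05]
    - [0.02, 0.08, 0.90]
  senior:
    - [0.95, 0.04, 0.01]
    - [0.03, 0.95, 0.02]
    - [0.01, 0.03, 0.96]
rob_distribution: {low: 0.33, some_concerns: 0.45, high: 0.22}
time_model_mean_seconds:          # per tier, per domain
  beginner:     {1: 82, 2: 152, 3: 259, 4: 207, 5: 363, 6: 555}
  intermediate: {1: 65, 2: 123, 3: 229, 4: 200, 5: 216, 6: 419}
  senior:       {1: 65, 2: 123, 3: 229, 4: 200, 5: 216, 6: 419}
time_sigma: 0.4                   # lognormal shape of per-study durations
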