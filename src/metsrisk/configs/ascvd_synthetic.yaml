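# Pooled-cohort-equations-style 10-year ASCVD risk -- SYNTHETIC coefficients.
# Sex- and race-specific strata (four subgroups); risk = 1 - s0 ** exp(lp - mean_lp).
# Coefficient VALUES are synthetic placeholders; substitute published values
# before any real-data use.
name: ascvd_synthetic
outcome_family: survival10y
standardize_flag: true
terms:
- {covariate: age, transform: log, coefficient: 9.0, stratum: white-man}
- {covariate: total_cholesterol, transform: log, coefficient: 1.0, stratum: white-man}
- {covariate: hdl, transform: log, coefficient: -0.9, stratum: white-man}
- {covariate: sbp, transform: log, coefficient: 1.9, stratum: white-man}
- {covariate: bp_treated, transform: identity, coefficient: 0.35, stratum: white-man}
- {covariate: smoking, transform: identity, coefficient: 0.66, stratum: white-man}
- {covariate: age, transform: log, coefficient: 7.5, stratum: white-woman}
- {covariate: total_cholesterol, transform: log, coefficient: 1.1, stratum: white-woman}
- {covariate: hdl, transform: log, coefficient: -1.1, stratum: white-woman}
- {covariate: sbp, transform: log, coefficient: 2.0, stratum: white-woman}
- {covariate: bp_treated, transform: identity, coefficient: 0.40, stratum: white-woman}
- {covariate: smoking, transform: identity, coefficient: 0.70, stratum: white-woman}
- {covariate: age, transform: log, coefficient: 6.5, stratum: black-man}
- {covariate: total_cholesterol, transform: log, coefficient: 0.3, stratum: black-man}
- {covariate: hdl, transform: log, coefficient: -0.5, stratum: black-man}
- {covariate: sbp, transform: log, coefficient: 2.2, stratum: black-man}
- {covariate: bp_treated, transform: identity, coefficient: 0.45, stratum: black-man}
- {covariate: smoking, transform: identity, coefficient: 0.55, stratum: black-man}
- {covariate: age, transform: log, coefficient: 8.0, stratum: black-woman}
- {covariate: total_cholesterol, transform: log, coefficient: 0.5, stratum: black-woman}
- {covariate: hdl, transform: log, coefficient: -0.8, stratum: black-woman}
- {covariate: sbp, transform: log, coefficient: 2.4, stratum: black-woman}
- {covariate: bp_treated, transform: identity, coefficient: 0.50, stratum: black-woman}
- {covariate: smoking, transform: identity, coefficient: 0.60, stratum: black-woman}
s0: {white-man: 0.914, white-woman: 0.967, black-man: 0.898, black-woman: 0.953}
mean_lp: {white-man: 47.0, white-woman: 42.0, black-man: 37.0, black-woman: 44.0}
intercept: 0.0
points_rules: []
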