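# Framingham-style 10-year general CVD risk equation -- SYNTHETIC coefficients.
# Sex-specific Cox-derived form: risk = 1 - s0 ** exp(lp - mean_lp) with
# log-transformed continuous predictors.  The coefficient VALUES below are
# synthetic placeholders of plausible magnitude; substitute the published
# values from the original source before any real-data use.
name: framingham_synthetic
outcome_family: survival10y
standardize_flag: true
terms:
- {covariate: age, transform: log, coefficient: 3.06, stratum: man}
- {covariate: total_cholesterol, transform: log, coefficient: 1.12, stratum: man}
- {covariate: hdl, transform: log, coefficient: -0.93, stratum: man}
- {covariate: sbp, transform: log, coefficient: 1.93, stratum: man}
- {covariate: bp_treated, transform: identity, coefficient: 0.40, stratum: man}
- {covariate: smoking, transform: identity, coefficient: 0.65, stratum: man}
- {covariate: age, transform: log, coefficient: 2.33, stratum: woman}
- {covariate: total_cholesterol, transform: log, coefficient: 1.21, stratum: woman}
- {covariate: hdl, transform: log, coefficient: -0.71, stratum: woman}
- {covariate: sbp, transform: log, coefficient: 2.76, stratum: woman}
- {covariate: bp_treated, transform: identity, coefficient: 0.50, stratum: woman}
- {covariate: smoking, transform: identity, coefficient: 0.53, stratum: woman}
s0: {man: 0.88, woman: 0.95}
mean_lp: {man: 24.18, woman: 26.30}
intercept: 0.0
points_rules: []
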