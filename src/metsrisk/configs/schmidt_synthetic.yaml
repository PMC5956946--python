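# ARIC-derived-style logistic diabetes risk equation -- SYNTHETIC coefficients.
# Probability = expit(intercept + lp) over clinical predictors including
# fasting glucose (which makes it a strong discriminator).  Coefficient
# VALUES are synthetic placeholders; substitute published values before any
# real-data use.
name: schmidt_synthetic
outcome_family: logistic
standardize_flag: true
terms:
- {covariate: age, transform: identity, coefficient: 0.040}
- {covariate: waist, transform: identity, coefficient: 0.030}
- {covariate: sbp, transform: identity, coefficient: 0.012}
- {covariate: glucose, transform: identity, coefficient: 0.055}
- {covariate: hdl, transform: identity, coefficient: -0.015}
- {covariate: family_history_diabetes, transform: identity, coefficient: 0.45}
s0: null
mean_lp: 0.0
intercept: -13.12
points_rules: []
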