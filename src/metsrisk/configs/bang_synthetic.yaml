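# ADA-style ordinal diabetes risk test -- SYNTHETIC point assignments.
# Integer points from age, adiposity, sex, family history and blood
# pressure; not Z-standardised for modelling (ordinal scale).  Point VALUES
# are synthetic placeholders (graded finely enough that cohort quintiles of
# the score are well defined); substitute the published scoring rules before
# any real-data use.
name: bang_synthetic
outcome_family: ordinal_points
standardize_flag: false
terms: []
s0: null
mean_lp: 0.0
intercept: 0.0
points_rules:
- {covariate: age, cuts: [35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 65.0], points: [0, 1, 2, 3, 4, 5, 6, 7]}
- {covariate: bmi, cuts: [22.0, 25.0, 28.0, 30.0, 35.0, 40.0], points: [0, 1, 2, 3, 4, 5, 6]}
- {covariate: sex, equals: man, points_if_equal: 1}
- {covariate: family_history_diabetes, equals: true, points_if_equal: 1}
- {covariate: bp_treated, equals: true, points_if_equal: 1}
- {covariate: sbp, cuts: [120.0, 130.0, 140.0], points: [0, 1, 2, 3]}
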