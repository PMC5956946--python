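# metsrisk

Does a continuous **metabolic syndrome (MetS) severity Z-score** add
predictive value on top of the established cardiovascular and diabetes risk
calculators?  `metsrisk` implements the full analysis pipeline for that
question — the kind of incremental-prediction study run on large biracial
US cohorts (ARIC-style sites plus a JHS-style site) — as a tested,
reusable Python package.  Because the real cohort data are
access-restricted, the package ships a first-class synthetic-cohort
generator with the same statistical structure, so every stage is
reproducible end to end.

## What it computes

**MetS severity score.**  The five traditional MetS components — waist
circumference, triglycerides, HDL cholesterol, systolic BP, fasting
glucose — are transformed (log triglycerides), standardised against a
reference sample, and combined with the loadings λ of a one-factor
confirmatory factor analysis, fitted separately by sex-and-race subgroup:

    MetS-Z = s · ( Σ_k λ_k z_k − m ),   z_k = (t_k(x_k) − μ_k) / σ_k

with `s`, `m` chosen so the reference sample scores to mean 0, SD 1.
Higher score = worse metabolic status (positive loading on glucose,
negative on HDL).  HOMA-IR = insulin × glucose / 405 is also provided.

**Nested model ladder.**  For each comparator risk score (Framingham-style
and pooled-cohort-style 10-year CVD equations; ordinal ADA-style and
logistic ARIC-derived-style diabetes scores — shipped as *editable YAML
specs with synthetic placeholder coefficients*):

* Model A — risk score only;
* Model B — MetS severity only;
* Model C — risk score + MetS severity;
* Model D — Model C + score×MetS interaction;

all site-adjusted, fitted by Cox proportional hazards for time to incident
CHD (in-repo Newton partial-likelihood maximiser, Efron ties by default,
Breslow by flag) and by logistic regression for 10-year incident T2DM
(visit-interval detection under ARIC/JHS diagnostic rules: fasting glucose
≥ 126 mg/dL, non-fasting ≥ 200 mg/dL, HbA1c ≥ 6.5 %, medication,
self-report per protocol).

**Added-value statistics at the 10-year horizon (τ = 3652 d):**

* c-statistic: all-pairs concordance, ties ½ (DeLong CI for binary
  outcomes, bootstrap for censored follow-up);
* discrimination slope and **IDI** = slope(new) − slope(old);
* **continuous NRI** = [P(up|event) − P(down|event)] +
  [P(down|non-event) − P(up|non-event)], with the event/non-event
  decomposition reported separately; under censoring, event status at τ is
  estimated by Kaplan–Meier weighting within reclassification groups
  (complete-case fallback by flag);
* AIC = 2k − 2·logL per model, VIF collinearity diagnostics (severe > 10);
* per-quintile MetS hazard/odds ratios across fifths of the comparator
  score (the interaction analysis), with log-scale plots and sidecar TSVs.

## Worked example

```python
from metsrisk import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n_participants=6000, n_boot=30, make_plots=False)
manifest = run_pipeline(cfg, "out/")
res = manifest["_results"]

r = res["bang_synthetic"]          # ordinal diabetes score, T2DM outcome
rep = r["reports"]["C"]            # Model C vs Model A
print(round(rep.c_old.value, 3), round(rep.c_new.value, 3))
print(round(rep.idi.value, 4), round(rep.nri.overall.value, 3))
```

prints

```
0.727 0.802
0.073 0.632
```

Reading: on a 6,000-participant synthetic cohort (3,816 analytic after the
baseline exclusions), adding MetS severity to the ordinal diabetes score
raises the c-statistic from 0.727 to 0.802, with IDI 0.073 and continuous
NRI 0.632 — the severity score carries real metabolic signal beyond the
point score.  For the CHD comparators the same run shows essentially
unchanged c and small IDI but a clearly positive non-event NRI, i.e. the
score mostly helps re-classify people who stay event-free — the
qualitative pattern this kind of analysis is designed to expose.  The
output directory gains `results_<score>.json`, `table_chd.tsv` /
`table_t2dm.tsv` (model-by-model AIC, HR/OR with CIs, c, IDI, NRI),
quintile sidecars and a provenance `manifest.json`.

A CLI mirrors the library: `metsrisk simulate`, `metsrisk score-mets`,
`metsrisk score`, `metsrisk report` (see `--help`).

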