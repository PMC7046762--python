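# tedrecon

Reconstruction of thyroid equivalent doses (TED) from internal radioiodine
for residents evacuated after a reactor accident, built for dosimetry and
radiation-epidemiology groups who have (a) individual whereabouts records
from behaviour questionnaires and (b) a spatiotemporal air-concentration
database produced by an atmospheric transport–dispersion model.

The pipeline:

1. **Behaviour screening and discretization** — hourly whereabouts over
   11–25 March 2011 (JST) are validated (impossible movement speeds,
   unlocatable days), then collapsed onto 56 six-hour segments
   (AM1/AM2/PM1/PM2 of 12–25 March).
2. **Exposure lookup** — each segment is assigned the nearest landmark
   (haversine distance) of a landmark × segment × chemical-form ¹³¹I
   concentration table.
3. **Dose model** — inhalation TED

   E_inhal = Σᵢ (V/4) · (Cᵢ,p·e_p + Cᵢ,el·e_el + Cᵢ,met·e_met) · FC · DF_shelter

   over the 56 segments, with age-specific ventilation V (m³/day),
   thyroid dose coefficients e (Sv/Bq) per chemical form, an uptake-rate
   correction FC = 0.62 and a sheltering factor DF_shelter = 0.5.
   Short-lived radionuclides (¹³²Te/¹³²I, ¹³³I) are added by scaling dose
   accrued on 12–13 March by 1.59 and on 15–16 March by 1.08.  Tap-water
   ingestion dose is Σⱼ V_tap · C_tap,j · e_ing · FC · Sf · Xⱼ/3 over 14
   days with Xⱼ meals per day.
4. **Uncertainty** — FC ~ Normal(0.62, 0.20) truncated at 0 and
   DF_shelter ~ Triangular(0.1, 0.5, 0.95) are propagated by 100,000-draw
   Latin-Hypercube Monte Carlo; because the dose is linear in FC·DF, the
   95% uncertainty interval of any dose statistic is the statistic times
   the product's 2.5th/97.5th-percentile multipliers.
5. **Scenario clustering** — forward stepwise regression finds the few
   segments carrying most of the dose; Ward hierarchical clustering on
   those segment doses groups subjects into evacuation scenarios, compared
   by Kruskal–Wallis and Steel–Dwass all-pairs tests.

A synthetic-data module generates plume-episode concentration tables,
evacuation-archetype cohorts with closed-form ground-truth doses, and
decaying tap-water series, so the whole pipeline is exercised end-to-end
without any restricted survey data.

## Worked example

```bash
tedrecon simulate --seed 42 --out demo          # synthetic cohort + concentrations
cat > demo/config.yaml <<'YAML'
behaviour_csv: demo/behaviour.csv
concentration_csv: demo/concentrations.csv
dosimetry_config: src/tedrecon/data/reference_config.yaml
ui: {n_draws: 100000, seed: 20110312}
clustering: {k: 4, r2_stop: 0.9999}
YAML
tedrecon cluster --config demo/config.yaml --out demo/out --k 4
```

prints the per-scenario table

```
 cluster  n  usage_rate_pct       median ... significance
       1 30            30.0 1.764048e+01              **
       2 25            25.0 1.063872e+00              **
       3 25            25.0 7.243026e+00              **
       4 20            20.0 4.253263e-09              **
```

— four evacuation scenarios: shelter-in-place near the source (median 18
mSv for a 1-year-old), a southern trajectory through a later plume (1.1
mSv), a northbound evacuation through the first plume (7.2 mSv), and
early evacuation out of every footprint (~0 mSv); `**` marks scenarios
whose dose differs from some other scenario at p < 0.01 (Steel–Dwass).
`demo/out/summary.csv` holds the cohort summary (mSv, two significant
figures, 95% UI in parentheses conceptually: columns `*_ui_low/high`):

```
group,n,mean,mean_ui_low,mean_ui_high,median,median_ui_low,median_ui_high,p95,p95_ui_low,p95_ui_high
SYN,100,7.4,1.9,15.0,7.2,1.9,15.0,18.0,4.5,37.0
```

i.e. a cohort mean of 7.4 mSv (95% UI 1.9–15) driven almost entirely by
whether a subject's route crossed the 12-March plume.

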