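# ewscompare

Tools for evaluating the National Early Warning Score (NEWS) and its 2017
revision (NEWS2) on observation-level hospital data, aimed at researchers in
clinical risk prediction and deterioration detection.

Aggregate early-warning scores sum integer weights (0–3) assigned to seven
bedside inputs — respiratory rate, SpO₂, supplemental oxygen, temperature,
systolic blood pressure, heart rate and conscious level (AVPU) — and trigger
clinical review at thresholds such as 5 and 7 points. NEWS2 introduced an
alternative SpO₂ weighting ("scale 2") for patients with, or at risk of,
hypercapnic (type II) respiratory failure (T2RF): its zero band sits at
88–92% and saturations above 92% are penalised only on supplemental oxygen.
Whether that change helps or harms detection of deterioration is an
empirical question about discrimination, which this package answers with:

- **scoring** — deterministic NEWS/NEWS2 computation from vital-sign
  observation sets (both SpO₂ scales, GCS→AVPU conversion), driven by
  editable weight-table CSVs that ship with the package;
- **cohort** — an exclusion flowchart for completed adult admissions and
  T2RF risk-group classification from ICD-10 codes (COPD J40–J44,
  bronchiectasis J47, cystic fibrosis E84, obesity E66, and neuromuscular /
  chest-wall conditions with respiratory failure J96) plus
  oxygen-prescription flags;
- **outcomes** — labelling of every complete observation set with four
  24-hour endpoints: in-hospital death, unanticipated ICU admission,
  cardiac arrest, and their composite;
- **discrimination** — the c-statistic (tie-adjusted concordance,
  `AUROC = P(score⁺ > score⁻) + ½·P(tie)`), paired bootstrap comparison of
  two systems on the same observations (2000 resamples, percentile CIs),
  sensitivity/specificity/PPV at review thresholds, and efficiency curves
  (sensitivity vs. fraction of observations triggering);
- **missing_data** — multiple imputation by chained equations with
  predictive-mean matching, pooled AUROCs via Rubin's rules on the logit
  scale;
- **synthetic** — a multi-hospital cohort generator with a latent severity
  process driving both vitals and events, calibrated per risk group by
  root-finding so that realised event rates hit configured targets — it
  provides ground truth for every analysis step, since real observation
  databases of this kind are not public.

## Worked example

```python
from ewscompare import VitalSignSet, score_news, score_news2

obs = VitalSignSet("adm-1", heart_rate=92, systolic_bp=104,
                   respiratory_rate=22, temperature=38.4, spo2=91,
                   on_oxygen=True, consciousness="A")
n  = score_news(obs)
n2 = score_news2(obs, use_scale2=True)
print("NEWS      :", n.value, n.components)
print("NEWS2(s2) :", n2.value, n2.components)
```

prints

```
NEWS      : 10 {'respiratory_rate': 2, 'spo2': 3, 'supplemental_oxygen': 2, 'temperature': 1, 'systolic_bp': 1, 'heart_rate': 1, 'consciousness': 0}
NEWS2(s2) : 7 {'respiratory_rate': 2, 'spo2': 0, 'supplemental_oxygen': 2, 'temperature': 1, 'systolic_bp': 1, 'heart_rate': 1, 'consciousness': 0}
```

The same saturation of 91% on oxygen carries weight 3 under NEWS but sits in
scale 2's zero band, so NEWS2 scores this observation three points lower —
under the NEWS threshold of 7 it would still trigger an urgent review,
under NEWS2 it sits exactly at the boundary. Aggregated over a whole
cohort, such shifts move sensitivity, workload and the c-statistic; the
pipeline quantifies all three.

A full study runs from the command line:

```sh
ewscompare run --seed 42 --out study_out        # simulate → score → label → analyse
ewscompare simulate --n 2000 --seed 7 --out data/
ewscompare score --obs data/observations.csv --out scored.csv
```

`run` writes a report bundle: the exclusion tally, per-group event counts,
the labelled observation table, AUROC and threshold tables per risk group ×
endpoint (with paired-bootstrap differences and 95% CIs), efficiency
curves, and the multiple-imputation sub-analysis, all stamped with the seed
and a configuration hash. Identical configuration and seed reproduce the
bundle byte for byte.

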