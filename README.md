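# ease-score

Risk stratification of atrial-fibrillation (AF) recurrence after catheter
ablation from routine echocardiography. The package implements the **EASE
score** (Echocardiographic Atrial Strain and conduction Evaluation), a
0–12-point composite of six left-atrial parameters, together with a
calibrated synthetic-cohort generator and a from-scratch survival-analysis
layer (Kaplan–Meier, Greenwood variance, k-group log-rank), so the whole
scoring-to-outcome pipeline can be exercised and tested without patient
data.

It is aimed at clinical researchers and biostatisticians who work with
already-measured echo parameters (no image processing is done here).

## The score

Each patient contributes six parameters; each is banded by published
thresholds and awarded points, summing to a total of 0–12:

| Parameter | normal (0 pt) | borderline (1 pt) | abnormal (2 pt) |
|---|---|---|---|
| LASr, reservoir strain (%) | > 23 | 15–23 | < 15 |
| PA-TDI, conduction time (ms) | < 120 | 120–150 | > 150 |
| LAVI, volume index (mL/m²) | < 34 | 34–48 | > 48 |
| Stiffness index E/e′ / LASr | ≤ 0.5 | — | > 0.5 (2 pt) |
| E/e′ ratio | ≤ 14 | — | > 14 (2 pt) |
| LASct, contractile strain (%) | > 6 | — | ≤ 6 (2 pt) |

The stiffness index is always derived (E/e′ divided by LASr-as-percent:
E/e′ = 10 with LASr = 20 % gives exactly the 0.5 boundary). Totals map to
risk categories **low (0–3)**, **intermediate (4–8)**, **high (9–12)**; an
alternate banding (4–7 / 8–12) used in some reports ships as the named
config `fig6`. LASct is only measurable in sinus rhythm; a missing value
is refused by default, or handled by a `worst_case` / `omit_rescale`
policy.

Recurrence follows the standard definition: any atrial arrhythmia episode
lasting longer than 30 s occurring after a 3-month (90-day) blanking
period; time-to-first-recurrence curves are estimated with the
product-limit estimator S(t) = Π (1 − dᵢ/nᵢ) and groups are compared with
the log-rank test.

## Worked example

Score three patients from a CSV:

```sh
$ cat meas.csv
patient_id,lasr_pct,pa_tdi_ms,lavi_ml_m2,e_over_eprime,lasct_pct
P01,28,100,30,8,10
P02,18,135,40,10,8
P03,12,160,52,16,4

$ ease score --input meas.csv --out scores.csv
$ cat scores.csv
# config: ease_default
# config_hash: ee49186d84db
patient_id,...,stiffness,pts_lasr,pts_patdi,pts_lavi,pts_stiffness,pts_ee,pts_lasct,total,category,flags
P01,...,0.2857...,0,0,0,0,0,0,0,low,
P02,...,0.5555...,1,1,1,2,0,0,5,intermediate,
P03,...,1.3333...,2,2,2,2,2,2,12,high,
```

P01 is normal on every axis (total 0, low risk). P02 is borderline on
LASr/PA-TDI/LAVI and has an elevated stiffness index (10/18 ≈ 0.56 > 0.5),
totalling 5 — intermediate. P03 is abnormal on all six axes — the maximum
12, high risk.

A full synthetic run (128 patients, seeded) through scoring, recurrence
filtering and stratified survival:

```sh
ease simulate --n 128 --seed 42 --out-dir cohort/
ease score    --input cohort/measurements.csv --out cohort/scores.csv
ease survival --scores cohort/scores.csv --episodes cohort/episodes.csv \
              --meta cohort/cohort_meta.csv --out cohort/km.json
ease report   --scores cohort/scores.csv --km cohort/km.json \
              --out-md cohort/report.md --out-json cohort/report.json --seed 42
```

which prints (report.md):

```
| Category     | n  | %     | 12-mo KM incidence | 95% CI          | crude |
|---|---|---|---|---|---|
| low          | 39 | 30.5% | 8.1%               | [0.0%, 16.9%]   | 10.3% |
| intermediate | 68 | 53.1% | 35.4%              | [23.7%, 47.2%]  | 39.7% |
| high         | 21 | 16.4% | 87.3%              | [67.1%, 100.0%] | 81.0% |

Log-rank test: chi2 = 44.045, df = 2, p = 2.73e-10
```

i.e. at this cohort size the three categories already separate cleanly:
12-month Kaplan–Meier recurrence rises monotonically from 8 % (low) to
87 % (high), and the log-rank test rejects equal hazards decisively. The
`crude` column is the raw event proportion over variable follow-up, shown
for comparison with the censoring-corrected KM incidence.

The same machinery is available as a library (`ease_score.compute_breakdown`,
`generate_cohort`, `km_estimate`, `logrank_test`, ...); the CLI is a thin
wrapper.

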