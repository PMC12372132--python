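# Methods

This note documents the models and numerical choices behind `ease-score`:
the scoring rules, the synthetic-cohort generator, and the survival
estimators. It is the package's own account of its design; every number
quoted here is computed by the test suite or `scripts/acceptance.py`, not
asserted from elsewhere.

## 1. Scoring model

Six parameters are scored from threshold bands and summed to a 0–12 total.
The published literature on the score states the thresholds and the total
range but not the per-parameter point values; the shipped assignment —
0/1/2 for the three parameters with a stated borderline band (LASr,
PA-TDI, LAVI) and 0/2 for the three with a single cutpoint (stiffness,
E/e′, LASct) — is the only one consistent with a 0–12 range given those
bands. It is a reconstruction, and it is fully configurable through
`ThresholdConfig` (every band edge, point value and category boundary is
data, not code).

**Band-edge convention.** Comparatives are read literally: "greater than
23 %" makes the normal LASr band (23, ∞), borderline [15, 23], abnormal
(0, 15); "below or equal to 0.5" makes normal stiffness (0, 0.5];
"above 14" makes abnormal E/e′ (14, ∞); PA-TDI's implicit middle band is
[120, 150] (stated normal < 120, abnormal > 150); LAVI analogous with
cuts 34/48; LASct normal (6, ∞). Bands are half-open and contiguous, so a
value exactly at an edge lands deterministically in exactly one band — no
tolerance fuzzing, which keeps scoring bit-reproducible.
`validate_config` enforces contiguity, full coverage of (0, ∞), point
monotonicity in the abnormality direction, and that the attainable total
spans exactly 0..12.

**Category boundaries.** The default is low 0–3, intermediate 4–8, high
9–12. A variant banding 4–7 / 8–12 appears in some of the source
material's figures and tables; both are shipped (`default`, `fig6`) and
the boundary is a config field. The package takes no position on which is
"correct".

**Missing LASct.** LASct is unmeasurable when the patient is in AF at the
exam. Policies: `refuse` (default — scoring clinical data should not
silently invent a value), `worst_case` (assign the maximum 2 points,
flagged), `omit_rescale` (score the five available parameters, rescale
their 0–10 total to 0–12 by ×1.2, round half-up, flagged). With the
default bands rescaling never lands exactly on .5, but half-up is defined
anyway for custom point schemes.

## 2. Synthetic-cohort generator

The generator emulates a single-centre cohort of first-time
pulmonary-vein-isolation patients for paroxysmal AF: 128 patients by
default, category proportions ≈ 29.7 / 47.7 / 22.6 %, a strong negative
LASr–stiffness correlation (target −0.72), follow-up median 14 months
(IQR ≈ 11–18), and per-category 12-month recurrence of < 10 % (low) and
> 60 % (high).

**Measurement model.** Each patient draws a latent remodeling severity
(mild / moderate / severe, weights 0.30 / 0.47 / 0.23) and a shared
standard-normal latent factor z (z > 0 = more remodeled). Each of the five
primitive parameters is severity-conditional normal, shifted by a
per-parameter loading times z, truncated at physiologic floors
(LASr ≥ 2 %, PA-TDI ≥ 30 ms, LAVI ≥ 5 mL/m², E/e′ ≥ 1, LASct ≥ 0.5 %).
The stiffness index is never sampled; it is always E/e′ / LASr, so the
identity holds exactly on every synthetic row. The shared factor is what
produces the cross-parameter correlation structure — in particular the
strong negative LASr–stiffness correlation — on top of the between-severity
separation.

The default means/spreads (see `GeneratorParams`) were calibrated by Monte
Carlo (4×10⁴ draws) against four targets simultaneously: the three
category proportions, the LASr–stiffness correlation, P(total ≤ 3 | mild)
> 0.8 and P(total ≥ 9 | severe) > 0.6. One structural choice fell out of
that calibration: the latent factor is damped within the moderate class
(scale 0.35 vs 1.0). With a full-strength shared factor the moderate class
spreads across all three categories and the fixed severity weights cannot
reproduce the observed proportions; damping keeps moderates concentrated
in the intermediate band while mild/severe retain the full factor that
drives the correlation. At the frozen defaults a 10⁴-patient cohort gives
proportions ≈ 30.4 / 48.1 / 21.5 %, r ≈ −0.74, and the per-severity
concentration probabilities 0.98 / 0.89.

**Outcome model.** Within each risk category, latent recurrence time is
exponential with rate λ = −ln(1 − p₁₂)/12 per month, so its 12-month
cumulative incidence equals the configured p₁₂ (defaults 0.08 / 0.35 /
0.65; the intermediate value is unstated in the source material — 0.35 is
a design choice between the published < 0.10 and > 0.60 bounds).
Censoring is purely administrative at end of follow-up. A latent time
inside the blanking window surfaces as a qualifying episode just after
blanking ends (day 91), preserving the 12-month incidence. Follow-up is
log-normal(μ = ln 14, σ = 0.373), matching the median of 14 months and
reproducing quartiles ≈ 10.9 / 18.0.

**Nuisance episodes.** So the recurrence filter has something to reject,
each patient also logs Poisson(0.5) short episodes (uniform 5–30 s,
anywhere in follow-up) and, with probability 0.3, one long episode inside
the blanking period. Magnitudes are arbitrary and configurable; they exist
to exercise the filter, not to model AF burden.

**Randomness.** One root seed; per-patient substreams are spawned by
counter (`numpy.random.SeedSequence.spawn`), so a cohort is bit-identical
under a fixed seed and patient i is identical regardless of cohort size.

**What the generator does not emulate.** Demographics and comorbidities
(age, sex, hypertension, BMI, ...) are not modeled — the score does not use
them. Real measurement error structure (inter-observer variability,
vendor differences in strain software), non-exponential hazards
(early clustering of recurrences after blanking), loss to follow-up, and
rhythm-dependent LASct missingness are all absent: every synthetic patient
has an LASct value. Passing calibration therefore shows that the pipeline
is internally consistent and recovers its own parameters — not that the
score performs as published on real patients.

## 3. Survival analysis

**Recurrence filter.** An episode qualifies if its duration is strictly
greater than 30 s ("longer than 30 s" read literally; a `strict_duration`
flag switches to ≥ for the common clinical convention) and its onset is
strictly after the blanking period (3 months operationalised as 90 days).
Days convert to months at 30.44 d/mo. The earliest qualifying onset is
the event time; otherwise the patient is censored at end of follow-up.
Episodes logged after follow-up ends are ignored with a warning rather
than rejected, since trailing data entry is common in episode logs.

**Kaplan–Meier.** Standard product-limit estimator over distinct event
times, implemented directly (lifelines is used in the tests as an
independent oracle, never as the implementation). At tied times events
precede censorings — subjects censored at t remain in the risk set for
events at t — the usual KM convention, stated here because it matters for
tied data. Variance is Greenwood's formula; when the risk set is
exhausted (S = 0) the variance is reported as 0 rather than propagating a
division by zero. Confidence bands are plain (linear-scale) Greenwood
± 1.96·SE clipped to [0, 1]; a log-log transform would behave better near
0/1 but the plain band keeps the report directly interpretable and is
sufficient at the cohort sizes reported.

**Log-rank.** The k-group statistic accumulates observed minus expected
events over pooled event times with the hypergeometric covariance, drops
one group, and inverts the covariance with a pseudo-inverse (guarding
against degenerate risk configurations); the statistic is referred to
χ²(k−1). For k = 2 this reduces exactly to the squared z-form, which the
tests verify.

**KM incidence vs crude proportion.** Published per-category recurrence
figures rarely state whether they are 12-month cumulative incidences or
crude proportions over variable follow-up. The package reports the
12-month KM incidence as the primary quantity (it is the
censoring-correct choice) and emits the crude proportion alongside for
comparison.

## 4. Problem sizes and tolerances

The stochastic self-checks run on cohorts of 10⁴ patients (5×10³ for the
correlation target), sizes at which the Monte-Carlo standard error of a
category proportion is ≈ 0.5 percentage points and of the correlation
≈ 0.01 — comfortably inside the calibration tolerances (±3 points on
proportions, ±0.08 on the correlation, ±0.5 months on median follow-up).
Binomial parameter-recovery checks use 4 standard errors as their margin.
Numeric equality checks against the survival oracle use an absolute
tolerance of 1e-10; scoring itself is integer and exact.

## 5. Known limitations

- The 0/1/2–0/2 point scheme is a reconstruction (see §1); any clinical
  use would need the original weighting confirmed.
- Exponential within-category hazards are a single-parameter convenience;
  they cannot express the early post-blanking recurrence clustering seen
  in practice.
- The calibration ties the generator to one scoring config (the default
  Table-style boundaries); under the `fig6` boundaries the category
  proportions shift and the shipped proportion targets no longer apply.
- `omit_rescale` treats the five observed parameters as exchangeable with
  the full set up to scale, which overweights them slightly for patients
  whose missing LASct would have been normal.
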