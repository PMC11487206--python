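# frailscreen

Wearable-based frailty screening for community-dwelling older adults,
as a tested, reusable analysis pipeline.

Frailty and falls risk are usually assessed with in-clinic instruments —
the FRAIL questionnaire, the Short Physical Performance Battery (SPPB),
the Timed Up and Go (TUG), 4-m gait speed, and the FROP-Com falls-risk
tool. A single ankle-worn wearable recording triaxial acceleration and
interval heart rate can screen for the same constructs passively.
`frailscreen` implements that screening analysis end to end:

* **synthetic cohort generator** — seeded older-adult cohorts with a
  configurable robust/prefrail/frail mix, latent gait and heart-rate
  recovery (HRR) physiology, clinical assessment batteries, and matching
  raw accelerometer (g) and heart-rate (bpm) streams;
* **gait analyzer** — step detection from the vector-magnitude signal,
  walking-bout segmentation with the 40-continuous-step qualification
  rule, cadence/vigor metrics, and an integer 0–5 gait risk score;
* **daily living analyzer** — per-epoch energy (mean squared magnitude
  deviation, g²) normalised to the participant's own 1 step/s walking
  energy, intensity bands (light < 10 %, moderate 10–30 %, high ≥ 30 %),
  and daily kcal classes (low < 521, middle 521–770, high > 770);
* **heart-rate analyzer** — automated HRR: for each run of
  high-intensity epochs, HRR = peak HR − next interval sample, averaged
  into one per-participant statistic (the screener uses its negative, so
  a cutoff of −14 reads "recovery below 14 bpm screens positive");
* **reference standards** — FRAIL scoring (0 robust, 1–2 prefrail, 3–5
  frail) with the functional/nonfunctional split, SPPB totals and the
  gait+balance subset, FROP-Com bands (≤ 11 / 12–18 / ≥ 19), and
  auditable dichotomization of every standard;
* **diagnostic validation** — 2×2 tables, sensitivity/specificity/
  PPV/NPV, ROC over all distinct-score cutoffs, the Youden-optimal
  cutoff J = max(sensitivity + specificity − 1), and trapezoidal AUC
  (for a single operating point, AUC = (sensitivity + specificity)/2).

## Worked example

`examples/05_validation_report.py` simulates a 22-person cohort,
runs all three analyzers and validates the two screeners against eight
reference-standard variants:

```text
           screener           reference  optimal_cutoff  sensitivity  specificity  ppv  npv  auc
      gait_analyzer   sppb_gait_balance        0.500000         0.62         0.89 0.89 0.62 0.78
      gait_analyzer          gait_speed        0.500000         0.82         1.00 1.00 0.85 0.91
      gait_analyzer                 tug        2.500000         0.75         1.00 1.00 0.88 0.92
heart_rate_analyzer frail_nonfunctional      -15.345875         0.62         1.00 1.00 0.64 0.81
heart_rate_analyzer            frop_com      -17.957479         0.75         0.80 0.82 0.73 0.82
...
```

Each row is one screener × reference pair: the cutoff maximising the
Youden index, the 2×2 statistics at that cutoff, and the trapezoid AUC
of the full ROC (AUC > 0.8 = good screener validity). The gait risk
score cutoffs are midpoints between integer scores (2.5 ≈ "score ≥ 3
screens positive"); the heart-rate cutoffs are negative bpm deltas —
weaker recovery screens positive. Structurally excluded pairs (gait
analyzer × nonfunctional FRAIL items; heart-rate analyzer × functional
items) appear as not-applicable rows.

The other examples exercise each capability separately: cohort
simulation (`01`), gait metrics (`02` — detected cadence recovers the
latent cadence to ~1 %), daily energy (`03`), and HRR episodes (`04`).

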