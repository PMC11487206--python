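# Methods

This note documents the models, estimators and design choices behind
`frailscreen`: what is simulated, what each analyzer computes, which
parameters matter, and what the tests do and do not demonstrate.

## Scope and design

The package validates two wearable-derived screener statistics — a gait
risk score and a heart-rate-recovery (HRR) delta — against clinical
reference standards using a 2×2 diagnostic framework with ROC/Youden/
trapezoid-AUC machinery. Because no raw wearable cohort is publicly
available, the package pairs the analysis chain with a first-class
synthetic cohort generator whose defaults encode the study conditions
the analysis assumes. The generator is tested code, not a fixture: its
bookkeeping (injected step counts, latent HRR, scheduled bouts) is the
ground truth that closure and parameter-recovery tests check the
analyzers against.

The package is a library: the importable API plus `examples/` scripts
are the interface. No shell CLI is provided because every entry point
(simulate, analyze, score, validate) is a one-call Python function
(`frailscreen.run_study` runs everything with one seed).

## Synthetic cohort

Each participant has a latent state drawn from class-conditional
distributions:

| quantity | robust | prefrail | frail | notes |
|---|---|---|---|---|
| class probability | 0.41 | 0.45 | 0.14 | cohort mix at n = 22 ≈ 9/10/3 |
| true HRR (bpm) | 25 | 17 | 10 | SD 4; strictly decreasing by class |
| gait speed (m/s) | 1.05 | 0.75 | 0.45 | SD 0.12; cohort mean ≈ 0.83 |
| walk / moderate / high budget (min/day) | 60/120/45 | 40/90/30 | 20/60/20 | drives the activity schedule |

Cadence is coupled to speed, `cadence = 0.5 + 1.15·speed + ε`,
ε ~ N(0, 0.05), clipped to [0.8, 2.4] steps/s — older-adult step lengths
of roughly 0.45–0.6 m. Resting HR ~ N(72, 6) bpm.

Assessments are drawn from class-conditional discrete distributions
calibrated so default-mix cohort moments sit near a typical
community-dwelling fall-risk cohort (SPPB components ≈ 3.3/3.0/2.3,
TUG ≈ 14 s, 36 % fallers, 18 % ADL/IADL limitation). A single
`assessment_noise` knob (default 0.1) is the probability that a
participant's FRAIL score is drawn from a neighbouring band, giving
≈ 90 % agreement between the FRAIL category and the latent class.

### Signal model

Acceleration is in g with time in seconds from recording start; gravity
is a 1 g baseline on the vertical axis plus white noise (SD 0.02 g).
Scheduled bouts are laid out with rest gaps of at least 360 s (more
than one HR sampling interval, so recovery samples never collide with
the next exertion segment):

* **Walking** — each step is a raised-cosine vertical impulse of width
  0.3 s; amplitude `0.35 + 0.25·speed` g encodes gait vigor. A bout of
  n steps at cadence c injects exactly n impulses over n/c seconds.
  One deliberately short 25-step bout is always scheduled so both
  qualifying and non-qualifying runs occur.
* **Moderate / exertion segments** — sinusoidal magnitude oscillations
  with amplitudes computed from the participant's analytic 1 step/s
  walking energy to land at ≈ 18 % (moderate band) and ≈ 60 % (high
  band) intensity. Exertion bouts are aligned to the epoch grid.
* **Heart rate** — strictly periodic samples (default 300 s). Within
  the epoch-grid-expanded window of each walking/exertion segment, HR
  ramps from resting toward resting + gain (50 bpm for exertion, 60 %
  of that for walking); the first sample after the in-window peak is
  set to peak − (true HRR + noise). The expansion matters: partially
  covered epochs still classify as high intensity, so the analyzer's
  run spans whole epochs and must find ramped samples there.

With all noise knobs at zero (`CohortConfig.zero_noise()`) the
generator/analyzer loop closes: detected step count equals the injected
count, cadence is recovered to well under 1 % (limited only by the
sample grid), and mean HRR equals the latent value to one floating-point
rounding (the tests assert 1e-9 bpm).

## Gait analyzer

Steps are local maxima of the vector magnitude √(ax²+ay²+az²) above
1.25 g with a 0.35 s refractory interval (both configurable). The
magnitude is orientation-independent, which suits ankle placement.
Consecutive steps with gaps ≤ 3 s form a bout; "continuous" is not
quantified by any instrument definition, so the 3 s default (a few
missed steps at usual cadence) is configuration. Only bouts of ≥ 40
continuous steps qualify; a participant with no qualifying bout is an
explicit "insufficient gait data" case excluded pairwise downstream.

Metrics over qualifying bouts: step-count-weighted mean cadence;
`swing_power_proxy` (mean squared magnitude deviation within bout
spans, g²) and `toe_off_proxy` (mean step peak magnitude, g) as fully
specified vigor proxies — an inverse-dynamics biomechanics model is out
of scope, and the proxies preserve the monotone relationship to gait
vigor that the screener needs; pooled step-time coefficient of
variation; and the qualified step count.

The 0–5 risk score counts impaired features among low cadence
(< 1.4 steps/s), high step-time CV (> 0.10), low swing power, low
toe-off and low qualified step count. The last three default to
cohort-relative lowest-quartile cutoffs (`cohort_thresholds`): the
proxies are device-specific, so absolute norms do not exist; cadence
and CV use literature-style absolute cutoffs. All are overridable.

## Daily living analyzer

Epoch energy (default 60 s epochs) is the mean squared deviation of the
vector magnitude from 1 g. The energy statistic itself is a
reconstruction: the standard accelerometry surrogate, zero at rest and
quadratic in movement amplitude.

The walking reference rescales pooled qualifying-bout energy by
1/cadence², mapping observed walking to the 1 step/s reference (energy
scales quadratically with cadence). Intensity is
100·energy/e_ref with bands light < 10 %, moderate 10–30 %, high ≥ 30 %;
boundaries are exact (10.0 → moderate, 30.0 → high). Note that
sustained walking itself classifies high (cadence c ⇒ intensity
≈ 100·c² %), consistent with the band anchors ("intermittent walking"
at 10 %, "continuous walking" at 30 %).

Daily kcal = basal + k·Σ(intensity % × epoch hours), basal 400 kcal and
k = 2.8 kcal per %-hour by default — no published conversion exists, so
k is an explicit calibrated config chosen so a day with ~2 h moderate
and ~0.5 h high activity lands in the middle band. Classes low < 521,
middle 521–770 (closed interval), high > 770 kcal/day. Days with less
than 24 h of epochs are flagged partial but still summarised; the
hourly profile is normalised by the day's maximum.

## Heart-rate analyzer

For each maximal run of time-contiguous high-intensity epochs
containing at least one HR sample: peak = maximum HR sample in the run
(earliest on ties, maximising the recovery window); recovered = first
sample strictly after the peak, accepted if within one sampling
interval + 10 % tolerance; HRR = peak − recovered. Runs whose peak is
the final recorded sample yield no episode. The per-participant
statistic is the arithmetic mean over episodes; zero episodes is a
marked-missing result, excluded pairwise from validation.

The "next scheduled sample" reading of the recovery interval is
implemented (under strictly periodic sampling it coincides with a
fixed-lag reading); the tolerance handles jittered streams. The
screener consumes the delta (−HRR) so that more-negative values mean
stronger recovery and negative cutoffs read naturally.

Parameter recovery (100 participants, even robust/frail mix, HR noise
SD 4 bpm, ≥ 5 episodes each): estimator bias < 1 bpm, RMSE < 3 bpm, and
the screener separates the latent frail class with AUC > 0.9. These
simulations use 6 h recordings at 25 Hz with enlarged exertion budgets —
the condition that guarantees several episodes per participant — which
keeps each replicate light without changing the estimator under test.

## Reference standards and dichotomization

FRAIL: score = count of the five deficits; 0 robust, 1–2 prefrail, 3–5
frail; functional sub-score = fatigue + resistance + aerobic (0–3),
nonfunctional = weight loss + illnesses (0–2); the split is conserved
(functional + nonfunctional = total) for every input. SPPB: components
0–4, total 0–12, gait+balance subset 0–8 (the chair-stand component
misclassifies more often, so the subset is a first-class variant).
FROP-Com: 0–60 with bands ≤ 11 / 12–18 / ≥ 19.

The 2×2 framework needs binary conditions, and no instrument defines
them; the defaults are standard geriatric cutpoints — SPPB total ≤ 9,
gait+balance ≤ 6, gait speed < 0.8 m/s, TUG ≥ 13.5 s, any functional or
any nonfunctional FRAIL deficit, any FRAIL deficit for the combined
scale, FROP-Com ≥ 12, ≥ 1 fall for faller status. Every emitted label
records the rule applied, and all cutpoints are free parameters so
alternative choices can be explored.

## Diagnostic validation

Cutoffs are midpoints between sorted distinct scores plus ±∞ anchors —
never raw scores, so strict/non-strict semantics are unambiguous and
the ROC has one operating point per achievable classification.
Youden ties break toward higher specificity, then lower cutoff.
Zero-denominator statistics are reported as undefined, never clamped.
AUC is the exact trapezoid sum over operating points; against binormal
scores it matches the closed form Φ(d/√2) within 0.01 at n = 2000 per
class, and on arbitrary tied data it agrees with scikit-learn's
implementation to 1e-9 (test-only cross-check; the implementation is
independent). Report rates are displayed with half-up rounding to 2
decimals; internal values keep full precision. Structural exclusions
(gait × nonfunctional FRAIL, heart-rate × functional FRAIL) are
configuration mirroring the screeners' sensing domains, not inference.

## What the synthetic data does and does not show

The generator emulates: class-separated HRR with noisy interval
sampling, cadence–speed coupling, activity budgets spanning all three
bands, assessment batteries with realistic cohort moments, and the
40-step bout structure. It does **not** emulate gyroscope/compass
channels, photoplethysmography waveforms, stairs or uneven terrain,
posture, sleep, device artefacts (loose fit, dropout), or intra-bout
cadence drift beyond white timing noise. Passing closure and recovery
tests therefore demonstrates the correctness of the estimators under
the stated signal model — not device-level accuracy on real streams.

## Numerical choices and degenerate inputs

* Simulation sizes: analyzer-level tests use 6 h recordings at 25 Hz;
  default config is 24 h at 50 Hz. Seeds flow from one integer through
  `numpy.random.default_rng`; per-participant streams use child seeds so
  cohorts are reproducible element-wise.
* Exact boundaries everywhere a class edge is defined: 39 vs 40 steps,
  10 %/30 % intensity, 521/770 kcal, FRAIL 0/1–2/3–5, FROP-Com 11/12/18/19.
* Empty inputs: empty accelerometer → empty step list / empty HR stream
  (with a logged warning); no qualifying bouts → missing gait metrics
  and (without a configured fallback energy reference) missing HRR;
  missing statistics are dropped pairwise with the affected counts in
  the report's `n` column.
* Single-class condition vectors make a ROC undefined; the report emits
  a not-applicable row naming the reason rather than guessing.

## Known limitations

The vigor proxies are monotone stand-ins, not biomechanics; the kcal
conversion is a calibrated configuration, not a validated energy
expenditure model; dichotomization cutpoints are defaults, not study
facts; and the validation engine reports no confidence intervals —
at n = 22 the operating-point statistics carry wide sampling error, and
interval estimation is deliberately out of scope.
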