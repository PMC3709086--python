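# Methods

`vitaldrift` analyses the trajectory of five routinely charted vital signs
(heart rate HR, respiratory rate RR, oxygen saturation SpO2, systolic blood
pressure SysBP, tympanic temperature) over a post-operative ward stay, and
scores deterioration against a one-class "model of normality". This note
documents the models, the defaults and the design choices where the design
was genuinely open.

## Cohort model and filters

An observation is a vector **x** ∈ ℝ⁵ at a time *t* (hours since ward
admission). A patient is `normal` (discharged home) or `abnormal`
(re-admitted to the ICU or died on the ward); for abnormal patients the
first event time replaces discharge everywhere. Length of stay is the
number of distinct calendar days touched by a patient's observations
(admission day = day 1); for abnormal patients it is the day index of the
event. Filtering applies in two stages: observations with any missing
vital are removed (patients left empty are excluded), then patients whose
stay falls outside the inclusive 4–29-day window are dropped. Times are
relative hours, never wall-clock datetimes — the analysis uses only
relative time and day indices. Duplicate timestamps are kept: nurses may
chart twice within an hour and both measurements contribute to daily
averages.

## Synthetic cohort generator

The ward data the analysis was designed for are not publicly deposited, so
the generator produces cohorts with the statistical structure every stage
assumes. Its defaults are the study-scale conditions:

* 154 normal and 17 abnormal patients.
* Admission-day marginals (mean, SD): HR 80.6 (12.8) bpm, RR 16.7 (2.5)
  brpm, SpO2 97.0 (1.3) %, SysBP 115.7 (16.0) mmHg, Temp 36.6 (0.5) °C;
  discharge-day marginals HR 81.2 (11.7), RR 15.7 (1.0), SpO2 96.3 (1.5),
  SysBP 132.1 (16.6), Temp 36.4 (0.4).
* Each vital's mean follows an exponential recovery from the admission
  value toward the discharge value, mean(t) = discharge + (admission −
  discharge)·exp(−t/τ) with τ = 1.5 days; the observation-noise SD
  interpolates the two marginal SDs with the same weight. τ = 1.5 days
  makes trajectories visually stable after about four days, matching the
  recovery horizon the analysis expects; only that stabilisation horizon
  is constrained, so the exact constant is a design choice.
* Length of stay: a log-normal with median 9 days and IQR 5 (giving
  quartiles near 7/12), discretised and clipped to [4, 28]; abnormal
  time-to-event uses median 5, IQR 4. Only median/IQR/percentiles are
  specified by the target distributions; the log-normal shape is a choice.
* Charting cadence: an observation every 1–2 h (uniform) for the first
  40 % of the stay, every 4 h thereafter. At these defaults the discharge
  day pools ≈ 900 training vectors and the cohort ≈ 15 000 observations,
  the same order as the ward dataset the structure emulates.
* Deterioration: each abnormal patient receives one or two episode types
  drawn without replacement from {HR→150 bpm (tachycardia),
  HR→45 bpm with SysBP→190 mmHg (bradycardia + hypertension),
  RR→40 brpm (tachypnea)}. Affected vitals ramp linearly from their
  recovery-curve value at the start of a 24-h pre-event window to the
  extreme target at the event time. The series ends with an observation
  charted at the event itself — the measurement that triggers ICU
  admission — so the extremes that define an episode are actually
  observed.
* Noise is independent Gaussian per vital per observation; SpO2 is clipped
  at 100 %. Real vital signs carry within-patient autocorrelation,
  cross-vital correlation, circadian rhythm and treatment effects that the
  generator does not model, so passing tests demonstrate correctness of
  the *methods* under the stated marginal/drift structure, not clinical
  performance. An optional `missing_rate` masks vitals at random for
  filter testing; it defaults to 0.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical CSVs.

## Subgroups and distribution distances

For each patient five daily-average vectors are formed at fixed fractions
of the stay: G1 = day 1, G2/G3/G4 = days at 25/50/75 % of the stay, G5 =
last day. The day index is d_q = 1 + round(q·(L−1)) with rounding half
away from zero (no rounding convention is canonical; half-away keeps the
grid symmetric and endpoints exact). Drift per vital sign is the distance
between the G_i sample and the G5 sample (one value per patient each):

* **Kolmogorov–Smirnov**: sup |P(x) − Q(x)| over the pooled sample points,
  computed directly on the samples (the empirical-CDF definition), not on
  histograms.
* **Symmetric Kullback–Leibler (Jeffreys)**: Σ (p − q)·ln(p/q) over shared
  histogram bins, in nats (natural log is used everywhere in the package
  for internal consistency).
* **Bhattacharyya**: −ln Σ √(p·q) over the same bins.

Histograms use shared fixed-width bins spanning the pooled range of the
two samples, with per-vital default widths HR 5 bpm, RR 1 brpm, SpO2 1 %,
SysBP 5 mmHg, Temp 0.2 °C (configurable). Bins empty in exactly one
distribution make KL divergent; by default an additive smoothing of 1e−10
followed by renormalisation keeps it finite (this contributes a visible
positive bias on sparse tail bins — the test suite accounts for it), and a
`strict` mode returns `inf` as the divergent flag instead. A
Bhattacharyya coefficient of 0 (disjoint supports) also returns `inf`;
coefficients a rounding error above 1 are clipped so the distance is never
negative.

## Normalisation and Sammon mapping

Because the five vitals have very different dynamic ranges, every vector
is z-scored with the mean and sample (n−1) SD of each vital over **all**
observations of the whole filtered cohort (normal and abnormal together).
The Sammon stress of image points y for inputs x is

    E = (1 / Σ_{i<j} D_ij) Σ_{i<j} (D_ij − d_ij)² / D_ij ,

with D the input-space and d the map-space Euclidean distances; the
denominator weights are input-space distances (the conventional form).
Minimisation uses Sammon's diagonal-Newton update with magic factor 0.3
and step halving whenever a step would raise the stress, so the recorded
stress sequence is non-increasing; convergence is a relative stress change
below 1e−7, with a 500-iteration cap (the pipeline default caps at 200,
which at the 770-point study scale reaches stress ≈ 0.07). Image points
initialise uniformly at random in [−1, 1]² from the given seed; a PCA
initialisation exists but is off by default. Duplicate input points (zero
input distance, where the stress is undefined) are skipped in both sums
with a warning — they arise naturally when a 4-day stay maps G3 and G4 to
the same day. If even a vanishing step cannot reduce the stress the
optimiser stops at the local optimum; non-finite stress raises an error.

## Model of normality

The training set pools every observation charted on each normal patient's
last ward day — the most physiologically stable period. The density is an
isotropic-Gaussian KDE in normalised space,

    p(x) = 1 / (N (2π)^{D/2} σ^D) Σ_i exp(−‖x − x_i‖² / 2σ²),  D = 5,

with a single width σ from the nearest-neighbour rule: Δ_i = mean
Euclidean distance from x_i to its k = 10 nearest *other* points (ties at
the k-th distance broken by index order; k reduced to N−1 with a warning
for tiny samples), σ = mean of the Δ_i. Unsquared distances are averaged
and the grand mean is assigned to σ itself, not σ²; a squared-distance
variant of the rule exists in the literature but the unsquared form is
what this package implements. The rule scales exactly: σ(cX) = c·σ(X).

The novelty score is z(x) = −ln p(x), always evaluated with log-sum-exp so
extreme vitals give large finite scores instead of overflowing. The alarm
threshold is k = μ + 3·sd over the per-observation scores of all normal
patients (sample SD); a per-patient variant (average within patients
first) is available, as the reference set is describable either way.

Per-day trajectories average z over each day's observations; abnormal
patients are scored only up to their event. Group trajectories average
across patients per day with SE = sd/√(n patients contributing), the
patient as the unit of analysis, truncated at the group's 75th-percentile
stay (or time-to-event) — day 12 for the normal group and day 8 for the
abnormal group at study scale.

## Pipeline and numerical conventions

`run_pipeline` executes simulate/load → filter → distances → Sammon → fit
→ score and returns a bundle stamped with a hash of its YAML config. One
global seed derives independent per-stage sub-seeds by SHA-256 mixing of
the stage name, so stages can be rerun in isolation. The embedding stage
subsamples to at most 900 subgroup vectors (the study-scale 770 fits under
the cap untouched). Numeric outputs are written with 10 significant
digits.

## Known limitations

* The generator's independence assumptions (no autocorrelation, no
  cross-vital correlation) make the KDE's task easier than on real ward
  data; detection rates measured here do not transfer clinically.
* ε-smoothed symmetric KL is sensitive to the bin width on sparse tails;
  compare only values computed under one binning rule.
* The Sammon optimiser finds local optima; different seeds give different
  (rigidly equivalent or genuinely different) embeddings with similar
  stress.
* The SpO2 > 99 % display exclusion used in histogram figures is a
  plotting concern only; distances are computed on the full samples.
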