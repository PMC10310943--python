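# Methods

This document describes the signal model, the processing pipeline, the
default parameters (with units and rationale), the scope of the synthetic
cohort generator, the statistical and classification layers, and the known
limitations. It documents what the code computes; quantitative performance
claims are made only where the test suite computes them.

## 1. Signal model and geometry

A recording is a sequence of gaze samples `(t, x, y, valid)` at a nominal
60 Hz, with `x`/`y` expressed in degrees of visual angle relative to screen
center. `oculokit.geometry` converts screen millimeters at a known viewing
distance to angles with `angle = atan(offset / distance)` per axis and back;
the round trip is exact to numerical precision. Recordings are validated on
construction: at least 2 samples, non-decreasing time, angles within ±60°
(for valid samples only), and an inter-sample interval consistent with the
declared sample rate.

All detection and scoring operate in degrees and seconds. At 60 Hz the
sample interval is 16.7 ms; a 2° saccade lasts roughly 30 ms, i.e. about two
samples. This undersampling drives every design choice below.

## 2. Preprocessing pipeline

`preprocess_recording` runs, in order: denoising → artifact detection →
velocity estimation → saccade detection. Intrusion detection
(`detect_intrusions`) runs separately over fixation windows.

### 2.1 Denoising

A running median of width `median_window = 3` samples is applied to each
axis. Rationale: a width-3 median removes single-sample impulse noise
exactly while preserving the 1–2-sample position steps produced by small
(~1°) saccades; width-5 or larger medians smear those steps across samples
and pull the resulting speeds below the onset threshold. Recordings shorter
than 5 samples are rejected rather than silently filtered.

### 2.2 Artifact handling

Three artifact classes are detected and merged:

- **Blinks**: runs of invalid samples lasting at least 100 ms.
- **Dropouts**: shorter invalid runs.
- **Spikes**: samples implying radial speed above `max_vel_deg_s = 1000`
  deg/s, which is physiologically impossible for gaze.

Every artifact interval is padded by `artifact_pad_ms = 50` ms on each side,
because the samples flanking a blink are contaminated by lid occlusion
before the tracker flags them invalid. Intervals whose padded spans touch
are merged. Saccade candidates overlapping any artifact interval are
discarded; artifact samples are excluded from fixation analysis time.

### 2.3 Velocity estimation

Radial speed is estimated by central differences,
`v_i = |p_{i+1} − p_{i−1}| / (2Δt)`, with one-sided differences at the ends
and NaN wherever a neighborhood includes an invalid sample. Central
differences halve the noise variance relative to two-point differences but
**underestimate peak speed** for events shorter than ~3 samples — at 60 Hz
this is most saccades below ~4°. The detector compensates (next section)
rather than the velocity estimate, so `velocity()` remains an unbiased
textbook estimator wherever the signal is smooth.

### 2.4 Saccade detection (adapted I-VT)

A plain velocity-threshold (I-VT) detector fails at 60 Hz: small saccades
produce only one supra-threshold sample, the same footprint as a noise
transient. The detector therefore layers four refinements on I-VT:

1. **Candidate extraction.** Runs of samples with central-difference speed
   above `offset_vel_deg_s = 20` deg/s, extended to interpolated 20 deg/s
   crossings (half-sample linear interpolation on the speed trace). The
   20/30 deg/s offset/onset pair is the standard choice for low-rate
   trackers.
2. **Duration gate on the interpolated span.** The refined onset-to-offset
   span must be at least `min_dur_ms = 17` ms. An isolated symmetric noise
   spike refines to ~17 ms, while a genuine small saccade whose step
   straddles a sample interval refines to ~33 ms; a discrete run-length rule
   (e.g. "≥2 supra-threshold samples") would reject both.
3. **Dual lower-bound onset criterion.** The event is kept if
   `max(v_peak_central, v_displacement) ≥ onset_vel_deg_s = 30` deg/s,
   where `v_displacement` is the displacement between the medians of ±6
   samples around the event divided by `2Δt` — the speed the event *must*
   have reached to move gaze that far in at most two sample intervals. This
   recovers small saccades whose central-difference peak is undersampled,
   without lowering the threshold for noise (noise does not displace the
   medians).
4. **Sustained-displacement check.** The post-event gaze position (median of
   the following 6 valid samples) must differ from the pre-event position by
   at least `displacement_check_frac = 0.4` of the event amplitude,
   projected on the event direction. Real saccades relocate gaze
   persistently; oscillatory noise does not.

Event endpoints are refined by the half-sample crossing interpolation;
reported peak velocity is `max(two-point peak, amplitude / duration)` so
that peak ≥ mean velocity holds by construction even for 2-sample events.

**Physical floor.** At 60 Hz a 0.8° single-interval step implies only
24 deg/s of central-difference speed — below the 30 deg/s onset criterion —
so saccades under ~1° are not reliably detectable at tablet noise levels
(0.2–0.5° RMS). The intrusion amplitude floor (below) sits above this limit
on purpose.

### 2.5 Intrusion (square-wave jerk) detection

Within each fixation analysis window, detected saccades with amplitude of at
least `intrusion_min_amp_deg = 0.5`° count as intrusions. The first
`intrusion_skip_ms = 200` ms of each window is dead time so the saccade that
acquires the fixation target is not scored. `intrusion_count_mode` is
`"saccade"` (each intrusion saccade counts) by default; `"pair"` halves the
count to report square-wave jerks (out-and-back pairs) as single events.

## 3. Task metrics

`AnalysisConfig` defaults, with rationale:

| Parameter | Default | Unit | Rationale |
| --- | --- | --- | --- |
| `acceptance_radius_deg` | 2.0 | deg | target reached when gaze dwells within this radius; generous for 5–12° targets, tight enough to exclude mid-flight samples |
| `dwell_ms` | 100 | ms | 6 samples at 60 Hz; shorter dwells can be a saccade passing through |
| `min_saccade_amp_deg` | 1.0 | deg | task-relevant floor, matching the 60 Hz detectability limit |
| `anticipatory_ms` | 80 | ms | latencies below 80 ms precede visual processing and are anticipations; excluded from latency/velocity means but kept in saccade counts |
| `min_fixation_analyzed_s` | 1.0 | s | a fixation trial with less valid time yields unstable BCEA/intrusion estimates and is dropped with a warning |
| `acquisition_search_s` | 0.6 | s | window after fixation onset in which the acquiring saccade is sought |
| `response_dead_zone_deg` | 2.0 | deg | gaze nearer screen center is assigned to no arrow sector when scoring the anti-saccade recognition answer |

- **Fixation**: BCEA at 68% and 95% coverage
  (`area = 2πk·SD_h·SD_v·√(1−ρ²)` with `k = −ln(1−coverage)`), horizontal and
  vertical SDs, and intrusion rate = intrusions / analyzed time.
- **Pro-saccade** (split into short/large eccentricity classes): latency of
  the first target-directed saccade after target onset, first-saccade gain
  (projected amplitude / target eccentricity), absolute landing error, mean
  velocity, and number of saccades to reach the target.
- **Anti-saccade**: error rate (first response toward the cue), corrected
  fraction among errors, recognition rate, and latencies of correct and
  error responses.

The canonical battery is 24 parameters per subject (5 fixation, 7 + 7
pro-saccade short/large, 5 anti-saccade). Missing tasks yield NaN for the
corresponding parameters rather than an error.

## 4. Synthetic cohort generator

The generator exists to give the pipeline ground truth; it is a behavioral
model, not a physiological one. Scope:

- **Schedules**: fixation (5 × 7 s at fixed targets), pro-saccade (24
  trials: 12 short + 12 large eccentricity over 8 locations, fixation
  periods jittered 1–3.5 s), anti-saccade (12 trials by default, balanced
  left/right, arrow at fixation onset + 1.3 s for 0.4 s).
- **Saccade kinematics**: raised-cosine position profile with peak velocity
  from the main-sequence law `V_p = V_max(1 − e^{−A/C})` and duration
  `D = max(15 ms, 2A/V_p)`; landing scatter, multi-step hypometria with
  corrective saccades after a latency.
- **Fixation behavior**: Gaussian sample noise plus slow drift;
  predominantly horizontal square-wave-jerk pairs injected as a Poisson
  process (pair amplitude 1.6 ± 0.3°, truncated ≥ 0.8°; return saccade
  200 ms after the outgoing one) with a refractory dead time so pairs do not
  overlap.
- **Blinks**: Poisson at `blink_rate` per minute, realized as 150–300 ms
  invalid runs kept clear of injected saccades.
- **Group profiles**: `HC_PROFILE` and `PD_PROFILE` differ in the published
  PD direction — more intrusions, hypometric multi-step saccades, shorter
  reflexive latency, steeper small-amplitude main sequence, noisier
  fixation, more anti-saccade errors, lower recognition. Between-subject
  variation (`ProfileVariation`) is drawn per subject; for PD subjects a
  latent severity couples UPDRS-III scores to latency (+), gain (−), landing
  scatter (+), peak velocity (−) and multi-step probability (+).

All randomness flows from a single seed through `numpy.random.SeedSequence`
spawns, so cohorts are bit-reproducible and per-subject streams are
independent.

## 5. Statistics

- **Welch t from summary statistics** with Welch–Satterthwaite df
  (demographics tables typically arrive as mean ± SD).
- **Pearson χ²** on 2×2 tables without continuity correction, matching the
  convention of the clinical literature this battery follows.
- **Benjamini–Hochberg** step-up FDR adjustment, applied *within* each
  parameter family (fixation / pro-saccade / anti-saccade), as is
  conventional for per-table reporting.
- **Severity correlations** on PD subjects: Pearson when both variables
  pass Shapiro–Wilk at `normality_alpha = 0.05`, Spearman otherwise.
- **MANCOVA** per family on group with age and sex covariates, reporting
  Pillai's trace (most robust of the four classical statistics to
  covariance heterogeneity). With a single response, statsmodels' MANOVA is
  undefined, so the code uses the exact analytic reduction: for a 1-df term
  on one response, `F = t²` from the OLS fit, `Pillai = F/(F + df_resid)`,
  and the F(1, df_resid) p-value — identical to the univariate ANCOVA by
  construction.
- **ANCOVA post-hocs** per parameter: partial F for the group term,
  covariate-adjusted group means evaluated at the covariate averages, and
  the percent difference (PD − HC)/HC.

Numerical choices: designs are built as plain numpy matrices with explicit
0/1 codings (PD = 1, M = 1); rank-deficient designs (a constant column) are
rejected with a message naming the column rather than silently producing a
pseudo-inverse fit.

## 6. Classification

A ridge-regularized logistic model (penalty `λ‖w‖²/2` on weights, not the
intercept; default `λ = 1`) over six default features chosen from distinct
parameter families: `fix_intrusion_rate`, `pro_short_first_gain`,
`pro_short_mean_velocity`, `pro_short_latency`, `pro_short_n_saccades`,
`pro_large_first_gain_error`. Fitting uses scipy's L-BFGS on the exact
penalized negative log-likelihood; the result matches scikit-learn's
`LogisticRegression(C = 1/(nλ))` to high precision.

Evaluation is repeated stratified random subsampling (default 1000 splits,
70% of each class to train). Standardization is fit on the training fold
only. AUC uses the Mann–Whitney rank statistic (ties count one half). The
reported ROC is the vertical average of per-split curves on a fixed
101-point FPR grid; AUC and sensitivity/specificity intervals are 2.5/97.5
percentiles over splits; point sensitivity/specificity come from the pooled
held-out confusion counts at the 0.5 probability threshold.

Because cross-validated AUC on small cohorts has high variance, the
package's own stability expectation for the default 50-per-group synthetic
cohort is a declared band of **0.80–0.97** (asserted by the test suite at a
fixed seed), not a point value.

## 7. Reproducibility

Every stochastic entry point takes an explicit seed; derived seeds come from
`SeedSequence.spawn` and are reduced below 2³¹. Parameter tables are written
with 17 significant digits and read back with round-trip float parsing, so
write → read → write is byte-identical. The `run` pipeline writes a manifest
with SHA-256 hashes of all artifacts.

## 8. Limitations

- The detector targets 60 Hz tablet data; at high sampling rates (≥250 Hz)
  its displacement heuristics are unnecessary and a standard I-VT or
  adaptive detector is preferable.
- Saccades below ~1° are below the physical detectability floor at this
  rate and noise level; microsaccade metrics are out of scope.
- The generator models behavior (latencies, gains, intrusion statistics),
  not oculomotor physiology; its profiles encode literature-typical effect
  directions, and absolute effect sizes should not be read as clinical
  estimates.
- Velocity-based parameters (mean/peak velocity) inherit the undersampling
  bias of 60 Hz data even after the detector's corrections; they are
  comparable within a study but not across sampling rates.
- The classifier is a fixed-feature linear model intended as a transparent
  reference, not a tuned diagnostic instrument; no hyperparameter search is
  performed.
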