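# Methods

This note documents the models, parameter choices and numerical decisions
behind `circastress`, and what the synthetic study conditions do and do not
establish about real wearable data.

## 1. Synthetic cohort model (`synth`)

The generator emulates a multi-day ambulatory HRV study: continuous
beat-to-beat recording over `n_days` (default 3), with three daily
stress-induction sessions at 08:30, 14:00 and 22:30, each structured as
5 min rest, 4 min cognitive stress, 5 min rest.  The 4-min stress phase
(within the 2–5 min range typical of timed color-word interference tasks)
is the shortest duration for which a 2-min analysis window, anchored to the
recording start, fits entirely inside the phase; with 2 min no window would
ever be labeled stress.

### Instantaneous RR target

On a 250-ms grid the instantaneous mean RR (ms) is

    RR(t) = [ A0 + A1 sin(wx) + B1 cos(wx) + A2 sin(2wx) + B2 cos(2wx)
              + wander(t) ] * m_stress(t)
            + [ a_LF sin(2 pi 0.1 t) + a_HF sin(2 pi 0.25 t) ] * g(t) * v_stress(t)

with x = t / 2 min and w = 2 pi / 720 per 2-min sample (24-h fundamental,
12-h harmonic).  Components:

* **Circadian mean.**  Population amplitudes (A1, B1, A2, B2) =
  (77.6, −61.0, 2.3, −37.3) ms; per-subject values are drawn with
  between-subject SDs (42.0, 35.2, 27.1, 22.4) and per-day values with
  within-subject SDs (11.1, 10.8, 1.2, 11.2) — so day-to-day rhythm drift is
  deliberately much smaller than cohort spread (std1 < std2, the property
  the rhythm-variability summary measures).  A0 = 900 ms (SD 60 ms across
  subjects), a typical adult resting mean RR.
* **Oscillations.**  A respiratory (HF, 0.25 Hz, 25 ms) and vasomotor
  (LF, 0.1 Hz, 20 ms) component; their common gain is
  g(t) = 1 + 3 z(t) + OU(t), where z = (circadian mean − A0)/A0.  The
  coupling makes short-term variability itself circadian — high vagal tone
  at night raises mean RR and HF/LF amplitude together — so *every* derived
  feature (SDNN, RMSSD, pNN50, band powers, ST1/ST2), not just meanNN,
  carries the 24-h/12-h rhythm, as ambulatory HRV data does.
* **Slow wander.**  Ornstein-Uhlenbeck processes (correlation time 300 s)
  on the mean RR (SD 25 ms) and on the oscillation gain (SD 0.3) supply the
  non-rhythmic low-frequency variability of real recordings; without it,
  2-min windows from the same phase are implausibly homogeneous and the
  classification problem degenerates.
* **Stress response.**  Inside stress phases the mean is multiplied by
  1 − 0.08 and the oscillation amplitudes by 1 − 0.30 (multiplicative drop
  of mean RR and shrink of variability).  No published magnitude exists for
  this protocol; 8%/30% are moderate effects that leave rest and stress
  distributions overlapping across times of day — the regime the method
  targets.  Both are profile parameters.

### Beat generation, noise, artifacts

Beats are emitted by integrate-to-threshold over the rate 1/RR(t)
(cumulative integral crossing successive integers, inverted by linear
interpolation), which conserves elapsed time exactly: sum(rr) equals the
final timestamp by construction.  Measurement noise is Gaussian jitter
(SD 8 ms) on the beat *times*, the way wearable beat detectors actually
err; intervals inherit an MA(1) noise, elapsed time stays exact, and the
invariant t[i] − t[i−1] = rr[i] holds identically (additive white noise on
intervals would either break that identity or accumulate into clock drift
against the wall-clock session schedule).  Sensor artifacts hit each beat
with probability 0.01: missed beats merge two adjacent intervals into their
sum, extra beats split one interval at a uniform fraction in [0.3, 0.7];
both conserve elapsed time and are recorded in a ground-truth mask.
Parameter sets that would drive the instantaneous RR to 50 ms or below, or
jitter an interval non-positive, are rejected with a diagnostic rather than
clipped.

All randomness flows from one seed per subject through
`numpy.random.SeedSequence`; identical inputs give byte-identical
recordings.

### What the generator does not model

No baroreflex dynamics, sleep staging, posture or activity, no
menstrual/age physiology beyond an age label, no PRV-vs-HRV sensor
differences.  Passing tests therefore demonstrate that the *pipeline*
recovers what the model puts in (rhythms, stress responses, artifacts) —
not that any particular accuracy level transfers to field recordings.

## 2. Confidence-ellipse cleaning (`preprocess`)

The printed axis-aligned ellipse equation and the derived major-axis angle
alpha only cohere if the quadratic form is evaluated in the covariance
eigenbasis; the implementation therefore uses the full Mahalanobis form
z' C^{-1} z <= s, which is exactly the rotated-ellipse inequality.
s defaults to 5.991 = chi2(2).ppf(0.95), giving 95% nominal coverage.
Further decisions where the method description is silent:

* Windows are 50 intervals with step 25; the final window is re-anchored to
  the last 50 so the tail is always covered.  An interval flagged in any
  window is removed (conservative), and of a flagged pair the member
  farther from the window median RR is removed (deterministic; ties remove
  the later one).
* Sample covariance uses 1/(m−1); windows whose smaller eigenvalue is below
  10^-6 ms^2 (e.g. constant RR) are degenerate and flagged clean.
* Removed intervals are dropped, not interpolated; downstream features use
  surviving beats with their original timestamps.

Cleaning is not idempotent (a second pass may remove more); the suite
asserts only that a second pass removes no more than the first.

## 3. HRV features (`features`)

Formulas follow the conventions stated in the README exactly, including
three that differ from common variants and are kept deliberately:

* SDNN uses the population (1/N) normalization; RMSSD uses 1/(N−1).
* pNN50 divides the count of successive differences strictly greater than
  50 ms by the *window beat count* N (not N−1).
* ST1/ST2 are the Poincare sum-axis and difference-axis lengths with
  1/(N−1) normalization and no 1/sqrt(2) factor — ST1 here is sum-based and
  ST2 difference-based, the mirror image of the textbook SD1/SD2.  The
  boundary term uses consecutive pairs i = 2..N.

HR averages the two per-minute means of 60000/RR_i (beats/min).  Spectral
features: the window tachogram is cubic-spline resampled at 4 Hz,
mean-removed, fitted with a Burg autoregressive model of order 16
(`statsmodels`' Burg routine), and the AR spectrum
sigma^2 dt / |1 − sum a_k e^{−2 pi i f k dt}|^2 is evaluated on 513 points
over [0, 2] Hz; band powers are trapezoidal integrals.  4 Hz/order 16 are
the common short-term HRV convention; both are configurable.  Windows with
fewer than 20 surviving beats are flagged missing, never dropped, so the
2-min grid stays aligned.  A window is labeled rest/stress only when fully
inside a single annotated phase; boundary-straddling windows are
free-living and never enter training.

## 4. Circadian analysis (`circadian`)

Period spectra are mean-removed real FFTs with amplitude 2|X_k|/n plotted
against period n/k in samples (convenience conversion to hours provided);
total spectral power reproduces the series variance (Parseval check at
1e−8).  Cohort spectra use normal-theory 95% CIs (mean ± 1.96 sd/sqrt(m));
with 20+ subjects the normal vs t difference is negligible.

The two-harmonic fit is solved by variable projection: for fixed w the
amplitudes are an exact linear least-squares solve, and w is optimized by
bounded scalar minimization of the profiled RSS within ±20% of the 24-h
frequency — wide enough for realistic drift, narrow enough that the
fundamental cannot lock onto its own harmonic.  Day-wise fits use each
day's 720 samples; pooled fits use the full series.  The variability
summary follows the convention: std1 = mean over subjects of the SD (ddof 1)
of day-wise amplitudes, std2 = SD over subjects of pooled-fit amplitudes.

## 5. Smoothness-priors detrending (`detrend`)

With H = I and a d-th order difference penalty (d = 2 default), the trend is
(I + lambda^2 D'D)^{-1} x and the residual the high-pass complement.  The
solver uses the Woodbury dual form residual = D'(lambda^{-2} I + D D')^{-1} D x
with a banded Cholesky solve: O(n) memory, no dense inverse, numerically
stable for arbitrarily large lambda (the primal system's condition grows
with lambda^2 and fails in double precision near lambda = 1e8), and
anything in the null space of D — constants and ramps for d = 2 — is trend
exactly.  Agreement with a dense-inverse oracle is tested at 1e−8.

The interior-point residual gain is
lambda^2 (2 sin(w/2))^{2d} / (1 + lambda^2 (2 sin(w/2))^{2d}).  At
lambda = 10000, d = 2 the half-power point is w = lambda^{-1/2} = 0.01
rad/sample = 0.00159 cycles/sample (about a 21-h period at 2-min sampling);
a commonly quoted cutoff of 0.0012 cycles/sample for this lambda matches no
standard half-power or half-amplitude definition, so the package reports
the half-power value.  Consequences worth knowing: the 24-h component
keeps 36.7% of its amplitude (13.5% power; boundary effects push measured
removal on 3-day series to ~90%), while the 12-h harmonic keeps 90% of its
amplitude — detrending at this lambda removes the circadian fundamental,
not the ultradian harmonic.  Session-scale stress deviations (minutes) pass
essentially unattenuated, which is why the residuals preserve the
configured stress depression to within a few percent.

Detrending is applied per subject to the whole multi-day series (a
previous-day reference mode is exposed as an option).  Missing windows are
linearly interpolated before the solve and re-masked after.  No boundary
padding is used; the first/last ~half-filter-width samples carry natural
least-squares edge behaviour.

## 6. Rest/stress separability (`stress_stats`)

SSA, SSE and F follow the two-group ANOVA decomposition with df (1,
n1+n2−2); F equals the squared pooled-variance t statistic (verified
numerically) and p-values use the F(1, n1+n2−2) upper tail.  Groups pool
all rest-phase vs all stress-phase windows across the cohort; no
multiple-testing correction is applied (ten descriptive statistics, not a
discovery procedure).  Degenerate inputs: SSE = 0 with SSA > 0 reports
F = +inf; both zero is an error.

## 7. Classification scenarios (`classify`)

The boosting learner is an external dependency (XGBoost) used under a
narrow contract — binary classification, seedable, gain importances; its
internal objective/split mathematics is not re-derived here.  Grid search
is coordinate-wise (trees {50, 100, 200}, then depth {2, 3, 4, 6}, then
learning rate {0.05, 0.1, 0.3}), selecting by F1 on a stratified 20%
holdout, refitting on the full training split; importances are normalized
gain scores with ties at the top-7 cut broken by feature-name order.
Accuracy is window-level (each 2-min window one sample); subjects are
pooled across train/test, matching the study design being emulated (a
subject-held-out mode exists as a clearly non-default extra).

How the training period itself appears in the cross-period accuracy matrix
is configurable (`own_eval`): "holdout" (default) scores a reserved 20% of
the training selection — an honest generalization estimate with a noisy
(~60-window) diagonal — while "full" scores every window including those
trained on, the protocol cross-period figures in this literature typically
follow, which makes diagonal dominance a property of the *training* fit.
Raw and detrended variants of a scenario share the seed-derived sampling
and split, so their difference isolates detrending.

## 8. Problem sizes and budgets

Test-suite sizes are chosen for tight feedback, not asymptotics: the shared
end-to-end cohort is 20 subjects x 3 days (the scenario-direction checks
run 20 classifier seeds on it); the F-direction check uses ten 3-subject
cohorts without sensor artifacts (isolating the circadian confound — the
cleaning stage is exercised elsewhere) plus a three-seed ablation with the
rhythm and between-subject baseline spread switched off, since removing
per-subject baselines is a detrending benefit distinct from the circadian
one being tested.  Analysis drivers default to 6 subjects.  Coverage and
solver checks use 1e5 points / n <= 200 dense oracles.

## 9. Known limitations

* The generator's stress response is instantaneous and multiplicative; no
  anticipation, recovery kinetics, or inter-session habituation.
* The 12-h harmonic largely survives lambda = 10000 detrending (above);
  scenarios that hinge on ultradian removal would need a smaller lambda.
* vlf over a 2-min window is ill-posed (the band's lowest periods exceed
  the window); it is computed as specified but carries little information,
  and its F statistic is accordingly near 1.
* Window-level accuracy treats overlapping-session windows as i.i.d.;
  session-level voting is available but not the default.
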