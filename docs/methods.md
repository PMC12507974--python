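# Methods

`swaylab` implements the analysis chain of a dual-task posturography
experiment — standing balance recorded on a force plate while a working
memory task is performed under transcranial stimulation — together with
a synthetic-study generator that lets every stage be exercised and
validated without access to human data.

## The measurement model

A trial is a 90-s centre-of-pressure (CoP) recording at 200 Hz with
anterior–posterior (`x`) and medial–lateral (`y`) components in mm.
The per-sample **radial sway** is

    RS_i = sqrt(x_i^2 + y_i^2),

computed on absolute (uncentred) plate coordinates: RS measures distance
from the plate origin, so slow whole-body drifts contribute to it. A
centred variant (axis means removed per trial) is available behind
`centered=True` for analyses that want pure excursion-about-the-mean.

Processing per trial:

1. **Onset trim.** The first 4 s (800 samples) are discarded to remove
   startle transients at stimulus onset.
2. **Mean RS.** The trial average of RS is the primary sway outcome.
3. **Band decomposition.** Each axis is filtered with a 2nd-order
   Butterworth applied forward–backward (zero phase, effective 4th
   order) at a 0.3 Hz cutoff; low-pass and high-pass components are
   normed separately to give slow (feedback-driven drift) and fast
   (corrective adjustment) RS series. Filtering runs on the full
   recording *before* trimming so the discarded onset doubles as filter
   burn-in. Filtering the axes and then taking the norm is the default
   (`band_order="components"`); filtering the RS series itself is kept
   behind a switch, but note a high-pass applied to a non-negative
   series removes its mean, driving band-wise trial means toward zero —
   which is incompatible with fast-band mean sway being a meaningful
   positive quantity.
4. **DFA.** Detrended fluctuation analysis of the trimmed, unfiltered
   RS series: mean-centre, integrate, split into non-overlapping
   windows of size n, remove a least-squares line per window, record
   the RMS residual F(n); alpha is the OLS slope of log F(n) vs log n.
   Defaults: DFA-1, 20 log-spaced window sizes from 16 samples to N/4,
   windows anchored at the series start, tail discarded, no
   reversed-series pass. Anchors: alpha = 0.5 for white noise, 1.5 for
   Brownian motion, H for fractional Gaussian noise, H+1 for fractional
   Brownian motion (all verified by simulation in the test suite);
   1 < alpha < 1.5 is the antipersistent regime typical of quiet
   standing.
5. **Outlier exclusion.** Trials whose mean RS deviates more than k=2
   sample SDs (n−1 denominator) from the participant's mean for that
   condition are flagged, single-pass, and dropped from the model fits.
   The exclusion cell is subject × session × condition by default.
   Two caveats are worth knowing. First, the sample SD bounds |z| at
   (n−1)/sqrt(n), so with 5 trials per cell the k=2 rule cannot fire —
   at the default design the flag exists, is exercised by the tests on
   larger groups, and excludes nothing; studies with more trials per
   cell are where it bites. Second, the alternative reading — pooling
   a condition's trials across the three sessions
   (`outlier_groups=("subject","condition")`, 15 per group) — lets the
   rule fire but mixes sessions with different stimulation means in one
   group, so higher-mean cells lose more upper-tail trials and the
   recovered stimulation contrasts shrink by ~0.1 mm on the default
   synthetic study. Both groupings are offered; neither is innocuous,
   and which one matches a given lab's practice should be decided
   explicitly, not by default.

## The statistical models

Sway outcomes (mean RS, its two band means, and DFA alpha) are fitted by
REML as

    response ~ Stim + Condition + (1 + Trial | Subject)

with treatment coding against Sham and Silent. The cognitive error
score (absolute difference between the true repeat count of a letter
stream and the participant's report) is fitted as

    abs_error ~ Stim + Difficulty + (1 | Subject)

with Easy as reference — a per-trial count has no within-trial slope, so
the random structure is intercept-only. Counts are modelled linearly;
a log-link alternative is out of scope.

Fixed-effect covariance is the conditional GLS form `(X' V^-1 X)^-1` at
the estimated variance components — the convention mixed-model software
reports and the one marginal-means contrasts assume. (The joint-Hessian
standard errors some optimizers return additionally fold in
variance-parameter uncertainty and can differ by several percent for
the intercept; the package's REML fits were cross-checked against R
lme4 on identical data, agreeing in estimates and SEs to ~1e-3 when the
random-effects optimum is interior.) Estimation tries the statsmodels
default optimizer first, then an optimizer ladder; fits whose
random-effect covariance collapses to a degenerate boundary (symptom:
fixed-effect SEs of order 1e6) are rejected and non-convergence is
always flagged, never silently reported.

**Contrasts.** Estimated marginal means are fixed-effect predictions
per Stim × Condition cell; all pairwise differences are tested with
Tukey's studentized-range adjustment over the 9-cell family.
Denominator df use the residual approximation (observations minus fixed
parameters), recorded in every report header. Kenward-Roger and
Satterthwaite df are not available in the chosen stack; df and p-values
shift slightly under those approximations but estimates and SEs do not.

## The modified n-back task

Letters (A–Z excluding X, which resembles the fixation cross) appear
for 0.5 s separated by 2.0-s crosses; a trial holds 34 letters and 35
crosses (87 s of stimulus in the 90-s trial, slack after the final
cross). Easy scoring counts immediate (1-back) repeats; Hard counts
2-back repeats (one intervening letter). Overlapping repeats each count
per qualifying pair — `AAA` scores 2 under the Easy rule — a convention
that matters only for triples, which the stream generator avoids by
planting repeats at least three positions apart, so planted ground
truth is always unambiguous (round-tripped over 1000 seeds in the
tests). Easy and Hard scores are computed independently; no cross-rule
exclusion, since a block uses one rule.

## The synthetic study

`make_design` lays out 28 subjects × 3 sessions (Sham, left-DLPFC and
right-DLPFC cTBS in per-subject random order) × 15 trials — 5 Silent
(positions 1, 2, 8, 14, 15) and blocked sets of 5 Easy and 5 Hard —
i.e. 1260 trial slots and 840 scored task responses. The cTBS
descriptor (3-pulse 50-Hz bursts every 200 ms for 40 s = 600 pulses) is
carried as metadata only; no physiology is modelled.

Effects are injected additively on the linear scale per response, with
a per-subject Gaussian intercept and trial slope, mirroring the
analysis models. Default fixed effects (the package's reference
configuration for a plausible cTBS dual-task study):

| response | Intercept | RDLPFC | LDLPFC | Easy | Hard |
|---|---|---|---|---|---|
| mean RS (mm) | 4.921 | 0.433 | 0.597 | 0.385 | 1.563 |
| DFA alpha | 1.36 | 0.005 | −0.008 | −0.071 | −0.085 |
| error count | 1.95 | 0.72 | 1.57 | — | 1.77 |

Variance components are free parameters set so that full-design SEs are
plausible for a 28-subject study: subject-intercept SD 1.1 mm (RS),
0.04 (alpha), 1.0 (error); trial-slope SD 0.02 mm and 0.001 per trial;
an extra 0.3 mm of trial-level jitter on the RS target on top of the
generator's natural trial-to-trial variability.

**CoP trials.** Each axis is an exact fractional Brownian motion path
(fractional Gaussian noise via circulant embedding — the Davies–Harte
construction, O(n log n) and distributionally exact — cumulated; an
exact O(n²) Hosking recursion is the fallback for the rare
non-embeddable case). Two knobs are controlled per trial:

* *Amplitude:* the axis pair is scaled by `target / c(H)` where `c(H)`
  is the Monte-Carlo-measured expected trial-mean RS of a unit fBm pair
  at Hurst H, so the **expected** trial mean RS equals the linear
  predictor. Per-trial renormalization is deliberately avoided — it
  would destroy sampling variance and make recovery trivially exact.
  The natural between-trial variability of mean |fBm| (CV ≈ 0.3–0.4)
  supplies realistic residual noise.
* *Temporal structure:* the RS series is a nonlinear (norm) transform
  of the axes, so the fBm identity alpha = H + 1 does not hold for it.
  The axis Hurst is instead read off a shipped calibration table
  (`src/swaylab/data/calibration.json`) mapping H → mean realized
  RS-series alpha, measured with 150 replicates per grid point under
  the pipeline's own settings; the table is strictly monotone
  (alpha 1.03–1.70 over H 0.10–0.70) and inverted by interpolation.
  Regenerating it is scripted (`scripts/build_calibration.py`) and its
  stability is itself a test.

Band-wise (low/high) RS effects are represented in the config for
reference only and are matched in direction, not magnitude: the
generator has two degrees of freedom per trial (amplitude, Hurst), so
simultaneously matching four fitted sway models would be
overconstrained. A `hf_mix` knob can add white high-frequency content;
it defaults to 0 so the DFA calibration applies exactly.

**Error counts.** A task trial's absolute error is a Poisson draw with
mean = error linear predictor floored at 0.05; the self-report is
reconstructed as truth ± draw (below the truth when possible). Silent
trials carry no response record. The letter stream itself is generated
with a planted repeat count drawn uniformly from 1–5.

All randomness descends from one root seed through named seed-sequence
branches; any single trial can be regenerated in isolation, and trials
are generated lazily because a materialized full study is ~360 MB.

## What the generator does and does not emulate

It reproduces the design layout, additive condition/stimulation effects,
between-subject heterogeneity, trial-order slopes, fractal temporal
structure of sway, right-skewed trial-mean variability, and integer
error counts. It does **not** model biomechanics (no inverted-pendulum
dynamics), session-level random effects, learning/fatigue beyond the
linear slope, band-specific effect magnitudes, crossover scaling
regimes, or any TMS physiology. Passing recovery tests therefore shows
the *analysis chain* is correct and calibrated for data with this
statistical structure — not that real CoP data satisfies the model.

## Numerical choices and problem sizes

* Recovery experiments average 5 replicate studies in the test suite
  and 8 (sway) / 10 (error) in `scripts/acceptance.py`; a full study
  analysis takes ~1 min, so these runs stay within a few minutes.
* DFA oracle checks use 100 seeds per process at n = 17200 (the
  post-trim trial length).
* Zero-fluctuation DFA windows are dropped with a warning; fewer than 4
  surviving points is an estimation failure, surfaced per trial in the
  metrics table rather than aborting the run.
* Degenerate inputs: groups of one trial are never outlier-flagged;
  non-positive RS targets clip to a 0.1 mm floor; Poisson means floor
  at 0.05; alpha targets outside the calibration range clip to its
  edges.
* Trial files are plain text with a `# fs=...` header; a `time` column
  is accepted if its step jitters less than 1%.

## Known limitations

* Residual df everywhere; no Kenward-Roger/Satterthwaite.
* Under the pooled exclusion grouping, the ±2 SD rule plus
  right-skewed trial means shrinks recovered cell means and
  stimulation contrasts (see above); the per-session default avoids
  this at the cost of never firing on 5-trial cells.
* The error model is linear-Gaussian inference on Poisson counts;
  SEs are honest by simulation calibration but not exact.
* DFA window parameters are conventions; alpha values are comparable
  only under a fixed configuration, which is why the calibration table
  records its DFA settings.
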