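# Methods

This note documents the models, the numerical choices and the open design
decisions behind `rearrest`, in the order the pipeline runs.

## Problem setting

A patient who regains spontaneous circulation (ROSC) after out-of-hospital
cardiac arrest may rearrest minutes later.  The pipeline classifies
rearrest (RA) vs. sustained ROSC (NoRA) from a single post-ROSC ECG window
of `tw` ∈ {1, 2} minutes sampled at 250 Hz in microvolts.  The clinical
cohort this design targets is strongly imbalanced (≈34% RA), which drives
both the classifier construction and the choice of precision–recall
analysis alongside ROC.

## Synthetic cohorts

There is no public post-ROSC ECG corpus, so all development and testing
runs on simulated cohorts whose ground truth is known exactly.

**RR dynamics.** Beat times accumulate interval by interval
(integral-pulse style): `RR_k = mean_rr + lf_amp·sin(2π·0.10·t_k) +
hf_amp·sin(2π·0.30·t_k) + jitter`, with jitter resampled if an interval
would fall below the 0.2 s physiological floor.  Sampling the modulations
at the running beat times, rather than on a uniform grid, reproduces how
autonomic modulation expresses in real RR series.  Ectopic beats
(probability 0.02/beat) shorten one interval by 30% and lengthen the next
by the same amount, preserving downstream beat times — this produces the
NN50 and Poincaré short-axis dispersion typical of irregular post-arrest
rhythms.  If `sdnn_target` is set, the white-jitter SD is solved from
`target² = lf²/2 + hf²/2 + jitter²`.

**Waveform.** Each beat is a difference-of-Gaussians template: a narrow
positive QRS bump plus a lower, slower T bump at 30% of the following
interval.  The template is analytically integrable, so amplitude and area
oracles are closed-form.  The QRS *width* parameter is defined as the
interval between the points where the slope magnitude falls to 10% of its
extremum (σ = width/5.46) — deliberately the same convention the wavelet
delineator measures, so the generator's width is the delineator's ground
truth.  Additive disturbances: a baseline-wander sinusoid (< 0.5 Hz),
white noise, and sparse ±spike artifacts (3-sample, Poisson arrivals).

**Cohorts and class effect.** `round(n·prevalence)` patients are labeled
RA (defaults: n = 162, prevalence 55/162, the reference cohort split).
Between-patient heterogeneity applies lognormal scale factors (σ = 0.35)
to the modulation amplitudes, jitter and QRS amplitude, and a normal
perturbation (SD 0.08 s) to the mean RR.  RA patients get class-effect
multipliers, by default ×2.5 on the LF/HF modulation amplitudes, ×1.2 on
white jitter, ×2 on QRS-width jitter.  The asymmetry between the
structured (×2.5) and white (×1.2) components is deliberate: scaling every
RR component uniformly leaves sample entropy exactly invariant (the
tolerance r is proportional to the SD), whereas making the extra RA
variability predominantly sinusoidal yields the clinically observed
pattern of a *more variable yet more regular* RA series — higher SDNN and
SD2², lower sample entropy, and a correspondingly lower relative QRS power
with wider width jitter.  One master seed spawns per-patient substreams,
so cohorts are bit-reproducible and independent of patient order.

**What the simulator does not model** — and hence what passing tests do
not show about real data: chest-compression artifacts, electrode motion
and contact noise, rhythm transitions (VF, asystole, paced rhythms),
morphology changes beyond width jitter, and any physiologic coupling
between HRV and outcome.  The class effect is a controlled, planted
difference, not a claim about the clinical population; the pipeline's
near-perfect AUROC on effect cohorts characterizes parameter recovery,
not clinical performance.

## Conditioning and segmentation

Order-4 Butterworth band-pass 0.5–40 Hz applied forward–backward
(`sosfiltfilt`), doubling the magnitude order and cancelling phase so
R-peak positions shift by ≤ 1 sample.  Reflect padding of three seconds
suppresses edge transients in 1-minute windows.  The analysis segment is
the half-open window `[t_ROSC, t_ROSC + 60·tw)`; records without a full
window are skipped with a logged warning.

## QRS detection and signal quality

**Primary detector** (Hamilton–Tompkins family): zero-phase 8–16 Hz
emphasis, one-sample derivative, rectification, 80 ms moving-window
integration; candidate local maxima at ≥ 200 ms spacing feed running
signal/noise peak estimates with threshold `npki + 0.3125·(spki − npki)`;
when no beat arrives within 1.5× the running mean RR a single searchback
pass at half threshold is attempted per candidate.  Accepted peaks are
refined to the local |ECG| extremum within ±40 ms.  Detections within
200 ms of a segment edge are discarded — a partially rendered complex at
the boundary is not scoreable, and both detectors apply the same guard so
the agreement index is not penalized at the edges.

The signal estimate deliberately has no passive decay: a large in-band
artifact inflates it and the detector then misses subsequent beats.  This
is the failure mode the **variance correction** exists to repair: a
sliding 1 s variance is computed; samples in windows exceeding 5× the
median window variance are clipped to the 99th amplitude percentile of
the remaining signal; the detector re-runs on the clipped trace and the
two annotation sets merge (union, 200 ms deduplication, original index
kept on collision).  The merge can never remove an original beat, and on
clean signals no window crosses the threshold, so the correction is the
identity there.

**Secondary detector** (curve-length transform): 16 Hz low-pass, arc
length `√(c² + Δy²) − c` accumulated over a 130 ms window (c = 4 µV per
sample balances the time and amplitude terms), then the same adaptive
machinery with a lower threshold fraction (0.2).  Integrating arc length
over a window makes it more sensitive than the primary at low SNR, which
is exactly why agreement between the two is a useful quality index:
`bSQI = matched/(|a| + |b| − matched)` with greedy one-to-one matching at
150 ms tolerance (the standard tolerance in the beat-agreement
literature).  bSQI is reported per record, never used to exclude records.

**RR series.**  Intervals outside [0.2, 3.0] s (artifact gaps, missed
beats) are dropped individually; neighbours are kept.  Each retained
interval is timestamped with its terminating beat for spectral analysis.

## HRV features (v1–v17)

Time domain: mean (v1), sample SD (v2, n−1), RMSSD (v3), v4 = v2/v1, NN50
count at 50 ms (v5), interquartile range with linear-interpolation
quantiles (v6).

Frequency domain: Lomb–Scargle periodogram of the mean-subtracted RR
values at their beat times, evaluated on a fixed 0.005–0.5 Hz grid with
0.0025 Hz steps (resolves the LF lower edge for 1-minute windows; peak
frequencies quantized to the grid step).  The raw periodogram is rescaled
by `2T/N` so grid-integrated power approximates the series' variance
(within 20% for well-sampled tones).  v7/v9 are trapezoid-integrated LF
and HF powers; relative powers normalize by LF+HF — not total power — so
v8 + v10 = 1 and v11 = v8/v10 are mutually consistent (the alternative,
total-power normalization, is noted as an open choice in the literature
this follows).

Nonlinear: Poincaré v14 = var((RR_{k+1}−RR_k)/√2), v15 =
var((RR_{k+1}+RR_k)/√2) (sample variances; v14 equals half the variance of
successive differences exactly), v16 = v14/v15, with v16 flagged missing
when v15 is at float-rounding scale.  Sample entropy (v17): cubic spline
of (interval-end time, RR) onto a 10 Hz grid spanning the interval
timestamps (≥ 10 s required), then SampEn with m = 1, Chebyshev distance,
r = 0.2× the interpolated series' SD — the universal convention, and the
one that makes v17 scale-invariant.  Template counts follow the standard
definition (both m- and (m+1)-templates counted over the first N−m
positions, self-matches excluded); a constant series returns exactly 0.

## Waveform features (v18–v21)

Welch PSD with 12 s Hann windows, 50% overlap, 4096-point FFT (grid step
250/4096 ≈ 0.061 Hz).  v18 is the PSD centroid and v20 the 5–14 Hz band
fraction, both summed over the full grid (the conditioned signal carries
negligible power outside 0.5–40 Hz).  v19 is the mean absolute amplitude
of the filtered segment.  v21 delineates each QRS on the scale-2² detail
of an à-trous quadratic-spline wavelet transform (lowpass [1,3,3,1]/8,
highpass [2,−2]): the QRS produces a modulus-maxima pair of opposite sign
flanking the R peak; onset/offset are the 10%-of-maximum crossings within
±120 ms, and v21 is the sample SD of the widths.  Beats failing
delineation are excluded; fewer than 3 successes (or under half of all
beats) flags v21 missing.  Constant group delays cancel in width
differences, so filter-delay compensation is unnecessary.

## Classifier

`BalancedRandomForest` grows B = 300 unpruned CART trees (Gini,
⌈√p⌉ features per split).  Per tree: draw ⌈0.05·n⌉ instances with
replacement, then oversample the minority class within the bootstrap to
exactly 50/50; the out-of-bag set is everything absent from the
pre-oversampling bootstrap.  A 5% bootstrap of n = 162 is 9 instances and
can miss a class entirely: the bootstrap is redrawn (≤ 50 tries), then one
random instance of the absent class is forced in.  The positive-vote
fraction is the likelihood (multiples of 1/B); a 0.5 tie predicts the
negative class (deterministic, conservative toward the majority).

Permutation importance compares each tree's OOB error before and after
permuting one feature within the OOB rows; the reported importance is the
mean increase normalized by its SD over trees (the classical OOB z-score;
the raw mean is retained).  `TwoStageRandomForest` ranks features by this
importance (ties toward the lower index), refits on the top N_f, and
scores with the stage-2 model only; stage 1 and 2 use independent
substreams of one seed.  The default N_f is all features — adding
features monotonically improved both areas in the design experiments, so
the sweep is an analysis tool rather than a default.  The univariate
baseline is a logistic regression on one feature with class weights
inverse to class frequencies.

A note on invariances: trees split on order statistics, so scores are
exactly invariant to affine feature rescaling (units) and to any strictly
monotone transform *as ranked on the fitted instances*.  For unseen
points, CART's midpoint thresholds can move relative to the data under a
nonlinear monotone map; the effect on AUROC is marginal (tested at ±2
points) but not identically zero.

## Evaluation protocol

Patients (never segments) are partitioned: within each class, shuffle and
deal round-robin into k = 5 folds, so positive counts differ by ≤ 1
across folds and every patient appears in exactly one test fold per
repetition.  Per fold, median imputation is fitted on the training
patients only, the two-stage forest is trained, and test patients are
scored; the five test folds of a repetition are pooled before curves are
computed (one curve per repetition; per-fold choices would be too noisy
at ~32 test patients).  The default is 100 repetitions; the test suite
and acceptance script use 20 to stay within desk-scale runtimes.

Thresholds are the unique scores with ≥-threshold prediction.  AUROC is
the trapezoid over the ROC path (equal to concordant-pair counting with
half credit for ties).  AUPRC uses a rectangular step rule; the default
*conservative* variant weights each recall increment by the precision at
the previous threshold, which keeps the expected area of a random
classifier at the class prevalence — the classical upper-step
(average-precision) rule counts each newly retrieved positive in its own
precision and is biased upward by about two points at n = 162 (both
variants are available via `pr_rule`; PR trapezoids are avoided
entirely).  The F1-maximizing threshold is selected per repetition on the
pooled test scores (ties toward higher specificity); selecting on test
scores is mildly optimistic but matches how operating points are usually
reported alongside such curves, and the threshold is reported with the
metrics.  Repetitions aggregate as median (IQR); the "median repetition"
(closest AUROC to the median, ties to the lower index) is the one whose
curves are exported.  Feature-set comparisons use a two-sided
Mann–Whitney U on per-repetition metrics.

A methodological caveat: a single simulated 162-patient *null* cohort
(class effect disabled) carries a chance feature–label association worth
several AUROC points in either direction, so chance-level behavior is
verified by pooling repetitions over several independent null cohorts —
the same quantity, estimated with the cohort-level variance averaged
down.

## Degenerate inputs and missing values

Every feature has a missing state (NaN): fewer than 2–3 intervals for the
time-domain set, fewer than 8 for the spectrum, zero band power for the
ratios, a sub-10 s span for sample entropy, failed delineation for v21,
and an empty detection for everything.  Missing values are imputed with
training-fold medians inside the evaluation loop only.  Flatline or
sub-5 s segments raise or return empty annotations rather than fabricate
beats; both annotation sets empty makes bSQI undefined (reported as
missing, never as 0).

## Problem sizes

Defaults mirror the reference conditions: 162 patients (55/107), tw = 2
min, 250 Hz, B = 300, 5% bootstraps, 5 folds.  The acceptance script runs
20 CV repetitions on one effect cohort and 4 repetitions on each of 5
null cohorts, 1000 random-score draws for the baselines, and 20-patient
cohorts for detector quality — sizes chosen so a complete from-scratch
run finishes in a few minutes on one CPU while keeping every estimate's
sampling error well inside the bands it is checked against.

## Known limitations

* The variance-correction thresholds (1 s windows, 5× median variance,
  99th-percentile clip) are this implementation's concrete choice; the
  design is specified by its purpose (rescuing threshold-suppressed
  beats; identity on clean data), not by a published parameterization.
* The wavelet delineator's thresholds (scale 2², 10% crossing, ±120 ms)
  are fixed; ground-truth width recovery on synthetic beats (±20%) is the
  accuracy surface, and absolute onset/offset placement is not validated.
* Sample entropy at 1-minute windows rests on ~600 interpolated points;
  its variance is visibly larger than at 2 minutes, consistent with the
  general behavior of short-segment HRV estimators.
* No powerline notch, no resampling, no multi-lead support, and no
  probability calibration of the vote fractions.
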