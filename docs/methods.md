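# Methods

This note documents the models, defaults, and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the
design decisions taken where more than one reasonable reading existed.

## Task model and synthetic sessions

A session is a sequence of self-paced two-alternative forced-choice trials.
Each trial has an initiation time (nose-poke), a stimulus-touch time, and —
on correct trials — a reward-retrieval time; conditions are stimulus
contrast (difficulty: easy = −1, hard = +1) and target location (left = −1,
right = +1).  The generator enforces the task's structural constraints:

* **Balanced design.** `n_trials` must be divisible by 4; the four
  difficulty × location types appear equally often.  The target location
  never repeats more than 3 consecutive trials; the sequence is drawn
  left-to-right with types weighted by their remaining counts and the
  run-extending location masked, restarting on the (rare) dead end.
* **Reaction times** to touch are truncated normal per difficulty
  (truncation 0.5–15 s; trials slower than 15 s are excluded from analysis,
  so the generator never produces them).  Defaults: easy 4.5 ± 1.0 s, hard
  5.5 ± 1.0 s — within the ranges typical of this task (≈ 4–5 s easy,
  ≈ 5–6 s hard).  The truncated normal matches the first two moments that
  behavioral reports provide; real reaction-time distributions are
  right-skewed, which the generator does not reproduce.
* **Accuracy** defaults to 0.99 (easy) and 0.80 (hard); hard-condition
  contrast is typically calibrated to hold accuracy between 60% and 90%,
  and 0.80 sits mid-range.  Analyses use correct trials only.
* **Inter-trial interval** is fixed at 10 s so that a full 7-s baseline
  window always precedes initiation.  Real ITIs are variable and sometimes
  shorter; the baseline-statistics code flags and excludes trials with
  truncated baselines, and that path is tested, but the default generator
  never exercises it.
* **Spike trains** are inhomogeneous Poisson, sampled by thinning against
  the envelope rate so the realized process is exactly Poisson with rate
  λ(t) = baseline + amplitude · exp(−(t − t_align − latency)² / (2σ²)) on
  trials matching the unit's preferred condition, baseline elsewhere,
  floored at 0.  Baseline defaults: RS 2.88 Hz, FS 6.56 Hz.  The Gaussian
  bump is a deliberate idealization of "preference confined to a brief
  epoch"; real preference episodes need not be symmetric or unimodal.
  Poisson spiking ignores refractoriness and rate autocorrelations, so
  passing tests demonstrate correctness of the estimators under the stated
  model, not robustness to non-Poisson firing.
* **Raw traces** superpose a biphasic template (negative trough, positive
  peak `peak_to_trough_ms` later) at each spike time on white Gaussian
  noise.  No drift, no LFP, no correlated noise, no electrode nonlinearity;
  detection/sorting scores on these traces are upper bounds relative to
  real data.

Everything is seed-deterministic: the same seed reproduces spike times
bit-identically.  Seeds for sub-streams are derived with
`numpy.random.SeedSequence`.

## Detection and sorting

Filtering is a 4th-order Butterworth high-pass at 300 Hz applied
forward–backward (`sosfiltfilt`), chosen zero-phase so event times agree
between raw and filtered traces.  The detection threshold is −4 × SD with
the SD taken over the entire filtered trace (the simplest literal reading;
robust estimators such as median/0.6745 were deliberately not used), with a
2-ms deadtime.

Snippets default to 1 ms before / 2 ms after the event sample.  The event
sample is the trace minimum within one deadtime after the crossing,
localized to sub-sample precision by a parabolic fit and extracted on the
fractional grid by linear interpolation.  Threshold-crossing alignment is
available (`align_on_trough=False`) but not the default: crossing times
jitter by ±1 sample with noise, which displaces otherwise identical
waveforms enough that k-means splits a single unit into several phase
clusters and template merging cannot repair it.

Sorting is three-stage: k-means with `k_over` clusters (default 10) on a
random subset of ≤ 5000 snippets; average-linkage agglomeration of the
cluster centroids, merging below 0.5 × the median inter-centroid distance
(no principled threshold exists for this step; the fraction is
configurable); every event assigned to the nearest merged template
(Euclidean distance on the snippet vector).  Templates attracting fewer
than 2% of events are dropped and their events reassigned — these are
almost always spike-overlap artifacts; overlapping-spike resolution is out
of scope.

Cell types: the RS/FS cutoff is the 10th percentile of the pooled
peak-to-trough duration distribution (on large real datasets this lands
near 0.52 ms).  Durations above the cutoff are RS, below FS; a duration
exactly at the cutoff is RS (the published rule uses strict inequalities
and leaves equality undefined; RS is the more common type, so ties go
there).

## PETHs and baseline normalization

Counts use half-open bins [left, right) so a spike on an edge belongs to
exactly one bin; 200-ms bins over [−2, 3] s around target touch by default
(initiation alignment and a [−6, 3] s window are configurable).  The
baseline is the 7 s before initiation cut into the same 200-ms bins; the
per-trial mean and SD of those 35 bin counts are averaged across trials to
one session-level mean/SD per unit, and z = (count − mean)/SD.  Whether
the normalizing SD should be per-trial or session-level is ambiguous in
common usage; session-level was chosen because per-trial SDs of 35 Poisson
counts are noisy (and occasionally zero), which would inject trial-to-trial
scale noise into every downstream statistic.  A unit whose baseline SD is
exactly zero (silent or perfectly regular) borrows the SD pooled across
all units' baselines, with a logged substitution.

## Bin-wise GLM and the contiguous-bin criterion

Per bin, ordinary least squares of z across trials on an intercept,
Difficulty (±1), Location (±1), and optionally their product.  The fit is
closed-form and vectorized over bins ((XᵀX)⁻¹XᵀY for the trials × bins
response matrix), which is what makes 100 shuffles per unit cheap; the
coefficient-identity test (β_D = half the hard-minus-easy condition-mean
difference on balanced designs, exact) pins the implementation against an
independent computation.  Per-variable significance uses the partial
F statistic — the squared t of that coefficient on F(1, n−k).  An omnibus
model F cannot attribute preference to a specific variable, which the
difficulty/location/both classification requires, so the per-coefficient
form is used.

The null calibration permutes whole condition rows jointly (difficulty and
location stay paired), preserving the four-type balance; independent
per-variable permutation is the main alternative and would only loosen the
null.  Run lengths of consecutive p < 0.05 bins are pooled across 100
shuffles and both main variables; the threshold is the nearest-rank 95th
percentile of realized runs (defined 0 when no run occurs).  Under the
standard design (56 trials, 25 bins) the probability that a chance run
extends past one bin is just under 0.05, so the threshold is 1 bin and
preference requires ≥ 2 contiguous significant bins — the acceptance
script recomputes exactly this.  A unit's preference peak is the bin with
the largest |coefficient| inside qualifying runs (ties to the earlier
bin); its sign is the preferred condition.  Units significant for both
variables yield one call per variable.

## Peak-time clustering

Clustering operates on preference-peak latencies only (1-D), not whole
coefficient series: preference is transient, so whole-series distances are
dominated by the uninformative majority of the trial.  Groups are
(cell type, variable, peak sign); RS-only by default since FS counts are
typically too small for a stable tree.  Ward linkage; the dendrogram is
cut at 95% of the maximum merge height and families are the connected
components below the cut.  "95% of the full tree" could also be read as a
leaf-count criterion; the height cut is the default because it is
well-defined for any tree shape, and the `fraction` parameter exposes the
knob.  Family summaries are unweighted means across member units of the
coefficient series and per-condition trial-averaged z-PETHs, plus paired
t-tests of epoch-mean firing between condition levels (default epochs:
stimulus viewing [−2, −0.5] s, reward acquisition [0.5, 2.5] s).

## Population decoding

Features are spike counts in 400-ms windows sliding in 100-ms steps over
[−1, 1] s around touch, divided by the window length (raw rates; a
standardization toggle exists but is off by default since the linear SVM
on same-unit features across folds does not require it).  The classifier
is a linear-kernel SVM with C = 1 — a conventional choice for the
high-dimensional, few-trial regime; both are configurable.

Cross-validation is leave-one-out with one adjustment: each training fold
also drops one random trial of the class opposite the held-out trial, so
folds stay class-balanced.  Plain leave-one-out under-represents the
held-out class by one training trial, which biases chance-level accuracy
below 50% by roughly 1/(2 × trials) (measured −0.015 at 40 trials) and
would make shuffle controls systematically anti-conservative references.
With the balanced fold the shuffle control is centred on 50% (measured
0.508 ± 0.012); plain folds remain available via
`balance_training=False`.

Pooled decoding assembles pseudo-simultaneous populations: per iteration,
20 trials per condition are sampled from each session with enough trials,
unit features are concatenated across sessions with one condition's trials
in the first half of the matrix and the other's in the second, and
leave-one-out accuracy is computed per bin; 15 iterations.  This assumes
trials are exchangeable across sessions within a condition — no
cross-session noise correlations exist or are simulated.  Significance is
a per-bin paired t-test between test and shuffle series across replicates
(sessions or iterations), Bonferroni-corrected over bins.

## Summary statistics

The count-bias test is the standard one-df goodness-of-fit chi-square of
two counts against equal expectation, Σ(O − E)²/E with E = (n₁ + n₂)/2.
Note that published values for this comparison are sometimes about twice
this statistic for the same counts; the package reports the standard form
and makes no attempt to reproduce a nonstandard one.  Peak-time uniformity
is a one-sample Kolmogorov–Smirnov test against the uniform distribution
on the analysis window.  No multiple-testing correction is applied to
these report-level contrasts; Bonferroni is used only for the per-bin
decoding tests.

## Numerical conventions and degenerate inputs

* Percentiles: cell-type cutoff uses linear interpolation
  (`numpy.percentile`); the run-length threshold uses nearest rank, since
  run lengths are small integers and interpolation would manufacture
  non-integer thresholds.
* Bins are half-open everywhere; a spike on an edge is counted once.
* Zero-variance bins (constant z across trials) get F = 0, p = 1 rather
  than NaN.
* Flat traces (SD = 0) detect nothing, with a warning.  All-identical
  waveform durations label every unit RS, with a warning.  Singleton
  clustering groups yield a one-leaf tree, with a warning.
* Identical test and shuffle accuracy series give p = 1 (no evidence), not
  NaN.

## Problem sizes

The test suite and acceptance script run the full method at the study's
natural per-session scale (56 trials, 25 bins, 100 shuffles per unit) with
100 null units for calibration checks, 50 injected units for parameter
recovery, and 4 sessions × 12 units for decoding comparisons — sizes at
which every statistical check has comfortable power while the whole suite
completes in a few minutes on one core.

## Known limitations

* No drift correction, artifact rejection is a simple amplitude criterion
  at best, and overlapping spikes are neither resolved nor modelled beyond
  being discarded as small clusters.
* The GLM is ordinary linear on z-scored counts; Poisson regression might
  be preferable for very low rates but is out of scope.
* Cluster families have no stability/bootstrap assessment.
* The behavioral generator does not model error dynamics (post-error
  slowing, lapses) or any within-session nonstationarity.
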