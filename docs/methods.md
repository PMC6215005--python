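# Methods

`nogodecode` implements a data-driven pipeline for predicting
inter-individual response-inhibition performance ("good" vs "bad"
performers) from Go/Nogo EEG, together with a synthetic cohort generator
that gives every stage a recoverable ground truth. This note documents
the models, the tunable parameters, the numerical choices, and what the
synthetic validation does and does not establish.

## Behavioral model and group formation

Performance is summarized by the speed-accuracy ratio

    ratio = 100 * (1 - FA) / RT   [percent / ms],

the percentage of correctly inhibited Nogo trials divided by the mean Go
hit reaction time. Larger is better: at the default simulation means
(FA = 12%, RT = 348 ms) the ratio is ≈ 0.253 %/ms, matching the
magnitude a cohort with these statistics produces. Subjects are excluded
when their mean Go RT exceeds the cohort mean + 3 SD (computed before
any exclusion) or when false alarms and/or misses reach 50%. The
remaining cohort is split at the median ratio into equally large "low"
and "high" groups; ties at the median are broken by stable subject-ID
order so the groups are always as equal as possible (for odd N the low
group receives the median subject).

## Preprocessing

Stages run in a fixed order: artifact rejection → current source
density (CSD) → baseline correction → condition averaging.

* **Rejection** drops a trial when, on any channel, any sliding window
  (step one sample) of 100 ms has a peak-to-peak range above 200 µV, or
  any 200 ms window has a range below 0.5 µV ("activity" is read as
  peak-to-peak range). Window length in samples is `round(ms·fs/1000)`.
  Rejection operates on µV data, before CSD, because the thresholds are
  voltage criteria. The implementation screens trials with cheap
  necessary conditions (global range, aligned half-windows) and runs the
  exact sliding scan only on flagged trials; a brute-force scan over all
  window positions serves as the test oracle.
* **CSD** is a spherical-spline surface Laplacian (Perrin-style g/h
  expansion): spline order m = 4, Legendre truncation n = 10, and a
  ridge `smoothing_lambda` (default 1e-5) on the spline system's
  diagonal. Electrode positions come from the standard 10/20 montage,
  sphere-fit and projected to the unit sphere. The operator is built so
  that a degree-l spherical harmonic maps to +l(l+1) times itself
  (verified to <1% against the analytic eigenvalue on dense montages for
  l ≤ 4); output is reference-free and reported per unit-sphere area.
  The recording software's "precision 2.72^-7" setting has no standard
  equivalent; smoothing is exposed as the configurable ridge instead.
* **Baseline**: per trial and channel, the mean over −200..0 ms is
  subtracted. CSD and baseline are both linear and commute (tested).
* **Averaging** uses only correct trials (Go responses within the
  deadline; Nogo without any response). Subjects with zero retained
  trials for a condition are listed and excluded, never NaN-filled.

Classical ERP quantification: P1 and N1 by local-maximum peak detection
(90–110 ms and 170–190 ms at PO9/PO10), N2 and P3 by mean amplitude
(250–280 ms at Cz; 370–410 ms at FC1 and P1). If a window contains no
interior local extremum the window extremum is returned with a fallback
flag rather than failing. Electrode choices can be validated
topographically: per electrode, the subject-wise mean |amplitude| is
compared against the average of all other electrodes with a paired
one-sided t-test at the fixed Bonferroni-style threshold p = 0.0007.

## Time-frequency decomposition

The Morlet wavelet is taken in the exact printed form

    W(t, f) = A exp(−t²/σt²) exp(2iπft),  A = (σt√π)^(−1/2),

with σf = f0/ratio (ratio 5.5), σt = 1/(2πσf). Note the Gaussian
exponent is −t²/σt², not −t²/(2σt²): the worked resolutions
(2σf = 1.09 Hz at 3 Hz; 2σt = 350 ms and 2σf = 1.82 Hz at 5 Hz) are
reproduced exactly by these closed forms, so the form is kept verbatim.
One printed value (2σt = 1770 ms at 1 Hz) is inconsistent with the
closed form (1750.7 ms); the closed form is followed. A consequence of
the verbatim exponent is that the effective Gaussian time-sigma is
σt/√2 and the effective spectral sigma is √2·σf — the wavelet is √2
broader in frequency than the nominal σf.

Total power is computed per single trial (squared magnitude of the
complex convolution, zero-padded at the epoch edges) and then averaged
over trials, retaining non-phase-locked activity. Kernels are truncated
at ±5σt (Gaussian tail < 1e-5). The transform is evaluated as one dense
matrix product per subject (signals × banked kernel values), which is
numerically identical to direct convolution (tested to 1e-10) and fast
on the restricted output grid the feature banks need. Output samples
within one wavelet duration (2σt) of an epoch boundary are flagged as
edge samples; at 1–2 Hz with ±2 s epochs this affects much of the axis,
which is why the long epochs exist. Flagged columns stay in the feature
bank (carrying an `edge` descriptor flag) so the documented grid counts
hold; they can be excluded with an option.

Theta band power for the classical analysis is the mean over 5–6 Hz,
240–320 ms, pooled over FCz and Cz.

## Feature banks and selection

Candidate features are every (channel, time) sample of the correct-Nogo
ERP average in 0..1.5 s (inclusive; 64 × 385 = 24 640 columns at full
scale) and every (frequency, channel, time) cell of correct-Nogo total
power on the 1..18 Hz grid (18 × that). All features are z-scored
across subjects (population SD, divisor N; configurable). In "paper
mode" normalization and selection use the full analysis set; in "nested
mode" normalization statistics and selection come from training subjects
only.

Selection is a hybrid filter–wrapper:

1. **Filter**: two-sample t-test per column (Welch by default; the
   pooled-variance statistic is an option), keep p < 0.01 strictly.
2. **Wrapper**: sequential floating forward selection (SFFS). Forward
   steps add the candidate maximizing the stratified 10-fold
   cross-validated accuracy of an RBF-SVM
   (K(x,y) = exp(−‖x−y‖²/(2σ²)), σ = 5, cost C = 1); after each
   addition, backward steps remove any member whose exclusion strictly
   improves the best accuracy known for the smaller size. Folds are
   drawn once per run from the seed, so results are reproducible.
   Ties between candidates are broken by smaller filter p-value, then
   column order.

With 240 subjects and k = 10 each test fold has 24 subjects, so fold
accuracy is quantized in steps of 1/24 ≈ 4.17%. Per-step uncertainty is
a Student-t interval over the k fold accuracies
(mean ± t_{0.995,k−1}·sd/√k at the default 99% level); two results
differ significantly only when their intervals are disjoint (touching
endpoints overlap). The SVM cost is not part of the emulated analysis
description; C = 1 (the LIBSVM default) is used and exposed in the
configuration. On one-dimensional z-scored features this choice mildly
underfits (cross-validated accuracy a few points below a threshold
rule); it is kept for fidelity, not performance.

## Verification protocol

70% of subjects (stratified by group, largest-remainder rounding;
168/72 at full scale) form a training set on which the filter and SFFS
are re-run; an SVM fit on the training subjects is scored once on the
validation subjects for each cumulative feature count. The permutation
test reassigns group labels over all subjects (preserving group sizes),
refits on the training side and rescores on the validation side, 1000
times by default; reported is the percentage of permutations the
real-label accuracy strictly exceeds (ties count as not-better).
Permutations reuse the already-selected features; a stricter
re-selection mode is not the default. Ablation removes the selected
columns and re-runs the entire filter + SFFS + validation protocol on
the remainder.

Because a planted component is spatially and temporally extended —
neighboring time samples are correlated, and the CSD image of a smooth
topography has spline sidelobes of 20–30% relative amplitude on nearby
electrodes — ablating a single column cannot restore the null. The
packaged ablation study therefore removes every column on channels
where the planted component's CSD image exceeds 10% of its maximum.

## Synthetic cohorts

Each subject has a latent performance score z ~ N(0,1) that drives both
behavior and EEG:

* **Behavior**: FA = logistic(logit(0.12) − a·z + noise),
  RT = 348 − b·z + noise, with slopes fixed at 0.9 of the configured
  between-subject SDs (fa_rate_sd 0.05, rt_sd 30 ms) and idiosyncratic
  noise filling the remainder; trial outcomes are then simulated
  per-trial (Bernoulli false alarms and misses, per-trial RT jitter of
  50 ms), so empirical rates carry binomial noise that shrinks with
  trial count, as in real data. At full trial counts the ratio
  correlates ≈ 0.9 with z; the median split then mislabels ~10–15% of
  subjects, which attenuates any planted group effect by roughly that
  correlation.
* **EEG**: band-limited (0.5–18 Hz) 1/f-power Gaussian noise
  (8 µV RMS) plus band-limited white noise (3 µV RMS), synthesized
  spectrally; plus a component repertoire. Components are either
  phase-locked Gaussian transients (σ = duration/4) or Hann-windowed
  sinusoid bursts with a random phase per trial (induced activity,
  visible only in total power). Every component loads on all channels
  through a spherical Gaussian topography (default σ 0.45 rad; 0.35 for
  the focal group-modulated plants) — a single-electrode delta would
  alias into high spatial frequencies on a sparse montage and its CSD
  sidelobes would outweigh the source.
* **Amplitude model**: amplitude_i = A·(1 + γ·z_i + cv·g_i + 0.1·e_i),
  with a shared per-subject gain g_i (anatomy/conductivity; cv = 0.4)
  common to all components and small component-specific jitter. γ is
  calibrated in closed form (half-normal moments) so that the Cohen's d
  of a modulated component's amplitude between ideal median-split
  halves of z equals the configured `effect_size`; the default 1.0
  corresponds to the ~68% single-feature accuracies such studies
  report.
* **Default repertoire**: visual P1/N1 at PO9/PO10, Nogo-N2 at Cz,
  Nogo-P3 at FC1, Go-P3 at P1 (group-neutral), plus three
  group-modulated plants on Nogo trials: a 10 µV/80 ms transient at
  C3/322 ms, a 20 µV/500 ms 4 Hz theta burst at C3/324 ms (its
  total-power time course raises the 4 Hz bin roughly eightfold over the
  late-epoch baseline — deliberately stronger than the two-to-threefold
  condition effects typical of fronto-central theta, so that the 4 Hz
  bin unambiguously dominates the plant's own footprint), and an
  8 µV/250 ms 9 Hz alpha burst at
  T7/207 ms. Burst amplitude and duration were chosen so the 4 Hz bin
  dominates the plant's own time-frequency footprint, i.e. so the
  generator is self-consistent with its declared ground truth.
* Optional gross artifacts (large steps, flat channels) can be injected
  at a configurable rate for exercising the rejection stage; trial
  retention dispersion is exposed as a dropout-rate knob.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning (one child per subject, split into
behavioral and EEG streams), so cohorts are bit-reproducible and the
behavioral table is identical whether or not EEG is synthesized — which
permits the `synthesize_conditions=("nogo",)` option used by the
recovery studies to skip Go-trial EEG the feature banks never read.

**What the generator does not emulate**: spatially correlated background
noise, realistic head-model forward projection, ocular/muscle artifacts,
non-stationary noise, latency jitter of components across trials or
subjects, and continuous (non-epoched) recordings. Passing tests
demonstrate internal consistency of the pipeline and recoverability of
planted effects under this idealized noise model, not performance on
real recordings.

## Recovery studies and their limits

The packaged recovery study (`nogodecode.recovery`) runs the full
pipeline on 20 seeded cohorts (240 subjects, effect size 1.2, one ERP
and one theta plant at C3) at a reduced demonstration scale — 16
channels, 64 Hz, 120 trials per subject — chosen so a 20-seed study
completes in minutes on one CPU; the methods are identical at full
scale. Two recovery readings are reported:

* **strict**: first selected feature on the plant's channel within
  ±20 ms (TF additionally within ±1 Hz);
* **within method resolution**: plant channel, with offsets within the
  wavelet's own resolution (|Δt| ≤ 2σt ≈ 437 ms and |Δf| ≤ 2√2·σf ≈
  2.1 Hz at 4 Hz; ±50 ms for the 80 ms ERP transient).

The strict reading is not reliably attainable, for reasons that are
properties of the method rather than of the implementation:

1. At 4 Hz with f0/σf = 5.5 the wavelet's time resolution is
   2σt = 437 ms and its effective spectral sigma is √2·σf ≈ 1 Hz, so a
   time-frequency argmax cannot localize to ±20 ms/±1 Hz.
2. Between-subject variance of amplitude/power features is dominated by
   the shared amplitude factor (latent score + gain), so the group
   t-statistic saturates at a label-noise ceiling across every bin and
   channel that carries any leakage of the planted signal (wavelet
   smearing, burst sidebands, CSD spline sidelobes). Within that
   plateau the argmax location is decided by noise.
3. The SFFS first feature is the argmax of cross-validated accuracy
   with 1/24 granularity and ~0.02–0.03 evaluation noise over tens to
   hundreds of filter-passed candidates, so even when the planted
   column is the global t-statistic maximum it wins the accuracy argmax
   in only ~60–70% of runs. Studies of this design exhibit exactly this
   instability internally — a full-set analysis and a train/validation
   re-analysis of the same data can select the top feature at
   neighboring electrodes tens of milliseconds apart.

The within-resolution rates, the per-run offsets, the null-cohort and
ablation calibrations, and all oracle comparisons are recomputed from
scratch by `scripts/acceptance.py`.

## Numerical and engineering choices

* Epoch arrays are float32 (µV precision); all reductions (averages,
  t-tests, CSD, wavelet oracle paths) run in float64. The wavelet gemm
  follows the input dtype: float64 in oracle comparisons, float32 in
  the streaming pipeline.
* Subjects are processed one at a time in the pipeline driver, so
  cohort-scale memory stays bounded at any configuration.
* Zero-variance feature columns are dropped with a logged warning
  before z-scoring; empty filter results fall back to the single
  smallest-p column so downstream reporting stays defined.
* Degenerate inputs raise informative errors rather than propagating
  NaNs: all-identical ratios (no median split), subjects without
  retained trials, epoch windows that do not bracket the stimulus,
  oscillations above Nyquist, folds with a single class.
* `go_fraction = 1.0` is permitted in the generator (no Nogo trials);
  every downstream Nogo analysis then raises a clear error, as the
  degenerate case demands.
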