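# Methods

## Scope and design

The package reproduces, at desk scale, a stress-assessment feature pipeline
whose inputs are continuous ECG (400 Hz), blood volume pulse (201 Hz) and
skin conductance (201 Hz) recorded over a three-emotion elicitation
session. Because no public recordings exist for this protocol, a synthetic
cohort generator is a first-class component: its planted parameters map
one-to-one onto extracted features, which turns every pipeline stage into a
testable estimator. All randomness flows through `numpy` Generators seeded
explicitly; identical configurations produce identical cohorts.

## Synthetic cohort model

**Session timeline.** Six contiguous segments: relax (180 s), neutral
(240 s), relax, negative, relax, positive. Segment labels switch the
active `StateEffect` at boundaries.

**RR intervals.** RR_n = μ + a_LF·sin(2π·0.1·t_n) + a_HF·sin(2π·0.25·t_n)
+ ε_n, ε_n ~ N(0, σ²), floored at 0.3 s, with t_n the running beat time —
an IPFM-flavoured tachogram whose mean, SD and band structure are directly
recoverable as MEANRR/HR, SDNN and LF/HF features.

**ECG.** One template QRS complex (dominant Gaussian R spike, small Q/S
dips, ±60 ms support) per beat plus optional white measurement noise.
P/T waves, ectopy and motion artifacts are out of scope.

**BVP.** One pulse per beat occupying the beat interval: cosine rise to
the peak 30 % into the interval, cosine decay back to the onset level.
The per-beat peak-minus-onset amplitude is drawn from N(amp_mean, amp_sd),
so pulse-wave amplitude features have exact planted truth.

**Skin conductance.** Tonic level + linear drift per segment (level steps
smoothed with a 15-s moving average at the joins), plus a homogeneous
Poisson train of sudomotor responses (Bateman impulse response,
τ₁ = 0.75 s, τ₂ = 2.0 s, unit peak) with exponentially distributed
amplitudes, plus white noise.

**Default state effects.** Neutral/relax: mean RR 0.787 s; negative:
0.740 s with reduced HF modulation, pulse amplitude 0.62 vs 0.72, SCR rate
8/min vs 4/min and a higher, faster-drifting tonic level; positive sits
between. Mean RR, RR spread, pulse-amplitude statistics and SCR amplitudes
follow the per-state values printed in the study's selection table; SCR
rates and tonic levels are not printed there, so conventional resting
electrodermal values were chosen. The RR variability budget is split
deliberately: HF modulation (a_HF = 0.04–0.05 s) dominates white noise
(σ ≈ 0.01 s), matching the strong short-lag autocorrelation of real HRV.
This matters for multiscale entropy on 60-s windows (~75 beats): with
white-noise-dominated RR, template matches at coarse scales become so rare
that the entropy is undefined in a large fraction of windows, which no
parameter recovery can fix; with modulation-dominated RR the entropy
profile falls with scale, as reported for real data.

**What the generator does not emulate** — and hence what passing tests do
not show: realistic ECG/PPG morphology and its detector failure modes,
movement and electrode artifacts, non-stationary baseline wander,
respiratory sinus arrhythmia coupling, inter-subject variability beyond
the per-state parameter sets, and any genuine psychophysiology. Tests
against this cohort validate the *estimators*, not claims about human
subjects.

## Preprocessing

* ECG/BVP: 4th-order Butterworth band-pass 1–40 Hz and powerline notch
  (Q = 30, 50 Hz), both applied forward–backward so event times are not
  shifted. Filter order and Q are common defaults; the detectors do not
  depend on them sharply.
* R peaks: derivative → squared energy → 150-ms moving-window integration
  → peak picking with 0.25-s refractory period and a two-pool adaptive
  threshold (candidates split around their mean height; threshold one
  quarter of the way from the noise-pool mean to the signal-pool mean),
  then refinement to the local extremum of |x − median(x)|, which makes
  detection invariant to polarity and positive scaling.
* Pulses: prominence-gated maxima; onset = signal minimum between
  consecutive peaks; amplitude = peak − onset; width = inter-onset
  interval.
* GSR: polyphase anti-aliased resampling to 4 Hz (`resample_poly`,
  line-padded so constants survive the edges), then convex decomposition:

  minimise ½‖y − Kq − Bl‖²/n + α·mean(q) + γ·mean((Δ²l)²) over q ≥ 0,

  with K the Bateman convolution, B a piecewise-linear tonic basis with
  10-s knots, α = 4·10⁻³, γ = 10⁻². Because q ≥ 0 makes the L1 term
  linear, the problem is a smooth bound-constrained quadratic solved
  exactly by deterministic L-BFGS-B — no external QP solver. SCR events
  are read off the recovered driver: consecutive above-floor driver mass
  is clustered (gap one sample), the cluster mass is the event amplitude
  (the kernel has unit peak), and events below 0.01 µS are dropped.
  Rise time is onset-to-peak of the kernel response. A median-smoothing
  split is the fallback if the solver fails. Recovered event counts on
  planted Poisson trains are within ~5 % of truth on average; residual
  misses are genuinely sub-threshold amplitudes (the exponential
  amplitude law puts ~2 % of events below 0.01 µS) and near-coincident
  events inside one kernel width.
* Windows: half-open [start + k, start + k + 60) s, fully inside their
  segment, never straddling boundaries (so window labels are unambiguous);
  a 240-s block yields 181 windows, matching the published count.

## Features

All SDs are sample SDs (n−1). NN50 counts successive differences strictly
greater than 50 ms; pNN50 divides by n−1. Spectral HRV uses the tachogram
cubic-interpolated to 4 Hz, linearly detrended, Welch with 32-s Hann
segments and 50 % overlap; VLF (<0.04 Hz) is reported for completeness
although a 60-s window cannot resolve it reliably. Sample entropy uses
Chebyshev distance, m = 2, r = 0.2 × sample SD, self-matches excluded,
both template counts over the same n−m starts; a constant series scores 0
by convention and A = 0 yields a missing value. Multiscale entropy
coarse-grains by non-overlapping block means at scales 1–5 with r fixed
from the scale-1 series.

Ambiguities resolved as package conventions: H_W is the mean per-pulse
amplitude/width ratio (its reported magnitude ≈ 10 is inconsistent with a
plain amplitude; an `amplitude-only` reading would duplicate MEANPA);
HIGH is the mean raw signal value at pulse peaks (upper-envelope mean),
distinct from MEANPA; the second BVP "mean interval" row of the published
table (≈ 79, a rate) is exposed as PR, the pulse rate; AUCR/AUCP are the
same feature (canonical name AUCR). Tonic and phasic window statistics are
computed on per-subject z-normalised series — the published tonic means
are negative, which raw conductance cannot be — with a raw mode available;
SCR amplitudes and rise times stay in raw units. Missing window values are
imputed by the per-subject-segment median; a column more than 20 % missing
aborts extraction.

## Selection

**Transitions.** With relax aliased to neutral, a transition (A→B) is any
adjacency of mapped labels; under the default protocol the three
transitions (neutral→negative, negative→neutral, neutral→positive) are all
immediately adjacent segment pairs, with the relax blocks serving as the
neutral flank. "Before" and "after" are per-subject means over the full
flanking segments (window-level pairing would make the 60-s overlapping
windows grossly non-independent). The normality gate (Shapiro–Wilk,
α = 0.05) is applied to the paired *differences*, which is what the
t-test assumes; Wilcoxon discards zero differences, uses the exact null
below 25 non-zero pairs and a continuity-corrected normal approximation
above. Zero-variance differences are scored p = 1. The discrete method
runs a two-group Kruskal–Wallis per pairwise state comparison on the same
segment means (the test is unpaired by construction, whatever the
protocol's pairing). No multiple-testing correction across features is
applied, matching the benchmarked procedure; the conjunction over three
comparisons already makes per-feature type-I error ≈ α³.

**Redundancy.** Greedy keep-first walk in the fixed registry order
(the published procedure does not state an order; order dependence is a
documented property, not a bug), |Pearson r| computed on pooled
window-level values across all segments, strict > 0.9 for both methods.
Constant features (undefined correlation) are kept and flagged.

**PCA.** Per-signal z-scored blocks, full SVD, fixed component counts
{ECG 6, BVP 5, GSR 6} as inputs — the published dimensions come without a
selection criterion, so they are configuration, not estimation.

## Classification harness

KNN (k = 5, Euclidean), decision tree (Gini, unlimited depth), random
forest (100 trees), SVM (RBF, C = 1, γ = 1/d); hyperparameters are
unreported in the benchmarked study, so common defaults are fixed and
exposed. Standardisation is fit on training folds only. Stratified
10-fold CV in two units: pooled windows (the shape implied by
features × windows × subjects matrices, but leaky — adjacent 60-s windows
at 1-s steps share 59 s of signal, so a subject's near-duplicates appear
on both sides of a fold) and subject-grouped folds (recommended; every
report carries an explicit leakage flag). Metrics are macro-averaged per
fold and then averaged across folds; classes are balanced by design so
macro and weighted averaging coincide in expectation. The binary stress
task maps negative → stress, neutral/positive → non-stress.

The published headline accuracies were obtained on the study's unreleased
85-subject recordings; they are not reproducible from simulation and the
harness makes no attempt to match them.

## Problem sizes

The test suite and acceptance script run cohorts of 1–8 subjects (full or
halved protocol), which exercise every code path end to end; statistical
properties of the selection stage (type-I ≤ α at n = 85 over 500
replicates, power > 0.99 at a 1-SD paired shift over 200 replicates) are
simulated at the per-subject segment-mean level where the signal chain
contributes nothing but cost. Entropy implementations are checked against
an exhaustive O(n²) oracle on series up to 300 points.

## Known limitations

* The EDA driver-clustering event detector merges SCRs closer than one
  4-Hz sample and cannot see amplitudes below the 0.01 µS floor.
* VLF power on 60-s windows is dominated by the detrending and window
  choices; treat it as a bookkeeping feature.
* With few subjects (< ~10) the Shapiro gate is weak and the Wilcoxon
  branch is rarely taken; transition selection is designed for
  cohort-scale n.
* The greedy redundancy filter's output depends on the registry order by
  construction; reordering candidates changes which of a correlated pair
  survives.
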