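# Methods

This note records the model, the numerical choices and their rationale, and
what the synthetic corpus can and cannot show.

## Problem and unit of analysis

Overnight audio over a sleeping subject alternates between snore events,
audible breathing, and near-silence.  The classification unit is the
**segment part**: a 3200-sample (200 ms at 16 kHz) window cut from a
labelled segment after the segment is min-max normalized to [−0.5, 0.5].
Normalization is per *segment*, not per part or per recording: subjects
differ in absolute loudness (microphone distance, voice), while the
amplitude structure across parts within one segment is informative and is
preserved.  A trailing remainder shorter than one part is discarded rather
than padded — padding would inject silence-like samples into snore parts
and bias the entropy downward.  Windows do not overlap.

## Features

**Shannon entropy.** H = Σ pᵢ log₂(1/pᵢ) over an equal-width histogram of
the part's amplitudes.  The bin grid is fixed to the normalized range
[−0.5, 0.5] with **32 bins** (config knob): a 5-bit ceiling comfortably
above the ~4.5 bits that loud structured parts reach, while keeping
≈100 expected samples per occupied bin.  Empty bins contribute nothing; a
constant part has zero entropy.

**Largest Lyapunov exponent.** Each part is delay-embedded with the global
choice **m = 5, τ = 8**.  Per-part selection of (m, τ) via false nearest
neighbours and the first minimum of average mutual information is
implemented as a diagnostic (`embedding` module) but not run per part: the
selected values vary little across classes, and a common embedding keeps
features comparable.  λ₁ is estimated by the nearest-neighbour
divergence-curve method:

1. pair every trajectory point with its nearest neighbour at temporal
   separation greater than a **Theiler window** (default: the signal's
   mean period, the reciprocal of its mean power-spectral frequency), so
   pairs are not trivially correlated;
2. track y(i) = ⟨ln dⱼ(i)⟩ over forward steps i, dropping pairs that leave
   the trajectory or coincide exactly;
3. fit a least-squares line over steps **i ∈ [1, 6]**; the slope is λ₁ in
   nats per sample (the sampling step is the time unit — no absolute-time
   rescaling is applied, so values are comparable across parts but not
   directly to implementations that report nats/second).

Two numerical details matter.  The fit starts at step 1 because the step-0
point is selection-biased: the neighbour was chosen to minimise exactly
that distance, so y(0) sits below the curve's continuation, and for
signals at or below the noise floor (a pure sinusoid sampled at an integer
period, for instance) the spurious jump would masquerade as divergence.
The fit ends at step 6 because at τ = 8 the broadband audio classes
decorrelate within a few samples: the informative early-growth region of
the curve is short, and a longer window (the curve is computed to
`max_step` = 30) only averages in the saturated plateau and compresses all
classes toward zero.  Both bounds are config knobs; estimator validity is
established independently of the audio pipeline on the logistic map
(slope within 5% of the analytic derivative-sum exponent ln 2 at r = 4)
and on periodic signals (|λ₁| < 0.02).

Neighbour search is an exact k-d tree query with adaptively grown k to
satisfy the Theiler exclusion; this is exact nearest-neighbour search, not
an approximation, and is what keeps full-scale feature extraction at
roughly 20 ms per part.

## Synthetic corpus

The generator emulates the *feature-space structure* of clinical SRS data,
not its waveforms.  Class recipes (all parameters in `SynthesisConfig`):

* **snore** — 10-harmonic stack on a 100–150 Hz fundamental; the
  fundamental period is modulated at 2% depth by a logistic map at
  r = 3.99 (mild chaotic aperiodicity that does not destroy the harmonic
  structure); a 2–5 Hz raised-sine envelope (floor 0.08, exponent 1.5) and
  a band-limited (≤800 Hz) breathy floor at 5% relative amplitude.
* **breathing** — Gaussian noise band-passed to 300–800 Hz under a slowly
  varying turbulent gust envelope (low-passed noise gain raised to the 4th
  power, floor 0.05, for strongly peaked gusts).
* **silence** — a band-limited (≤1 kHz) low-amplitude noise floor plus
  rare large clicks (~8 s⁻¹, hundreds of floor standard deviations, as
  produced by a recording chain); after min-max normalization the floor
  collapses into one or two histogram bins.  A config flag
  (`silence_second_cluster`) produces the secondary, higher-entropy
  silence regime (milder clicks) that clinical data also shows.
* **subject effects** — each subject draws its own fundamental range,
  breathiness, jitter depth, breathing band, envelope floors, ambient
  cutoff and click rate from a substream keyed by (dataset seed, subject).
  This is what makes the subject-disjoint Experiment II genuinely harder
  than the shared-subject Experiment I; with identically distributed
  subjects the two protocols would differ only by sampling noise.

Durations are uniform on [0.5, 2.0] s (clinical segments vary; no duration
table is published).  All draws descend from one dataset seed through
per-segment substreams keyed by (seed, subject, class, index), so datasets
are bit-reproducible and independent of generation order.

Calibration targets were the documented class clusters: snore entropy
mostly within [2.0, 4.5] bits at low λ₁, breathing entropy below ~3.3 at
intermediate λ₁, silence entropy mostly below 0.3 at the highest λ₁.  The
generator reproduces this geometry and ordering; the absolute λ₁ scale of
the noise-dominated classes (silence ≈ 0.10–0.12 nats/sample here) sits
below the 0.15–0.25 band reported for clinical silence, because the
magnitude of a divergence-curve slope for noise-like signals depends
strongly on the fit window and time units, neither of which is recoverable
from the published description.  The ordering, not the absolute scale, is
what the classifiers consume.

What passing tests on this corpus do **not** show: robustness to real
room acoustics, microphone responses, overlapping events, mislabelled
boundaries, or snorer populations whose clusters overlap more than the
calibrated ones.  Absolute accuracies on the synthetic corpus are not
claims about clinical accuracy.

## Classifiers

**One-against-all SVM.**  One binary soft-margin machine per class
(+1 vs rest), Gaussian kernel with width 1.0 on standardized features,
C = 10⁷, and a 10⁻⁷ ridge added to the training kernel diagonal for
conditioning.  Standardization is essential at this C: the raw feature
scales (λ₁ ~ 0.1, H ~ 0–5) would make a unit kernel width meaningless.
Prediction is the argmax of the per-class decision values, ties toward the
lower class index (snore < breathing < silence); one-vs-all has no reject
option, so an input far from every class still gets the least-negative
class.  The binary sub-problems are solved by scikit-learn's SVC on the
precomputed (ridged) kernel matrix; the joint multiclass objective that
the formal presentation writes down is implemented through this equivalent
per-class decomposition.  The solver stopping tolerance defaults to 0.1
rather than libsvm's 1e-3: the epsilon is an absolute bound on the dual
KKT violation, and at C = 10⁷ the gradient scale makes 1e-3 needlessly
strict — on overlapping data it costs minutes of extra iterations with no
measurable accuracy change (config knob `SvmConfig.tol`).

**ANFIS.**  First-order Sugeno system on the two inputs with g = 3
generalized-bell memberships per input (9 rules — the smallest grid that
can carve three clusters per axis; config knob).  Initialization is a grid
partition: centres equally spaced over each input's training range, width
a = half the centre spacing, b = 2.  Hybrid learning per epoch: consequent
parameters solved exactly by linear least squares with premises frozen
(minimum-norm solution with a warning if the system is rank-deficient),
then premises updated by a normalized, parameter-scaled gradient step
(default length 0.01) that is halved up to 8 times and skipped entirely if
it would increase the training RMSE — so the recorded error is
non-increasing by construction.  A learning rate of 0 is accepted and
reduces training to the pure least-squares solve.  The class decision uses
a single crisp output regressed on codes 1/2/3 and decoded to the nearest
code, clamped, half-way points rounding down; this matches the
single-output network architecture, and the three classes are ordered
along the entropy axis so the code ordering is not arbitrary.

## Experiments and metrics

Experiment I splits each (subject, class) group so the first ⌈n/2⌉
segments train (matching the published per-cell train ≥ test counts);
Experiment II partitions subjects per the shipped design table, and a
shared subject on both sides is an error.  Zero-count design cells are
legal (one subject has no snore segments).

Per class: sensitivity 100·TP/(TP+FN) and PPV 100·TP/(TP+FP).  The single
headline **total accuracy** is 100·trace/total — the overall fraction of
correctly classified parts.  The per-class TN-based accuracy
100·(TP+TN)/total is also reported but is *not* the tables' bold number:
trace/total is the definition that reproduces every published total (e.g.
4795/5234 = 91.61%).  Classes with an empty row or column get NaN metrics
and are flagged, never a division error.  ROC curves are one-vs-rest
threshold sweeps with trapezoidal areas.

## Problem sizes used

Validation runs the full Experiment II at the published design scale
(553 + 787 segments, ≈7600 parts, ≈4 minutes end to end), and the
Experiment I vs II ordering comparison on 10%-scaled designs across five
seeds.  The logistic-map oracle uses 10⁴ samples for the estimate and 10⁵
for the derivative sum.

## Known limitations

* λ₁ values are fit-window- and unit-dependent (see above); only within-
  pipeline comparisons are meaningful.
* The entropy estimator is histogram-based; parts with all mass on a bin
  edge can split between two bins, which is why a minority of silence
  parts report up to ~1 bit.
* The SVM at C = 10⁷ is slow to converge on heavily overlapping data;
  even at the default stopping tolerance, training the full-scale corpus
  takes on the order of a minute.
* FNN uses no Theiler correction inside its neighbour search, and no
  alternative delay criteria are provided.
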