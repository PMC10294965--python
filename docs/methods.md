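# Methods

## The measurement model

The package operationalizes movement abnormality as distance from the
distribution of healthy movement, read out through classifier confidence.
Five functional primitives compose the tabletop task: reach (arm moves
into contact with the object), transport (arm conveys the object),
reposition (arm returns without the object), stabilization (minimal motion
holding the object), idle (minimal motion at the ready). Reach, transport
and reposition are *motion-based*; only their prediction probabilities
enter the abnormality read-out, because the quiet classes carry little
information about movement quality.

A classifier trained only on healthy subjects assigns each predicted
primitive a winner-take-all softmax probability over the five classes
(hence every confidence value is ≥ 1/5). If test movement is
in-distribution, confidence is high; impairment shifts the joint
distribution of the 76 input channels and confidence falls. The package
treats that fall — pooled per subject over windows and model versions —
as a continuous, ratio-scaled abnormality measure, validated against the
generator's ground-truth impairment parameter.

## Data model and units

A recording is a frames × 76 matrix at 100 Hz with gap-free half-open
labeled segments. Channel layout: 27 accelerations (9 sensors ×
x/y/z, m/s²), 27 orientation components (3 generic smooth components per
sensor — the 27-count bookkeeping admits only 3 of a unit quaternion's 4
components, so the schema stores three generic orientation signals), and
22 anatomical angles in degrees (per side: shoulder flexion/extension,
internal/external rotation, adduction/abduction, total flexion; elbow
flexion/extension; wrist flexion/extension, pronation/supination,
radial/ulnar deviation; plus thorax and lumbar flexion/extension, axial
rotation, lateral flexion). Relative to a moving side, channels are
tagged `moving_ue` (26), `contralateral_ue` (26), or `trunk` (24 = 3 back
sensors × 6 channels + 6 trunk angles). Units are metadata only; models
standardize per channel with statistics fit on their own training split.

Impairment categories follow the clinical convention: 0–25 severe, 26–52
moderate, 53–65 mild; 66 (normal) maps to "none" since the bands describe
impaired subjects.

## The synthetic cohort

The generator emulates the semi-structured tabletop task: per trial, an
initial idle, then for each of 8 outer targets a reach → transport →
(25 % chance of a stabilization) → reposition cycle separated by idles.
Motion primitives last 0.5–1.0 s before slowing and carry minimum-jerk
acceleration profiles on the moving arm's sensors (hand peak 3 m/s²,
forearm 0.7×, arm 0.45×), with class-distinct signatures: reaches pair an
outward profile with elbow extension (−30°) and shoulder flexion bumps;
transports show the largest hand-orientation excursion and shoulder total
flexion; repositions mirror the acceleration sign and reverse the angle
bumps. Idle is strictly quieter than stabilization. All subjects carry
physiological baseline variability — slow sway (0.05–0.4 Hz sinusoids) on
joint angles (trunk amplitude 0.1–0.45°, limbs 0.2–1.0°), accelerations
(0.005–0.04 m/s², below the 0.05 m/s² sensor noise so idle means stay in
the noise floor) and orientation components — so "quiet" channels are
realistically non-constant rather than pure sensor noise. Without this,
standardization would amplify any impaired-side trunk activity by orders
of magnitude, an artifact of constant training channels rather than a
property of the method.

Impairment is a single parameter θ ∈ [0, 1] applied to the paretic side:
amplitude attenuation 0.7·θ, duration dilation 1 + θ, band-limited 4–8 Hz
kinetic tremor at 0.5·θ of the healthy peak, and trunk compensation with
gain θ (2.5° flexion excursions and 0.15 m/s² back-sensor acceleration at
θ = 1 — clearly present yet below moving-arm prominence, mirroring the
clinical picture where compensation accompanies rather than replaces the
primary deficit). θ = 0 reproduces the healthy generator bit-for-bit. The
FMA-like score is round(65·(1−θ)); impaired subjects cap at 65.
Subject idiosyncrasy (log-normal channel gains, sd 0.15; a tempo factor
clipped so motion durations stay within [0.5, 1.0]·slowing seconds) makes
the leave-one-subject-out design meaningful. All randomness flows through
one seeded generator; per-subject seeds derive from (config seed, subject
id), so identical inputs give bit-identical cohorts.

What the generator does *not* emulate: biomechanically consistent joint
kinematics, gravity and posture, magnetometer effects, flexor/extensor
synergy patterns distinct from attenuation, visual-target errors, or
session effects. Passing tests therefore demonstrate that the pipeline
recovers a monotone impairment signal under its stated generative
assumptions — not clinical validity on real sensor data.

## Windowing

Models consume 6-s windows (600 frames) and predict only the middle 4 s
(frames [100, 500)); the flanks give temporal context. The stride is
400 frames so middle segments tile a recording and no probability is
pooled twice. Per-frame model outputs are collapsed to token sequences by
run-length encoding; runs shorter than 10 frames (0.1 s) in *model*
output are absorbed into the preceding run, since true primitives last at
least 0.5 s. Ground-truth tracks are never filtered.

## Models and training

Both models standardize inputs per channel (training-split statistics
only) and average-pool the time axis by 10 (600 → 60 steps) inside the
differentiable graph. Pooling tames the sequence length for CPU-scale
back-propagation-through-time while preserving the 1-per-0.1-s structure
that distinguishes primitives; gradients with respect to the standardized
600 × 76 window remain exact.

**Seq2seq.** Three bidirectional GRU encoder layers (hidden 64 per
direction) feed a bridge into a single-layer GRU decoder that unrolls
over learned positional inputs and emits, per step, a 5-class softmax and
a separate sigmoid stop signal. Two deliberate choices: (1) positional
rather than previous-token decoder inputs force all class evidence
through the encoder state — with token feedback, the task's regular
grammar lets a decoder stay confident on out-of-distribution input, which
defeats the measurement; (2) a separate stop head rather than a 6-way
softmax keeps each emitted token's confidence the maximum of a true
5-class softmax. Training is token-level cross-entropy (teacher-forced
lengths) plus stop-head binary cross-entropy; decoding is greedy with at
most 12 tokens.

**ASRF.** A 76 → 64 linear projection followed by four residual dilated
temporal convolutions (kernel 3, dilations 1/2/4/8) with two heads:
framewise class logits and a boundary logit. Boundaries are detected at
probability > 0.5 with non-maximum suppression over a 0.25-s radius;
between boundaries, frames are relabeled by majority vote of the
framewise argmax (ties broken by higher mean softmax probability, then
fixed class order); collapsed runs become tokens whose confidence is the
mean winning framewise probability over the run. The boundary loss is a
positively-reweighted binary cross-entropy on label-change frames.

Both train with Adam (lr 5 × 10⁻³, batch 32), inverse-frequency class
weights (the task is idle-heavy), label smoothing 0.1 — without it the
networks saturate (healthy confidence ≈ 0.99) and the OOD read-out loses
dynamic range — and a nominal decoupled weight decay of 10⁻³. Defaults:
28 epochs for seq2seq, 18 for ASRF; the deeper recurrent model needs the
extra epochs to stabilize its confidence geometry. Training is
deterministic given (seed, data order); the neural layers run on an
in-package vectorized reverse-mode autodiff engine whose adjoints
(including the fused GRU BPTT and dilated convolutions) are verified
against central finite differences in the test suite.

## Protocol

Leave-one-subject-out over the healthy cohort: for each healthy subject,
the remainder is split subject-wise into training and validation with
max(1, round(remaining/7)) validation subjects — at 29 healthy subjects
this reproduces a 24/4 split — the model trains on the training subjects
and is tested only on its held-out subject. Impaired subjects, never seen
in training, are scored by a seeded sample of K versions (default 3 at
demo scale) and their predictions pooled. Splits are re-sampled per
iteration; version seeds derive from (global seed, held-out id). The run
asserts that train, validation and test subject sets are disjoint in
every iteration.

## Evaluation and confidence analysis

Edit metrics: the minimal-cost unit alignment between predicted and
ground-truth token sequences, counting deletions (spurious predictions),
insertions (missed tokens) and substitutions. Among minimal alignments
the one maximizing aligned pairs is chosen (backtrace preference:
substitution, then deletion, then insertion), which makes counts
deterministic and exactly symmetric under sequence swap. Per subject,
counts are pooled over all windows before computing FDR, TPR and F1
(micro-averaging); per-trial averaging of ratios is deliberately avoided
because ratios of small counts are unstable.

Confidence: per subject, winning probabilities of *predicted*
motion-based tokens across versions form the probability cluster
(predicted-class filtering, since ground truth is unavailable at
deployment; empty clusters are excluded with a logged count). Summaries:
sample mean/SD; Cauchy location/scale by damped-Newton maximum likelihood
(initialized at median and half-IQR, tolerance 10⁻⁸, at most 200
iterations, falling back to the initializer with a warning — the Cauchy's
heavy tails make its location a robust median analogue, and the reported
"IQR" is 2 × scale, exact for a Cauchy); PC1 of the z-scored
(location, spread) pairs across subjects with the sign fixed so the
location loading is ≤ 0 (higher PC1 = lower confidence); and the
1-Wasserstein distance between a subject's cluster and the pooled healthy
test clusters. Group inference is a subject-level permutation test on
per-subject mean confidence (999 permutations, two-sided
p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1)); collapsing to one value per
subject respects within-subject correlation without a mixed-model
dependency. Pairwise category contrasts, when reported, are
Bonferroni-corrected across the three comparisons. Spearman's rank
correlation (ties mid-ranked) relates each summary to the impairment
score over impaired subjects.

## Attribution

For a predicted motion-based token, reverse-mode differentiation gives
|∂(winning softmax probability)/∂input| over the 600 × 76 window, in
standardized units — raw-unit gradients would be dominated by the 1/sd
factors of quiet channels, a units artifact rather than model behavior.
For seq2seq the scalar is the token's probability at its decoder step;
for ASRF, the mean winning framewise probability over the token's span
(gradients pass through the softmax, not the discrete refinement).
Per subject, |gradients| are summed over time, tokens (up to 3 per
window) and a seeded sample of windows (default 2, chosen among windows
containing motion-based predictions), then normalized to sum 1; group
profiles average subject profiles and re-normalize. Summing the profile
over side tags asks whether confidence is driven by the paretic arm or by
compensatory trunk motion.

## Numerical and degenerate-input conventions

Softmax/log-softmax are computed with max-subtraction; BCE from logits
uses the |z| form. F1 is defined as 0 when TPR = 0 and FDR = 1. Constant
clusters yield SD 0 and a collapsed Cauchy scale; constant features are
dropped from PC1 with a warning; Spearman on constant input raises.
Recordings shorter than 600 frames yield no windows (logged). Channel
standard deviations below 10⁻¹² standardize as 1 to avoid division blowup.
Checkpoints carry a schema fingerprint; predictions on a mismatched
schema are refused.

## Scale of the shipped study and stability

The packaged demo study — 8 healthy subjects (≈ 50 windows each), 9
impaired at θ ∈ {0.2, 0.5, 0.8}, K = 3, hidden size 64 — was chosen so
the complete double-architecture LOSO run finishes in minutes on a single
CPU while leaving each property comfortably testable. At this cohort
size the ASRF read-out is strongly separated (healthy ≈ 0.89 vs impaired
≈ 0.62 pooled confidence; per-level means strictly ordered; Spearman ρ
≈ 0.95) and stable across seeds. The seq2seq read-out reproduces the
group effect robustly but its per-level separation is small (≈ 0.02–0.04
confidence units), so level ordering and per-subject correlations can
wobble at other seeds with only three subjects per level — the analogous
contrast was also the weaker one for the sequence model at full clinical
scale. The acceptance suite pins the demo seed; the attribution
localization check targets the segmentation model, whose saliency is the
one analyzed at full scale, since a desk-scale recurrent model retains
too much of its random input mixing for a sharp spatial profile.

## Known limitations

The synthetic impairment conflates attenuation, slowing, tremor and
compensation under one parameter; real deficits dissociate these. The
orientation channels are generic smooth signals, not quaternion
components. Confidence is uncalibrated (no temperature scaling by
design — the raw softmax is the object of study). The permutation test
replaces a mixed model and tests only the group mean. Gradients localize
sensitivity, not causality.
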