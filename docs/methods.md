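# Methods

## Signal model and preprocessing

A bilateral insole stream carries, per foot at a nominal 50 Hz: four FSR
pressure readings (heel, fifth metatarsal, first metatarsal, toe) and the
antero-posterior (AP) and vertical accelerations. FSR units are arbitrary
but consistent within a stream (volts in the simulator).

Smoothing is a single-pole exponential moving average, `y[t] = a x[t] +
(1-a) y[t-1]`, `y[0] = x[0]`, default `a = 0.3`. It is causal and O(1)
per sample, which suits streaming at 50 Hz; being a convex combination it
can never leave the input's range. The coefficient trades lag against
noise rejection; at `a = 0.3` the step-response time constant is about
three samples (60 ms), below the shortest phase duration at normal
cadence.

Calibration estimates each sensor's effective range from two recordings:
foot lifted (no load) and full body weight. Each recording is reduced to
its **first quartile** — of the unloaded readings for the range minimum
and of the loaded readings for the range maximum. A low quantile is
robust to transient spikes; for the loaded stage it is a conservative
choice of maximum (readings mostly exceed it, and normalization clamps at
1). Quantiles use linear interpolation between order statistics (the
common "type 7" convention), exposed as a named constant so the
convention can be swapped. Normalization maps `x -> (x - min)/(max -
min)` clamped to `[0, 1]`; negative raw readings are rejected as corrupt
rather than clamped, since a healthy FSR front end cannot produce them.

## Fuzzy gait-phase detection

Each normalized input is graded by a complementary sigmoid pair,

    f_low(x)  = 1 / (1 + exp(s (x - x0)))
    f_high(x) = 1 - f_low(x)

with inflection `x0 = 0.5` (symmetric domain) and slope `s = 15`
everywhere except the toe channel, where `s = 50`: toe pressure appears
only briefly in pre-swing and its on/off transition is much sharper, so a
steeper sigmoid segments that phase more cleanly. The steeper toe slope
applies to the toe antecedent of *every* rule, not only the pre-swing
rule, so the complement identity holds per channel.

The rule base maps pressure patterns to phases (one rule per phase;
"-" = irrelevant):

| heel | 5th | 1st | toe | phase |
|------|-----|-----|-----|-------|
| high | low | low | low | LR |
| high | high | - | - | MSt |
| low | high | high | - | TSt |
| low | low | - | high | PSw |
| low | low | low | low | Sw |

Rule activation is the **minimum T-norm** over the antecedent grades;
don't-care channels are excluded. Per sample the *active* phase is the
argmax of the five memberships. Ties retain the previously active phase;
the tie test uses a 1e-9 tolerance because a sample landing exactly on a
pattern transition produces several memberships equal up to round-off,
and resolving such a knife-edge by ulps would inject spurious one-frame
events. An optional debounce (minimum event duration, default 0 = off)
exists for very noisy streams and is off in every shipped test. Each
foot runs an independent detector instance.

Cycles are segmented at LR onsets (initial contact opens the cycle in
the standard five-phase model). For each complete cycle (all five phases
present) the measured per-phase duration is compared with the reference
partition — LR 10%, MSt 20%, TSt 20%, PSw 10%, Sw 40% — applied to that
cycle's own total duration; differences are averaged across cycles,
positive meaning over-estimation. Incomplete cycles (typically the
truncated tail of a recording) are dropped with a logged warning.

## Feature extraction

Twelve ring buffers of 128 samples (~2.56 s) cover the eight FSR and
four acceleration channels. Per buffer, three features: time-domain mean
(F1), root-mean-square (F2), and the dominant non-DC frequency of the
128-point FFT magnitude spectrum in Hz (F3; bin width 50/128 ≈ 0.39 Hz,
sentinel 0 when the non-DC spectrum is identically zero). No window
function is applied before the FFT (a Hann option exists behind the same
interface). The trio spans the time and frequency domains; it is
deliberately pluggable, since any fixed trio with that coverage serves
the classifier equally.

Feature 37 is the gait-phase-sequence code: the last four *activated*
phases of the left foot (appended only on phase change), concatenated
chronologically as decimal digits with LR=1, MSt=2, TSt=3, PSw=4, Sw=5;
fewer than four activations leave implicit leading zeros, so the code
lies in [0, 5555]. The digit map follows cycle order and the tracked
foot is configurable; only train/inference consistency matters. This
feature is what distinguishes forward from backward gait, whose
activation orders are reversed.

No vector is emitted during the 127-sample warm-up. Extraction is
causal, and a vectorized batch path (`extract_features_batch`) is tested
sample-for-sample equivalent to the streaming extractor.

## Dimensionality reduction and classification

Features are z-scored with training statistics before PCA: raw scales
differ by orders of magnitude (normalized pressures ~1 vs. sequence
codes ~10^3), and an unscaled scatter matrix would be dominated by the
code feature. The PCA is computed exactly as the pipeline defines it:
mean vector over all samples, scatter matrix `S = sum (x - m)(x - m)^T`
(= n × population covariance), symmetric eigendecomposition with
eigenvalues sorted descending (stable sort, so ties keep axis order; the
largest-magnitude component of each eigenvector is made positive;
eigenvalues above −1e-10 relative are clipped to zero). The top `I = 22`
eigenvectors form the 37 × I transformation `W`. Projection is `y = W^T
(x - m)`; the uncentered variant `y = W^T x` is available via
`center=False` and differs only by a constant shift of every class,
which the Gaussian classifier is invariant to.

The classifier assumes class-conditional feature independence with
Gaussian marginals. Parameters are the per-class MLE mean and 1/n
standard deviation (`ddof=1` switchable), floored at σ = 1e-9 to guard
within-class constant features. Priors are equal, so prediction is the
argmax of summed log-densities; posteriors are recovered by
max-subtracted softmax. Ties resolve to the lowest class index in the
fixed activity order (walking forward, walking backwards, lateral left,
lateral right, turning left, turning right, sitting down, standing up).

## Synthetic data: what it emulates and what it does not

The simulator replaces human trials. Forward walking follows the
reference phase schedule at a default cadence of 100 steps/min (1.2 s
stride); within each cycle the channel envelopes trace the rule-base
patterns, with don't-care channels held low so each phase presents an
unambiguous pattern. Transitions are raised-cosine ramps of 60 ms
(default), reflecting the soft, continuous nature of real pressure
hand-offs — square edges would make the fuzzy transition behaviour
untestable. Feet are offset by half a cycle; accelerations are
cycle-locked sinusoids (AP at stride rate plus a harmonic, vertical at
step rate). Gaussian noise (default SD 0.05 of each sensor's range, and
0.05 g on accelerations) is added, and levels are clipped to [0, 1]
before mapping onto per-sensor voltage ranges, so raw readings stay
inside the simulated sensor's calibrated range and normalization
round-trips exactly.

The seven other patterns each have a distinct documented signature:
backward walking reverses the activation order toe-to-heel, runs 15%
slower, and is forefoot-led (softer heel, fuller toe). The forefoot
asymmetry is not cosmetic: pure time reversal of a waveform preserves
FFT magnitudes and time-domain moments, so a merely reversed stream
would be invisible to the twelve buffer features and distinguishable
only by the sequence code; real backward gait genuinely loads the
forefoot first and more heavily. Lateral stepping loads the whole foot
at once at ~1.2 Hz with the leading side heavier and reduced AP
acceleration; turning is a slow (0.5 Hz) forefoot-weighted sway with the
inner foot loaded and a stronger outer-leg AP swing (left/right variants
are mirrored); sitting down and standing up are repeated 3 s monotone
weight transfers dwelling unloaded and loaded respectively.

Passing tests on this corpus show that the pipeline's machinery —
normalization, inference, features, projection, classification, fold
logic — is correct and that the classifier separates classes whose
signatures differ in the ways the features measure. They do **not**
show field accuracy on real gait: the simulator has no inter-subject
variability, no sensor drift or misplacement, no composite or
transitional activities, and its class-conditional distributions are
close to the classifier's Gaussian assumption by construction.

## Evaluation conventions

Cross-validation is six-fold with contiguous per-class blocks (no
shuffling — fold assignment is deterministic and seed-free); the
standardizer, PCA and GNB are refitted per fold and accuracy is pooled
correct/total. Class sizes not divisible by the fold count are truncated
with a warning. The feature sweep refits the PCA for each retained count
from 5 to 37. Recognition percentages weight each predicted sample by
its interval to the next (last sample gets the median interval) and sum
to 100 over the eight activities. Trial summary rows report the mean and
the **population** (1/n) standard deviation — the convention under which
the shipped reference per-trial tables reproduce their printed summary
rows; rounding (integers for milliseconds, two decimals for percent) is
display-only.

Default problem sizes — 1200 feature vectors per activity (9600 total),
10–12 cycles per detection trial — match the pipeline's design operating
point and run in seconds on one core.

## Known limitations

- Swing subphases (initial/mid/terminal swing) are not segmented;
  pressure sensors carry no information during swing, and the gyroscope
  route to knee angle is out of scope.
- The loaded-stage first-quartile maximum is conservative by design;
  sustained readings above it simply saturate at 1.
- The simulator's activity signatures are stylized; accuracy figures on
  it bound nothing about real recordings (see above).
- The phase-sequence code is a categorical quantity modelled by a
  Gaussian; this is harmless here (codes separate classes by large
  margins after standardization) but is the weakest distributional
  assumption in the model.
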