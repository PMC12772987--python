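# Methods

## Problem and model

The package estimates the apnea-hypopnea index (AHI, respiratory events per
hour of sleep) of a child from a single overnight airflow channel, and
classifies severity at the pediatric cutoffs 1, 5 and 10 e/h. The core model
is a segment-level regressor: a 1D CNN maps each standardized airflow segment
to the number of apneic/hypopneic events it contains. Subject-level AHI is
the segment mean passed through a linear correction fitted on training
subjects.

The correction does two jobs at once. First, a count per `m`-minute segment
must be scaled by `60/m` to become an hourly rate. Second, segments cover the
whole recording (total recording time, TRT) while the AHI denominator is
total sleep time (TST); with a wake fraction `w` the expected slope becomes
`(60/m) / (1 − w̄)`. Fitting a single regression of true AHI on the mean
segment prediction absorbs both factors plus any systematic bias of the
network. The regression is fitted on training subjects only and applied
unchanged to validation and test subjects, so model selection never sees
held-out information. Negative corrected AHIs are clamped to zero; segment
predictions themselves are left unclamped so the regression sees an unbiased
mean.

## Architecture and training

Each of the `Nc` blocks is conv(kernel 5, stride 1, same zero-padding) →
batch-norm → ReLU → max-pool(2) → dropout(r_drop); then flatten and a single
linear unit. Same-padding keeps temporal lengths pooling-determined, which
makes attribution alignment trivial; pool size 2 is the canonical halving
(with `Nc = 7` a 2,400-sample segment reduces to 18 taps). Two presets are
provided: the full-scale configuration (256 filters, 6–8 blocks, max
300 epochs) and a *desk* preset (16 filters, 4 blocks, max 80 epochs) that
trains in minutes on one CPU and is what the tests and the acceptance script
exercise. Weights are He-normal; arithmetic is float32 (float64 available,
used by the gradient-check tests). The implementation is plain numpy:
convolutions are evaluated as K shifted BLAS matrix products in channels-last
layout, and the explicit backward pass is verified against central finite
differences.

Training follows a plateau protocol: Adam at lr₀ = 10⁻³, Huber loss with
δ = 1 (robust to the occasional mislabeled or artifact-dominated segment),
seeded per-epoch shuffling, batch size keyed to segment length (64/128/256
for 20/10/5 min), learning rate halved after 10 epochs without validation
improvement, early stop after 30, and the returned weights are those of the
best validation epoch. All randomness (init, shuffling, dropout) derives
from one seed, so runs are bit-reproducible on fixed threading.

**Restarts.** At desk scale (≈500 training segments, 4 gradient steps per
epoch) optimization is bimodal across seeds: most runs learn the
amplitude-reduction feature, but a minority collapse to near-constant
predictions immediately — the validation minimum sits in the first few
epochs and early stopping fires without recovery. `train_with_restarts`
treats "best validation epoch ≤ 10 and early-stopped" as optimization
failure and retrains with a deterministically derived seed (up to two
restarts), returning the attempt with the lowest validation loss. This is a
standard multi-start remedy for small-sample non-convex fits; at full data
scale the restart path is effectively never taken.

Hyperparameter selection (`select_configuration`) trains one model per
(segment length, Nc, r_drop) combination and keeps the one with the highest
4-class validation kappa, breaking ties toward fewer blocks and shorter
segments (fewer parameters, finer temporal granularity).

## Synthetic airflow generator

Real pediatric PSG datasets are access-controlled, so the simulator defines
the study conditions for all tests:

* **Breathing**: a sinusoid at a per-record rate drawn from 15–30 breaths/min
  with ±10% per-breath period jitter, a slow ±10% amplitude envelope (period
  30–120 s), and additive Gaussian noise (SD 0.05 of baseline amplitude).
* **Events**: apneas multiply the local signal (noise included, as thermistor
  noise scales with flow) by 0.05; hypopneas by U(0.20, 0.55). With the
  envelope extremes this keeps the event-window RMS at ≤10% (apnea) and
  16–67% (hypopnea) of the 30-s flanking baseline, inside the AASM bands.
  1-s cosine tapers sit just outside the annotated window, so annotated
  intervals are fully suppressed and the onset/offset transitions the
  attribution methods should find are sharp. Durations are U(8, 20) s — at
  the slowest simulated breathing rate (15/min) the 8-s lower bound is the
  AASM "two missed breaths" minimum. Event count is
  `round(target_rate × sleep_time / 3600)`, so the stored true AHI equals
  the annotation count exactly and matches the target up to integer
  rounding.
* **Artifacts** (2/h): high-amplitude noise bursts (3–6× baseline, 2–5 s)
  and flatline disconnections (5–15 s). They are annotated but never counted
  as respiratory events, and are never removed from the signal.
* **Wake** (fraction drawn from 0.10–0.20): blocks at the record start and
  end plus one mid-night block, with larger irregular movement-like flow.
  Events occur only in sleep, which creates the TST < TRT bias the
  correction regression exists to absorb.
* **Placement**: events and artifacts keep ≥35 s clearance from each other
  and from wake boundaries so every event's flanking baseline is clean; a
  record too short for the requested events raises an error naming the
  constraint.

What the simulator does *not* emulate: realistic airflow morphology
(inspiratory/expiratory asymmetry, flow limitation), desaturation/arousal
physiology, sleep-stage structure, inter-night variability, or
vendor-specific sensor responses. Passing tests therefore demonstrate that
the pipeline recovers amplitude-reduction events and their rate under
controlled conditions — not clinical performance on real thermistor data.

## Preprocessing

Resampling uses polyphase anti-aliased decimation with the rational factor
approximating 4/fs to within 10⁻⁶ relative; breathing-band tones (<1 Hz)
keep their amplitude within 2%. Segments are consecutive and non-overlapping;
a trailing partial segment is dropped rather than padded (z-scoring a padded
tail would distort its amplitude statistics). Z-scoring guards flatline
segments (SD < 10⁻⁸ → all zeros). Segment labels count events by onset, so
each event contributes to exactly one segment. No filtering or artifact
rejection exists anywhere in the chain; a registry test enforces this.

## Statistics

ICC is the two-way, single-measure, absolute-agreement coefficient
(ICC(A,1)) computed from the ANOVA mean squares of the n×2 table — the
standard variant for method-comparison studies; Cohen's kappa is unweighted.
Both choices are cross-checked in tests against pingouin and scikit-learn.
Bland-Altman limits use the n−1 SD and the sign convention
estimated − actual. Binary diagnostics treat AHI ≥ cutoff as positive;
ratios with zero denominators are reported as flagged non-finite values
(Sp = 1 → LR+ undefined; Sp = 0 → LR− undefined) so cohort reports always
render.

## Attribution

Grad-CAM taps each block's post-ReLU feature maps (standard practice),
weights them by the temporal mean of the output gradient, rectifies, then
min-max normalizes each block map (all-zero maps stay zero), resizes to the
input length by linear interpolation, and averages — in that order. The
scalar regression output is the target; there is no class dimension.

Deep-SHAP propagates DeepLIFT multipliers from the output to the input
against a background of reference segments (default: 50 quiet-breathing
training segments with zero events; a zeros baseline is available).
Convolutions, inference batch-norm and the linear head are affine and
propagate exactly; ReLUs use the rescale rule `(relu(x) − relu(b))/(x − b)`
(gradient fallback when |x − b| < 10⁻⁷). Max-pooling uses a
delta-proportional rule — the window's output delta is distributed over
inputs in proportion to their deltas — rather than the classical
route-to-argmax rule, because the proportional rule preserves
summation-to-delta exactly even when the argmax differs between input and
reference. Completeness (Σφ = f(x) − E_b f(b)) is asserted at emit time with
tolerance 10⁻³·max(1, |Δ|).

Localization is quantified as the mean relevance inside annotated event
windows (±5 s margin) over the mean relevance elsewhere; |values| for SHAP.
A ratio above 1 means the attribution concentrates on events.

## Problem sizes

The acceptance script and end-to-end tests use 80/20/30
train/validation/test subjects with one-hour recordings, AHI targets uniform
on 0–20 e/h, 10-min segments and the desk preset — a size at which the whole
study (simulation, training with the full schedule, evaluation, attribution)
completes in a few minutes on one CPU. The oracle-recovery check uses 100
subjects. The full-scale preset is exercised by a forward-shape smoke test
only.

## Known limitations

* Desk-scale training sees ~500 segments, so generalization is limited by
  memorization; the reported desk-scale agreement statistics are far below
  what the architecture reaches with thousands of recordings.
* The simulator's breathing model is a stand-in; no claim of physiological
  fidelity is made beyond the amplitude-reduction event definitions.
* Event-to-segment assignment is by onset; boundary-spanning events are not
  fractionally split (flagged for sensitivity analysis).
* EDF support is single-channel with 1-s records and integer sampling rates;
  vendor annotation dialects (e.g. XML sidecars) are not parsed.
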