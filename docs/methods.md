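# Methods

This note records the modelling decisions behind `roiadj`: what the
synthetic benchmark emulates, how each stage is defined where the
literature leaves the choice open, the numerical conventions, and what the
passing test-suite does and does not establish.

## Problem setting

Two-stage fracture detection: a high-recall detector proposes candidate
boxes `(b_i, s_i)` on a radiograph; a second-stage adjudicator assigns
each ROI a probability `ŷ_i` of containing a true fracture, and the final
decision is made on the fused score `S_i = α·ŷ_i + (1−α)·s_i` at a
threshold `τ`. The adjudicator exists because the detector's errors are
structured: false alarms concentrate on anatomy that locally resembles a
fracture (growth plates, superimposed cortical edges, implants), and raw
detector confidences are overconfident on exactly those regions.

## The synthetic benchmark

### What the generator emulates

`synthgen.generate_scene` renders, at 256×256 (configurable, ≥64):

- **Bones** — bright, soft-edged elongated bands (half-width 10–15 px,
  ±20° off vertical, one per image column slot) with brighter margins
  mimicking cortical edges, on a noisy background with a mild illumination
  gradient and additive Gaussian pixel noise (σ = 0.03 intensity units).
- **Fractures (positives)** — thin (≈1–2 px), sharp, two-segment jagged
  dark lines crossing a bone band, with depth drawn from U(0.16, 0.42) so
  the faintest fractures genuinely approach the noise floor.
- **Growth-plate confounders** — smooth wide transverse lucent bands
  (Gaussian cross-profile, half-width 3–6 px, depth U(0.14, 0.30)): same
  gross geometry as a fracture but smoother and wider.
- **Overlap confounders** — a second bright band crossing the bone at
  30–60°, creating superimposed-edge crossings.
- **Implant-like blobs** — small saturated discs; off by default (the
  third entry of `confounder_rates`).

Every structure carries a tight ground-truth box (expanded to ≥24 px per
side so that proposal jitter cannot collapse the IoU-0.5 match), and every
scene a patient identifier. Given `(SceneConfig, patient_id)` the scene is
bit-reproducible; cohorts derive per-scene seeds from one master seed.

Default per-bone rates (fracture 0.5, growth plate 0.6, overlap 0.4) give
roughly balanced positive/hard-negative ROI streams at realistic densities
— a few candidate regions per radiograph, most of them non-fractures.

### What it does not emulate

No projection physics, no pediatric anatomy, no annotation noise, no
inter-annotator disagreement, no domain shift. Labels are exact by
construction. Consequently the benchmark can demonstrate that the
*mechanisms* work (mining finds the planted confounders, fusion improves
calibration of the planted overconfidence, saliency localizes the planted
fracture) but says nothing about absolute clinical performance; headline
numbers on real radiograph datasets are out of its reach by design.

### The mock detector

`mock_detect` emits one proposal per true fracture with center/size jitter
(Gaussian, σ = 2 px default), a false alarm on each confounder with
probability 0.8, and Poisson(1.0) random-location false alarms per scene;
proposals below the 0.25 confidence threshold are dropped and greedy NMS
at IoU 0.5 deduplicates. Confidences are Beta-distributed by proposal
type — true positives Beta(9, 1.8) (mean 0.83), confounder false alarms
Beta(7.5, 2.4) (mean 0.76), random false alarms Beta(2.5, 3.5) — making
`s` informative but imperfect and deliberately overconfident on
confounders. This is the regime in which confidence fusion is
non-degenerate and calibration improvement is measurable; a detector whose
confidences were already calibrated would leave fusion nothing to fix.
With `fp_rate_confounder` read as a per-confounder-box probability, the
expected false-alarm count per scene is that probability times the number
of confounders.

## Dataset construction

- **Labels**: a proposal is positive iff its IoU with some ground-truth
  fracture box is ≥ 0.5 — the same threshold used by NMS and detection
  evaluation, so one IoU convention runs through the whole pipeline.
- **Crops**: tight boxes, optionally context-padded (the pipeline default
  pads by 0.5 of each side, so the expert box occupies ≈ 1/4 of the patch
  — this is what makes the pointing game a non-trivial test); bilinear
  resize to 64×64; normalization (x − 0.45)/0.25, the approximate scene
  intensity statistics.
- **Augmentation** (training only): horizontal flip, rotation ±8°,
  brightness ±0.08, affine translation ±4% / scale ±4%, drawn per patch
  from the run seed. Evaluation never augments.
- **Splits**: patients are shuffled with the split seed and assigned
  greedily to the split with the largest remaining ROI shortfall. This
  cannot put one patient in two splits, and with uniform ROIs-per-patient
  it achieves target ratios exactly (250 patients × 11 ROIs at 80/10/10 →
  2,200/275/275). Disjointness is asserted on every run, and again inside
  `adjnet.train`.

## The adjudicator

A 4-block strided CNN (3×3 kernels, stride 2, channels 8-16-32-32, ReLU)
maps the 64×64 patch to a 32-dim embedding via global average pooling;
the embedding is L2-normalized (norms below 1e-12 raise rather than
divide), concatenated with the raw `s` (no rescaling — it is already a
probability), and classified by a 64-unit ReLU MLP with sigmoid output.
The backbone is deliberately small: the package targets desk-scale CPU
runs, and the adjudication framework is backbone-agnostic — anything that
exposes the same block/embedding interface can stand behind
`AdjudicatorModel`. He-style initialization from the run seed; no
pretrained weights (nothing is downloaded, ever).

Training: focal loss (γ = 2; probabilities clamped to [1e-7, 1−1e-7]),
Adam. The reference configuration is lr 1e-4, batch 32, up to 50 epochs
with early stopping on validation F1 (patience 10); the desk profile used
by tests, examples and the acceptance script runs 12 epochs at lr 7e-4 on
a ~200-scene cohort, which reaches the same qualitative behaviour in
seconds per fit. Validation F1 during training is computed from `ŷ` at
threshold 0.5 — the fused operating point is selected only after training,
so model selection never peeks at the fusion parameters. The parameters of
the best-validation-F1 epoch are restored on return. The engine
(`roiadj.nn`) is float64 by default; the pipeline trains in float32 for
speed. All forward/backward passes are hand-written and verified against
finite differences in the suite.

## Hard-negative mining

The mining rule is a strict threshold on the fused score among labeled
negatives: `N_h = {ROI : S > τ_mine ∧ y = 0}`, applied every epoch
(cadence K = 1) and accumulated — the pool only grows, matching the
progressive-expansion reading of the curriculum. Records are de-duplicated
by (source image, integer-rounded box); duplication of an original
negative as a mined negative is off by default.

Because the initial training pool is curated (all positives + the easy
negatives), mining draws from a **reservoir**: confounder-sited training
negatives (IoU ≥ 0.3 with a confounder box) start outside `D′` and enter
`N_h` only when the current model scores them above `τ_mine`. This mirrors
deployment, where convincing false alarms accumulate from the detector
stream, and it is what gives mining a measurable effect: without it the
model never sees a growth plate at training time and fires on them at
test time. During training the fused mining score uses the default
α = 0.6 (α is tuned on validation only after training, so some fixed
provisional weight is required; 0.6 is the reported default).

`select_tau_mine` implements a validation-set rule for choosing `τ_mine`
under label noise: the smallest candidate threshold (score midpoints plus
0 and 1) whose above-threshold set has a positive fraction of at most
1 − `precision_floor` (an empty set qualifies trivially; if nothing
qualifies, the median fused score is returned with a warning). On this
benchmark labels are exact, so the contamination concern the rule guards
against does not arise, and at any useful cutoff the above-threshold set
of a competent model is positive-dominated, making the rule maximally
conservative. The pipeline therefore mines at the fixed
`MiningConfig.tau_mine` default of 0.5; the selection rule remains
available for noisy-label settings.

## Fusion, thresholds, calibration, statistics

- `select_threshold` scans 0, 1 and all midpoints between consecutive
  distinct scores; decision rule `S ≥ τ`; F1 ties break toward the
  smallest τ (favoring recall). An all-positive validation set returns
  (0, 1.0); a set without positives is an error.
- `select_alpha` scans α ∈ {0, 0.05, …, 1}, selecting τ per α; F1 ties
  prefer α = 0.6, then the smaller α.
- ECE uses 10 equal-width bins on [0, 1] (last bin right-closed); empty
  bins carry zero weight. Brier is the mean squared error. Reliability
  data are exported per bin for plotting.
- Bootstrap CIs are seeded percentile intervals (default 1,000 resamples);
  resamples on which a metric is undefined are redrawn and counted.
- `wilcoxon_paired` is two-sided signed-rank: exact null for n ≤ 25
  without ties, normal approximation with tie correction otherwise
  (delegated to scipy, which implements exactly this contract).

## Grad-CAM and localization scoring

Channel weights are spatially averaged gradients of the adjudicator
*probability* with respect to the post-ReLU feature maps of the target
layer (default: the last conv block); the map is
`ReLU(Σ_k ω_k A^k)`, bilinearly upsampled to the patch and divided by its
maximum when positive. Note that with L2-normalized embeddings the
gradient lives in the tangent space of the unit sphere, so channels couple
through the normalization Jacobian; the test-suite checks the full
closed-form derivation on a toy network rather than a naive one-channel
shortcut. Masks use a relative threshold (0.5 of the maximum); the
pointing game takes the row-major-first argmax, making results
deterministic under ties. The chance rate reported next to pointing
accuracy is the mean expert-box area fraction of the patch (≈ 0.25 under
the default 0.5 context padding).

## The ablation ladder

The four configurations are cumulative, and the middle rung is defined
as follows: *+HNM* is a plain ROI classifier (the confidence input
replaced by a constant 0.5) trained **with** mining; *+adjudicator* adds
the confidence conditioning `z = [ψ; s]`; *+fusion* adds the convex
combination with α tuned on validation. The detector-only baseline decides
`s ≥ τ_s` with τ_s likewise tuned on validation. This ordering isolates,
in turn: the value of learned appearance with a hard-negative curriculum,
the value of conditioning on detector belief, and the value of blending
both scores at decision time. Ladder comparisons use medians over ≥5
seeds; single-seed orderings can invert between the upper rungs, whose
true gaps are small.

## Numerical conventions and degenerate inputs

Boxes are 0-based half-open pixel rectangles everywhere internally;
YOLO-txt (center-normalized) and the COCO-like JSON dialect are converted
at the I/O boundary, with floats written via `repr` so reader and writer
round-trip bit-exactly (and the coordinate arithmetic itself is exact for
integer boxes with power-of-two image dimensions). 0/0 metric ratios are
defined as 0 and logged. NMS suppresses strictly above the IoU threshold;
mining mines strictly above `τ_mine`; decisions accept at `S ≥ τ`.
mAP@0.5 uses all-points interpolation with greedy highest-IoU matching and
duplicate detections counted as false positives; with one foreground class
mAP equals AP. Degenerate embeddings, empty training sets, single-label
metric inputs, all-zero Wilcoxon differences and non-finite losses raise
rather than return silently.

## Known limitations

- The benchmark's confounders are parametric stand-ins; nothing here
  validates against real growth-plate appearance statistics.
- The mock detector's confidence model is generative fiat, not a trained
  detector's empirical distribution; calibration results quantify the
  mechanism, not any particular detector.
- The engine is CPU-only and desk-scale; at 224×224 with a deep backbone
  it is far slower than a GPU framework (the fidelity profile exists for
  structural parity, not throughput).
- Pool bookkeeping (e.g. the 1,663 + 940 = 2,603 hard-negative-augmented
  pool) reproduces accounting arithmetic; the package takes no position on
  the provenance of any externally reported cohort beyond that arithmetic.
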