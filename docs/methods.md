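# Methods

## Problem and pipeline

Scratching in mouse itch models is scored as *bouts*: maximal runs of
consecutive video frames in which the animal performs the rapid, repetitive
hind-limb motion directed at the irritated site. Manual frame-by-frame
scoring is the standard but is slow; this package automates it for
dark-coated mice filmed from above on a light arena floor at 60 Hz.

The pipeline has five stages:

1. **Preprocessing.** Successive frames are differenced (absolute pixel
   difference), cropped to a square window centered on the body centroid,
   binarized with a strict `> 15` gray-level threshold, and resized with
   nearest-neighbor interpolation to `out_size` (200 px at full scale).
   A *segment* stacks the 21 processed differences covering frames
   t−10 … t+10 and inherits the label of frame t. Motion images discard
   coat color and illumination, which is what makes the approach
   strain-agnostic.
2. **Classifier.** A convolutional recurrent network: three
   convolution + max-pool stages applied per frame (shared weights), two
   stacked LSTM layers over the 21 time steps, and five fully connected
   layers ending in a sigmoid scalar. The 3/2/5 stage skeleton is enforced
   by `CRNNSpec`; inner widths are free parameters because only the
   skeleton is fixed by the method.
3. **Training.** Per epoch, 100 segments are drawn from the scratch-labeled
   pool and 1,500 from all segments regardless of label (independent
   draws); each sampled stack receives one random horizontal-flip decision
   and one rotation by a random multiple of 20°, applied identically to all
   21 images with nearest-neighbor resampling so binarity is preserved.
   Optimization is Adam (default learning rate 3 × 10⁻⁵) on binary
   cross-entropy. Checkpoints are kept every `checkpoint_every` epochs and
   the checkpoint with the lowest validation frame error rate is selected
   (ties → earliest).
4. **Inference.** Each frame with full 21-frame context is called
   scratching when its score is strictly above 0.5. A *posterior filter*
   zeroes every predicted run shorter than 10 frames: sub-170 ms
   "scratching" at 60 Hz is biologically implausible and such runs are
   dominated by walking/grooming false detections. The filter is idempotent
   and can only remove calls.
5. **Evaluation.** Frame confusion counts and the derived percentages
   (sensitivity, specificity, PPV, NPV, error rate), a three-way error
   taxonomy, and per-video bout/duration agreement (Pearson r).

## Error taxonomy — operational definition

The narrative categories are formalized by run overlap:

* a maximal run of false-positive frames is a **false detection** when its
  enclosing predicted run overlaps no labeled bout, otherwise a **boundary
  error** (shifted start/end of an otherwise detected bout);
* a maximal run of false-negative frames is an **oversight** when its
  enclosing labeled bout overlaps no predicted run, otherwise a boundary
  error.

Every mispredicted frame lands in exactly one category, so
boundary + false detection + oversight = FP + FN; this partition identity
is property-tested. A false-positive run bridging two labeled bouts counts
once, as boundary.

## Numerical engine

No deep-learning framework is used: layers are numpy with explicit
backward passes (direct jitted 3×3 convolution kernels, jitted 2×2
max-pool with stored argmax, LSTM backpropagation-through-time, dense
layers), binary cross-entropy is computed from logits in log-sum-exp form,
and Adam updates a flat parameter dict. Gradients are verified in the test
suite against central finite differences on a float64 instance (continuous
inputs; binary inputs create exact max-pool ties whose subgradient is not
the two-sided numerical derivative). BLAS calls are scoped to a single
thread: the network's tall-skinny matrix products thrash a multithreaded
pool on a single core.

Initialization: He scaling for convolution and hidden dense layers, Xavier
for LSTM input/recurrent matrices, forget-gate bias 1. The recurrent
readout uses the final hidden state (`readout="last"`; `"mean"` is
available). Max-pool gradient goes to the first maximal element of each
window; any subgradient is valid at ties, and the choice is deterministic.

## Synthetic study conditions

No recordings are distributed with the method, so every stage is exercised
on synthetic videos: a dark ellipse (the body) on a light arena with
Gaussian pixel noise (sd 2, clipped to [0, 255]). Behaviors:

* **scratch** — an appendage disc adjacent to the body toggles between two
  radial positions with period 5 frames (~12 Hz at 60 fps, the scratch
  frequency range);
* **groom** — the same motif at period 20 frames, the slow-oscillation
  distractor; a frequency-sensitive classifier must separate it;
* **walk** — smooth whole-body translation (2 px/frame, bounce at walls);
* **still** — no motion.

Default synthetic resolution is 240 × 180 rather than full HD: the
preprocessing is resolution-agnostic and desk-scale training must stay
CPU-feasible. The appendage geometry (radius 0.3 r, displacement 0.35 r,
base offset 0.75 r from the body center) keeps both poses inside the
default crop window of 1.5 × body diameter. Schedules place bouts of
≥ 10 frames (so a perfect detection survives the posterior filter) with
≥ 12-frame separations and ≥ 15-frame margins from the video edges (so
every bout is fully scorable).

What the generator does **not** emulate: fur texture, pose articulation,
camera jitter, shadows, multi-animal scenes, and the pixel statistics of
real recordings (contrast and noise defaults are convenience choices).
Passing the synthetic end-to-end check therefore demonstrates that the
pipeline wiring, optimization, filtering and bout arithmetic work — not
that the classifier reaches any particular accuracy on real mice.

The end-to-end acceptance run uses two 600-frame training videos with 10
planted bouts each (20 bouts total), one validation and one held-out video,
the `small` model preset (input 64 px, channels 8/16/32, LSTM 32/32, FC
64/32/16/8/1), 10 epochs of 100 + 200 segments at Adam learning rate 10⁻³,
batch 32, checkpoints every 2 epochs. These are the package's desk-scale
defaults, sized so the whole run finishes in minutes on one CPU; the
full-scale defaults (200 px input, 100 + 1,500 sampling, 3 × 10⁻⁵, 800
epochs, checkpoints every 200) remain the config defaults.

## Numerical conventions and edge cases

* Frame indexing is 0-based; all intervals are half-open `[start, end)`.
* Difference image d_k pairs frames k and k+1 and is cropped at the body
  centroid of frame k (dark-pixel mask, `< 100` gray levels; intensity
  weighting is config-exposed via the threshold). A motionless mouse still
  yields a stable crop center because the centroid comes from the raw
  frame, not the difference.
* Grayscale conversion uses Rec.601 luminance weights, applied at read
  time; differencing color frames before graying is ill-defined, so the
  pipeline grays first.
* Binarization is strict (`> threshold`), including after augmentation and
  crop/resize, which use nearest-neighbor resampling precisely so that
  outputs stay in {0, 1}.
* Edge frames without a full 21-frame window are left unscored (NaN score)
  and called 0; they are excluded from confusion counts and logged.
* Reported percentages are rounded half-up to one decimal (0.25 → 0.3);
  raw ratios are retained internally. Metrics with zero denominators are
  reported as undefined (`None`), never as 0.
* An empty centroid mask falls back to the image center with a warning;
  a body clamped at the arena wall is never an error.
* Sampling quotas larger than the available pool fall back to sampling
  with replacement, logged. Non-finite training loss aborts with a
  diagnostic rather than continuing.

## Known limitations

* The synthetic generator is a wiring test, not a realism benchmark (see
  above); no claim about real-video accuracy is made or tested.
* Checkpoint-level determinism holds per machine; across CPUs with
  different SIMD rounding the trained weights can differ in the last ulp,
  which is why acceptance checks assert margins (baseline beaten, exact
  bout counts with well-separated bouts) rather than bitwise results.
* Video-container decoding requires an imageio plugin with an ffmpeg
  backend; PNG frame directories are the always-available interchange
  format. Splitting long recordings into ~10-minute chunks is an external
  `ffmpeg` concern (see README).
* The classifier scores each segment independently; no temporal smoothing
  beyond the run-length filter is applied, by design.
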