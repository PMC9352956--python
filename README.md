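# scratchdetect

Automated detection of scratching behavior in mouse videos.

Itch research quantifies scratching as *bouts* — maximal runs of
consecutive frames in which the animal rapidly and repeatedly moves a hind
limb toward the irritated site — and their durations. Manual frame-by-frame
scoring of 20–30 minute recordings is accurate but slow; this package
automates it for dark-coated mice (e.g. C57BL/6) filmed from above on a
light arena at 60 Hz, and ships a synthetic-video generator so the whole
pipeline is testable without any animal recording.

## Method

1. **Motion segments.** Successive frames are differenced, cropped around
   the body centroid, binarized (`|Δ| > 15`), and resized; the 21
   processed differences around frame *t* form the *segment* classified
   with the label of *t*.
2. **Convolutional recurrent classifier.** Three convolution + max-pool
   stages per frame, two LSTM layers across the 21 time steps, five fully
   connected layers, sigmoid output in [0, 1]; a frame is called
   scratching when its score exceeds 0.5. Trained with Adam on binary
   cross-entropy, sampling 100 scratch + 1,500 unrestricted segments per
   epoch with flip/20°-rotation augmentation; the checkpoint with the
   lowest validation frame error rate is selected.
3. **Posterior filter.** Predicted runs of nine or fewer frames are
   removed — scratching that brief is implausible at 60 Hz and such runs
   are almost entirely walking/grooming false detections.
4. **Bout statistics.** Each maximal surviving run is one bout;
   duration = run length / fps. Evaluation reports the frame confusion
   matrix, sensitivity/specificity/PPV/NPV/error rate, a three-way error
   taxonomy (boundary / false detection / oversight), and per-video
   bout-count and duration correlations against human labels.

The classifier is implemented natively in numpy (with two numba-jitted
convolution kernels); no deep-learning framework is required. See
`docs/methods.md` for the model, conventions, and limitations.

## Worked example

Run the packaged desk-scale demo — synthesize labeled videos, train the
small preset, predict a held-out video, evaluate:

```bash
scratchdetect run --out demo_run --seed 0
```

which ends with (real output):

```
run complete -> demo_run
pooled sensitivity 98.6%, PPV 92.7%, error rate 3.5%
```

`demo_run/report.json` holds the full evaluation: the confusion matrix,
the error taxonomy, and per-video human vs. predicted bout counts and
durations. Sensitivity is the percentage of human-labeled scratching
frames the model recovered; PPV the percentage of predicted scratching
frames that were truly scratching; the error rate counts all mispredicted
frames. On this synthetic demo the posterior-filtered predictions recover
the planted bout count exactly.

The same stages are available as composable subcommands on real data
(a video file or a PNG frame directory plus a `frame,label` CSV):

```bash
scratchdetect simulate   --out video_dir --seed 3
scratchdetect preprocess --in video_dir/frames --labels video_dir/labels.csv --out segs.npz
scratchdetect train      --segments train.npz --val val.npz --out run/
scratchdetect predict    --model run/model.ckpt.npz --in video_dir/frames --out pred.csv
scratchdetect bouts      --pred pred.csv --fps 60 --out bouts.csv
scratchdetect evaluate   --pred pred.csv --labels video_dir/labels.csv --fps 60 --out report.json
```

Long recordings are conventionally split into ~10-minute chunks before
processing (e.g. `ffmpeg -i in.mp4 -c copy -segment_time 630 -f segment
out%03d.mp4`); the pipeline itself is agnostic to video length above the
22-frame minimum.

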