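# Methods

## The problem and the pipeline

High-resolution esophageal manometry (HRM) records pressures along the
esophagus with a 36-sensor catheter while the patient performs ten 5 mL wet
swallows, and displays each swallow as a color pressure-topography plot
(position × time × pressure).  Chicago Classification v3.0 turns these
tracings into a motility diagnosis in two steps: per-swallow metrics — the
integrated relaxation pressure (IRP) of the esophago-gastric junction and the
swallow's contractile pattern — and a fixed decision tree over the ten
swallows.

`manoclass` automates this from the raster images alone:

1. **preprocess** — binarize the image (gray ≥ 128), locate the white swallow
   onset marker as the column with the most white pixels, crop the swallow
   region of interest (right of the marker) and the IRP region of interest
   (bottom 25 % of rows over the 10 s after the marker), resize bilinearly to
   299×299×3 (IRP task) or 224×224×3 (pattern task), and map pixels to
   [−1, 1] via p/127.5 − 1.
2. **classify** — a frozen convolutional backbone extracts features; a
   trained head (global average pooling → 20 % dropout → dense softmax) makes
   the per-swallow call.  One 2-class head for IRP (normal vs above cutoff),
   one 5-class head for the swallow patterns.
3. **chicago_rules** — the decision tree aggregates the ten per-swallow
   predictions into one of nine diagnoses.
4. **evalmetrics / pipeline** — scoring and orchestration.

## The decision tree

The study-level IRP verdict branches first:

* **elevated IRP**: no panesophageal pressurization → achalasia type I;
  ≥ 2 panesophageal → type II; ≥ 3 premature → type III; otherwise EGJ
  outflow obstruction.
* **normal IRP**: ≥ 3 premature → distal esophageal spasm; ≥ 2 DCI > 8000 →
  hypercontractile esophagus; ≥ 5 weak → ineffective esophageal motility;
  ≥ 5 fragmented → fragmented peristalsis; otherwise normal motility.

The branch order is applied literally.  One consequence is deliberate and
flagged: under elevated IRP, a study with zero panesophageal but three
premature swallows is typed as achalasia type I because the type I check runs
first.  `diagnose(..., strict_chicago=True)` reorders the premature check
ahead of it for users who want the clinically intended behaviour; the default
preserves the published order.  Absent contractility is not an output, and
failed/normal per-swallow labels count only toward an `other` tally that no
rule consumes.

The study-level IRP verdict is a strict majority vote over the per-swallow
IRP classes (ties → normal).  The source material classifies IRP per image
but applies the cutoff per study without saying how the two meet; majority
voting on binary labels emulates the clinical convention of judging the
median IRP against the cutoff.

## Per-swallow metrics

* **IRP** (mmHg): mean of the lowest 4 s (possibly non-contiguous samples) of
  the LES-band aggregate within the 10 s window after swallow onset.  Cutoff
  28 mmHg, the upper limit of normal for the solid-state catheter emulated
  here; configurable.
* **DCI** (mmHg·cm·s): integral over the distal esophageal segment and the
  post-onset window of pressure in excess of the 20 mmHg isobar,
  `sum(max(p − 20, 0)) · Δx · Δt`.  Weak < 450; hypercontractile > 8000.
* **Premature**: distal latency < 4.5 s.  **Fragmented**: break ≥ 5 cm in the
  20 mmHg contour with preserved vigor.

The numeric pattern definitions (450, 4.5 s, 5 cm) are the standard v3.0
conventions; they parameterize the simulator's ground truth and are not
claims about how any particular clinical annotator labeled images.

## The synthetic generator

No patient images ship with the package; every training and test image is
simulated.  The generative model is a traveling Gaussian pressure ridge on a
36 × 600 grid (60 s at 10 Hz, 1 cm sensor spacing): sensor rows 0–1 are the
upper sphincter (constant 25 mmHg tone), rows 2–30 the esophageal body, rows
31–35 the LES band.  The ridge arrives at body sensor *s* at
`onset + latency · depth(s)/L` with Gaussian temporal width (default 1 s) and
amplitude 80 mmHg; defaults per appearance class:

| appearance     | realization                                            |
|----------------|--------------------------------------------------------|
| normal         | amplitude 80, distal latency 7 s (DCI ≈ 1700)          |
| weak           | amplitude 35 (DCI ≈ 300 < 450)                         |
| hypercontractile | amplitude 220, width 2 s (DCI ≈ 12 000 > 8000)       |
| premature      | distal latency 3 s (< 4.5 s)                           |
| fragmented     | 5 cm mid-body amplitude gap, vigor preserved           |
| panesophageal  | 35 mmHg isobaric band across the body for 8 s          |
| failed         | no ridge; body stays within noise of the 2 mmHg baseline |

The LES band rests at 35–45 mmHg and, for 12 s after onset, sits at the
"relaxed" level: 4–12 mmHg for a normal-IRP swallow, 32–45 mmHg (no real
relaxation) for a high-IRP one.  Additive Gaussian noise (sd 1 mmHg, clipped
at 0) is seeded.  Ground-truth IRP and DCI labels are **measured from the
simulated field** with the same formulas defined above — never copied from
the generator's parameters — so label consistency is enforced at generation
time.

Rendering maps pressure through a fixed piecewise-linear
blue→teal→green→olive→red palette over [0, 150] mmHg and upsamples to the
pixel grid; the onset marker is a pure-white 2 px column at
`round(onset/duration · width)`.  Every palette color has grayscale mean
below 128 by construction, so binarization at 128 isolates exactly the
marker and marker localization is exact on every rendered image — a
simulator design choice that makes the preprocessing contract testable, not
a property claimed for vendor screenshots.

Study generation inverts the decision tree: per-diagnosis pattern counts are
sampled inside the firing region of exactly the intended rule (e.g. type II:
2–6 panesophageal, failed fillers; type III: exactly one panesophageal — the
count that escapes both the type I and type II rules — plus 3–6 premature),
the per-swallow IRP classes are sampled with the majority on the intended
side, and the batch is verified through the rule engine before it is
returned.

### What the simulator does not emulate

Real tracings have vendor axis legends and margins, respiration and
catheter-movement artifacts, variable esophageal length, mixed/borderline
swallow morphologies, and inter-annotator ambiguity.  Synthetic classes are
cleanly separated by construction, so per-swallow validation accuracies near
100 % and the high study-level accuracy below say that the pipeline's
plumbing and logic are correct — not that the classifiers would reach these
scores on clinical images.

## Classifiers

No deep-learning framework is required: backbones and heads are implemented
in numpy.  The default backbone, `tiny_test_cnn`, appends two normalized
coordinate channels to the RGB input (so globally pooled features retain
coarse position information, which separates premature from normal timing),
block-averages to 56×56, and applies three 3×3 convolution blocks
(32/64/128 channels, He-scaled seeded Gaussian weights, ReLU, 2×2 max
pooling) followed by global average pooling to a 128-vector.  Random
convolutional features with a trained linear readout are a standard strong
baseline, and a seeded backbone makes every result reproducible with no
weight downloads.  `inception_v3` / `densenet201` backbone names are
accepted and enforce their 299/224 input contracts; with random weights they
are stand-ins honoring those contracts, and requesting pretrained weights
raises an error since no weight source is bundled.

The head is trained with Adam (learning rate 1e-3), categorical
cross-entropy, batch size 32, inverted dropout 0.20 on the input features,
and per-epoch reshuffling, for 30 epochs with best-test-loss checkpointing.
Features are standardized with train-split statistics.  The stratified
70/15/15 train/test/validation split is drawn once per run: the test split
is monitored every epoch and selects the checkpoint; the validation split is
evaluated exactly once, on the finalized classifier, and its report is the
only validation artifact the API exposes.  Inference applies no dropout and
is deterministic; argmax ties break toward the earlier class in the declared
class order.

### Out-of-class swallows at prediction time

The pattern head has five outputs, but a study also contains normal and
failed swallows.  They are classified anyway (forced choice) and whatever
label they receive feeds the counts; no abstention threshold is applied,
because measured softmax confidence on out-of-class synthetic swallows
overlaps the in-class range and cannot gate them reliably.  The observable
consequence in the synthetic benchmark: normal-pattern swallows are absorbed
by the most similar trained class (fragmented), so normal-motility studies
are systematically pushed into the fragmented-peristalsis rule while every
other diagnosis is recovered — the study-level confusion matrix shows this
directly.  This mirrors the known weakness of excluding the failed/normal
classes from the classifier rather than papering over it.

## The synthetic benchmark (`pipeline.run_experiment`)

Defaults, chosen once as a desk-scale experiment: 70 training swallows per
pattern class (350) plus 150 normal/failed swallows that only the IRP task
sees (500 images total, each yielding a 299×299 IRP tensor and, for pattern
classes, a 224×224 swallow tensor); both heads trained as above; 200 fresh
held-out studies sampled uniformly over the nine diagnoses and diagnosed end
to end from pixels.  Every stage's seed derives from the single config seed,
and reports (JSON, sorted keys, probabilities rounded to 1e-6) are
byte-identical across reruns of the same config.  The class-exclusion config
mirrors the ablation of dropping the two most confusable diagnoses
(ineffective motility, fragmented peristalsis) from the study mix.

## Numerical and degenerate-input choices

* Grayscale for thresholding is the arithmetic mean of RGB (the marker is
  pure white, so any convex channel combination finds it).
* Marker histogram ties break to the smallest column index.
* Crops use 0-based, origin-top-left, half-open intervals; default top/bottom
  margins are 0 (synthetic images have no axis legends; real exports can set
  them in config).
* Bilinear resizing of 8-bit pixels cannot leave [0, 255], so normalized
  tensors stay in [−1, 1]; a clip guards float round-off.
* Precision/recall are 0 by convention on empty denominators; F1 is the
  harmonic mean (0 when both are 0); printed percentages are truncated, not
  rounded, to two decimals (31/32 → 96.87), with full precision retained
  internally.
* Degenerate requests error early: empty studies, all-black masks (no
  marker), crops that leave no pixels, IRP windows past the image edge,
  single-class training sets, non-finite losses.

## Known limitations

* The generative model targets appearance classes, not physiology; no
  vendor file formats, no multi-swallow frames, no de-skewing or color
  calibration.
* The rule engine's literal branch order is preserved by default even where
  it is clinically surprising (see above).
* How mixed per-swallow IRP predictions should aggregate at study level is a
  convention (majority vote) rather than a published rule.
* Accuracy figures from the synthetic benchmark characterize the pipeline on
  simulated data only and do not transfer to clinical images.
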