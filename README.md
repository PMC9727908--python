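# phantomqc

Automatic scoring of ACR mammography accreditation phantom images for
daily quality control (QC).

Mammography QC centres on a daily radiograph of a test phantom whose wax
insert holds 16 targets of decreasing conspicuity — six fibres, five
microcalcification (speck) groups, and five masses. A reviewer awards
each target 0, 0.5 or 1 point and compares the per-family totals
(fibres / 6, speck groups / 5, masses / 5) against acceptance
thresholds. Scoring by eye is slow and drifts between reviewers and
over the years of a device's life; `phantomqc` replaces it with a
convolutional-network classifier plus the statistics needed to audit it
against human reviewers.

The package covers the whole workflow, with a synthetic phantom
generator standing in for clinical QC archives so that everything is
testable offline:

- **`phantom_synth`** — renders ACR-style phantom radiographs at device
  pixel sizes 50–100 µm with per-phantom target geometry, wax texture,
  and noise whose variance is `σ_read² + g·I_wax / dose`; ground-truth
  visibility comes from a contrast-to-noise-ratio rule (CNR ≥ 2 visible,
  ≥ 1 barely visible).
- **`preprocess`** — locates the phantom by signal intensity, crops the
  wax insert from the axis intensity transitions, rotates to canonical
  orientation using the largest mass, replaces the burned-in phantom
  name with matched noise, cuts 16 target squares, removes background
  with 2-D polynomial fits (order 5 for fibres, order 1 otherwise), and
  emits 128×128 sub-images scaled to [0, 1].
- **`augment`** — degrades images by mixing in mosaics of randomly
  sampled 10×10 patches from a target-free noise template (weights
  30–80 % in 5 % steps; 110 images/device) and improves them by
  averaging 2–20 acquisitions aligned on a 0.05° rotation grid
  (120 images/device).
- **`dataset`** — 17-class labelling (f1–f6, c1–c5, m1–m5, plus one
  pooled non-visible class), 90:10 image-level splitting, and balancing
  by resampling-with-rotation to 2N sub-images per visible class and 6N
  non-visible (38N total).
- **`cnn_model`** — the eight published architectures CNN1–CNN8 (three
  to ten convolutional blocks; 5×5 then 3×3 kernels; batch norm + ReLU;
  3×3/stride-2 max pooling; 30 %/50 % dropout; 17-way softmax) with
  exact trainable-parameter accounting, built on an in-repo numpy
  engine and trained with SGD + momentum (lr 0.01, momentum 0.9).
- **`scoring`** — ACR point rules (speck groups score 0 / 0.5 / 1 from
  <3 / =3 / >3 visible specks), score sheets, pass thresholds.
- **`evaluation`** — noise power spectra (periodogram, radial binning,
  5-point smoothing, Parseval-consistent), accuracy and per-class
  sensitivity, exact Wilcoxon signed-rank, Fleiss' kappa, and
  reviewer-vs-model agreement reports.
- **`pipeline` / `phantomqc` CLI** — end-to-end orchestration with a
  JSON run manifest.

## Worked example

```python
from phantomqc.phantom_synth import make_device_profiles, generate_phantom
from phantomqc.preprocess import preprocess_image
from phantomqc.scoring import ScoreSheet, sheet_passes

profile = make_device_profiles(8, seed=7)[0]
image, truth = generate_phantom(profile, dose_factor=1.0, seed=3)
subs = preprocess_image(image, seed=0)
sheet = ScoreSheet.from_points(truth.points)
print(len(subs), sheet.totals, sheet_passes(sheet, (4, 3, 3)))
```

prints

```
16 (5.0, 4.0, 4.5) True
```

Sixteen normalized sub-images were extracted; at standard dose this
device sees 5 of 6 fibres, 4 of 5 speck groups and 4.5 of 5 mass points
(f5/f6 and m5 are only barely visible, c5's specks fall below the
visibility threshold), which passes the (4, 3, 3) site thresholds. A
full pipeline run, including training a reduced network and comparing
its score sheets with the ground truth, is one call:

```python
from phantomqc.pipeline import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(n_devices=2, images_per_device=6, seed=1))
```

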