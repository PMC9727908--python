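# Methods

## The scoring problem

Daily mammography QC images an ACR accreditation phantom: a wax insert
holding six fibres, five microcalcification (speck) groups and five
masses, ordered by decreasing conspicuity within each family. A
reviewer scores each target 0 (not visible), 0.5 (barely visible) or 1
(visible); speck groups score from the number of visible specks
(fewer than three: 0, exactly three: 0.5, more than three: 1). The
per-family totals are compared against site acceptance thresholds.
`phantomqc` automates this with a 17-class image classifier: each of
the 16 target sub-images is classified either as its own target class
(f1–f6, c1–c5, m1–m5) or as the pooled non-visible class, so the
network both detects visibility and recognizes which target it is
looking at — the recognition acting as an internal consistency check
("strict" scoring counts a target visible only when its own class is
predicted; "lenient" accepts any target class).

## Synthetic phantom model

The generator stands in for a clinical QC archive. Its defaults define
the study conditions and are not tuned per experiment.

Image model (intensities on a 16-bit-like scale):

* open-field background 3,000; phantom block 8,000; wax insert 10,000,
  the insert carrying a smooth per-phantom texture (Gaussian field,
  6 mm correlation length, sd 50) and a gentle plane gradient
  (amplitude 120) so background detrending has real work;
* 16 additive targets on a 4×4 grid. Fibres are anti-aliased line
  segments (10 mm long, diameters 1.56–0.40 mm, per-phantom angles)
  with Gaussian cross-profile; masses are flat-topped disks
  (9.0–2.5 mm) with Gaussian-tapered rims; speck groups are six
  Gaussian blobs (0.54–0.16 mm) in a per-phantom cluster pattern.
  Contrasts decrease strictly with index within each family
  (fibres 500→120, specks 650→160, masses 550→160);
* an engraved (dark, −2,500) blocky name overlay, which the
  preprocessing chain must learn to ignore;
* additive Gaussian noise with variance `σ_read² + g·I_wax /
  dose_factor` (per-device read noise 30–50, quantum gain 0.7–1.1).
  `dose_factor = ∞` leaves only read noise.

Fleet model: `make_device_profiles(8)` yields seven FFDM systems with
pixel sizes drawn from 83–100 µm and one 50 µm CR system, matching a
typical multi-vendor installed base. Each profile carries a phantom
seed, so every device images its own physically distinct phantom
(fibre angles and speck patterns differ), which is also true of real
ACR phantoms.

Ground truth is a contrast-to-noise-ratio rule with a hysteresis band:
CNR = contrast / σ_noise; ≥ 2 scores 1 point, ≥ 1 scores 0.5, below
that 0. Specks carry a fixed ±18 % amplitude pattern within each group
so that partially visible groups (and 0.5-point group scores) occur at
intermediate doses. Real visibility is a human judgement; the CNR rule
is this package's operationalization, chosen because it is monotone in
dose and exactly recomputable from the rendered image (both properties
are tested).

What the generator does **not** emulate: X-ray transport, scatter,
heel effect, detector blur/MTF, spatially correlated noise, and
artefacts. Tests passing on synthetic data therefore demonstrate the
pipeline's mechanics and internal consistency, not clinical
performance.

## Preprocessing

* Phantom extraction: Otsu threshold, largest connected region,
  bounding box. Wax extraction: smoothed row/column mean profiles;
  the strongest rising/falling gradient pair per axis, refined to the
  centroid of the gradient plateau (the smoothing window otherwise
  biases the edge by half its width). Candidate edges hugging the crop
  border (< 2 % margin) are rejected as artefacts; a flat profile at a
  plausible plateau is accepted as an already-cropped wax image.
* Orientation: restricted to 90° multiples (gross mispositioning is
  the only realistic failure). The largest mass is found as the peak
  of a band-pass (difference-of-Gaussians) response at the mass scale;
  its quadrant decides the rotation. A peak below 4 robust standard
  deviations returns the input flagged `orientation-ambiguous`.
* Name masking: the configured rectangle is refilled with Gaussian
  noise matched to the mean and sd of a surrounding frame.
* Sub-images: 16 squares stored in wax-relative fractional coordinates
  (side 0.24 of the wax), so one configuration serves all pixel sizes;
  a 100 µm device yields ~192 px patches and the 50 µm CR device ~384.
  Detrending fits a full bivariate polynomial basis (total order 5 for
  fibres, 1 otherwise) by ordinary least squares on [-1, 1]²
  coordinates. Patches are resized bilinearly to 128×128 and min-max
  scaled per patch to [0, 1] (patches are processed individually, so
  per-patch scaling; a constant patch is an error).

## Augmentation

Degradation mixes an image with a mosaic of 10×10 patches drawn
uniformly with replacement from the template's non-overlapping tiling,
the mosaic first rescaled to the image's wax mean:
`out = (1 − w)·image + w·mosaic`. The wax mean is preserved within
1 % for every weight. Because the mixture attenuates target contrast
by (1 − w), the noise that matters for conspicuity is the residual
relative to the retained signal, which grows strictly with `w`; the
monotonicity tests and the NPS comparison measure it that way. The
default campaign (weights 0.30–0.80 step 0.05, ten images each)
yields 110 degraded images per device.

Noise reduction averages 2, 3, 4 or K acquisitions (K defaults to 8;
5–20 depending on device performance), thirty images per level → 120
per device. Alignment detects the three most conspicuous speck groups
(robust-z ≥ 5.5 against the local MAD, subpixel centroid refinement)
and grid-searches the rotation on a 0.05° lattice within ±2°,
minimizing summed landmark displacement; the aligned image is produced
by a single rotation of the original, never by chained interpolations.

Training-time augmentation rotates sub-images by angles uniform on
[−3°, 3°] (bilinear, re-clipped to [0, 1]).

## Corpus assembly

Reviewer points are binarized for training (0.5 → visible). Consensus
labels take the median of the reviewers' points with ties at 0.5
rounded up. The train/validation split is 90:10 at image level
(unstratified), so no source image leaks across the split. Balancing
brings every visible class to exactly 2N sub-images and the pooled
non-visible class to 6N (N = training images) by drawing members with
replacement and rotating each draw; this is the rule that reproduces
the published corpus accounting (N = 2,376 → 16 × 4,752 + 14,256 =
90,288 = 38N). A class with no members raises an error rather than
silently skewing the balance.

## Networks and training

All eight architectures share one recipe: first convolution 5×5, the
rest 3×3, stride 1, size-preserving padding (forced by the published
feature-map sizes, 128 → 128 under the first convolution); channels
30, 45, 60, then +20 per block; each block is convolution + batch
normalization + ReLU, with 3×3/stride-2 unpadded max pooling on the
early blocks (forced by 128 → 63); dropout 30 % between blocks and
50 % before the single fully connected layer feeding the 17-way
softmax. Depth and pooled-block counts per architecture:

| name | blocks | pooled | head input | parameters |
|------|-------:|-------:|-----------:|-----------:|
| CNN1 | 3 | 3 | 15×15×60 | 267,122 |
| CNN2 | 4 | 3 | 15×15×80 | 387,062 (published 386,902) |
| CNN3 | 5 | 4 | 7×7×100 | 236,662 |
| CNN4 | 6 | 5 | 3×3×120 | 280,082 |
| CNN5 | 7 | 5 | 3×3×140 | 434,762 |
| CNN6 | 8 | 4 | 7×7×160 | 748,702 |
| CNN7 | 9 | 4 | 7×7×180 | 1,025,102 |
| CNN8 | 10 | 4 | 7×7×200 | 1,366,362 |

Parameter accounting counts convolution weights and biases, two affine
parameters per normalized channel, and the dense head; the built
network's tensors enumerate to the same totals. CNN2's published
total is exactly one 80-channel normalization's affine pair (160)
below the reconstruction of its printed layer column; the spec here
encodes the column as printed and carries the 160 discrepancy openly
rather than guessing which block lacked normalization.

Training is SGD with momentum (constant lr 0.01, momentum 0.9),
cross-entropy loss, mini-batch 2,736 (33 iterations per epoch on the
90,288-image corpus), 400 epochs for CNN1 and 300 otherwise, keeping
the checkpoint with the highest validation accuracy. The layers run on
an in-repo numpy engine (im2col convolutions, analytic batch-norm and
pooling gradients, inverted dropout); gradients are verified against
numerical differentiation and training is bit-deterministic under a
fixed seed on one platform.

Desk-scale profile: the full 128×128, 300-epoch configuration is the
default, but every knob (input size, epochs, batch) is a config value.
The repository's end-to-end check trains CNN1's block structure at
32×32 input on 2 devices × 20 high-dose images (640 sub-images) for
20 epochs with batch 64 — a corpus separable by construction — and
reaches perfect validation accuracy within that budget; a noiseless
phantom then scores the full (6, 5, 5).

## Evaluation statistics

* NPS: per-ROI periodogram of the mean-detrended ROI scaled by
  `a² / (Nx·Ny)` (a = pixel size in mm), ensemble-averaged, radially
  binned with bin width one frequency sample, smoothed with a 5-point
  moving average. Summing the 2-D NPS times the frequency-bin area
  recovers the ROI variance exactly (Parseval); the radial reduction
  was chosen over row/column averaging for its lower variance on
  isotropic noise.
* Wilcoxon signed-rank: zero differences discarded (classic
  treatment), midranks for ties, exact sign-flip null by convolution
  for n ≤ 25 (half-ranks handled by 2× integer scaling), otherwise a
  normal approximation whose variance uses the midranks directly
  (Σr²/4, which reduces to the tie-corrected formula). Two-sided p as
  `2·min(P≤, P≥)` capped at 1.
* Fleiss' kappa: the standard (P̄ − P̄ₑ)/(1 − P̄ₑ) for a constant rater
  count; degenerate single-category tables return NaN with a flag.
  Cross-checked against statsmodels in the tests.
* Agreement reports: per target family, mean ± sd of totals, fraction
  of images scored exactly equal and within ±1 point, the signed-rank
  p-value, and a consensus-vs-model scatter table.

## Known limitations

* The CNR visibility rule is a stand-in for human judgement; absolute
  sensitivities on synthetic data say nothing about clinical accuracy.
* The patch-mosaic degradation whitens low-frequency noise (patches
  are only 10×10), so degraded and real low-dose images differ in NPS
  shape at low frequencies.
* The numpy engine is single-threaded BLAS-bound; full 128×128
  training at 300 epochs is possible but slow, and is not exercised by
  the test suite.
* Pass thresholds (default 4/3/3) are a conventional site setting, not
  a published constant; configure to local policy.
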