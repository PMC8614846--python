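# Methods

This note documents the models, conventions and numerical choices behind
`kneejsw`, and what the synthetic validation does and does not demonstrate.

## Phantom construction

A phantom knee is defined by a superior tibial margin (a polynomial in the
normalized plateau coordinate x) and a gap profile g(x) in mm; the inferior
femoral margin is *derived* as tibial margin minus g/(mm per pixel), so the
joint gap is correct by construction rather than by measurement. Margins are
quantized to whole pixel rows before rendering; the recorded truth is the
quantized profile (the one actually encoded in the mask), so downstream
recovery tests are exact up to stated tolerances rather than fuzzy. The
analytic minimum location is recorded from the continuous profile, because
quantization flattens the minimum into a tie of columns.

Conventions: image rows increase downward; the femur has smaller row
indices. Pixel (r, c) occupies [r−0.5, r+0.5] × [c−0.5, c+0.5]; the femoral
margin sits on the bottom edge (r + 0.5) and the tibial margin on the top
edge (r − 0.5). A right knee renders the medial compartment at high
columns; a left knee is its mirror image. Intensity noise is additive
Gaussian on the radiograph only — masks are always noise-free, so geometry
tests are isolated from segmentation quality.

The phantoms emulate the geometry of the tibiofemoral joint space and the
label statistics of annotated masks. They do **not** emulate trabecular
texture, projection physics, the double anterior/posterior tibial edge, or
osteophytes; a network that segments phantoms perfectly has demonstrated
the pipeline's correctness, not clinical-grade segmentation.

## Observer pairs and cohorts

Observer pairs are b = a + bias + N(0, sd²) with a drawn from a clipped
normal centred at 3.5 mm (SD 1.35 mm), typical of medial minimum-JSW in a
screening population. Synthetic cohorts draw baseline KL grades from a
published screening prevalence (38.6 / 18.1 / 26.4 / 13.7 / 3.2% for grades
0–4) through a Gaussian copula, so bilateral knees of one subject are
correlated (ρ ≈ 0.7) while the marginal prevalence is exact. Each knee's
64-point width profile is a healthy baseline profile minus a severity-scaled
narrowing shape (Gaussian bumps at x = 0.8 medial and x = 0.2 lateral,
0.65 mm per grade by default, `lateral_fraction` splitting the two), plus
per-knee and per-site noise (0.10 / 0.08 mm). `signal_strength` interpolates
between KL driving the narrowing deterministically (1) and narrowing
independent of KL (0). Progression of unaffected knees follows the same
latent narrowing through a threshold; dropout (10%) blanks the 48-month
grade.

## Preprocessing

Intensity normalization clips the histogram between the 5th and 99th
percentiles and maps the clipped range affinely to [0, 1]. The percentiles
are the inclusive order statistics (`higher` for the low cut, `lower` for
the high cut) rather than linearly interpolated values: with interpolation,
re-normalizing an already-normalized image finds a 5th percentile slightly
above zero and rescales by ~1e-6, whereas the inclusive choice makes the
operation exactly idempotent — a property the pipeline relies on because
images may pass through normalization more than once. The two definitions
differ by at most one order statistic. Flat histograms fall back to min–max
mapping; constant images map to zeros.

Resizing is bilinear for radiographs (anti-aliased when downscaling) and
nearest-neighbour for masks, which preserves the label set exactly. Pixel
spacing is carried per axis as (row_mm, col_mm) because a non-square input
resized to a square has anisotropic spacing; vertical widths use row_mm and
Euclidean distances use both.

## Segmentation network

The encoder is the standard 18-layer residual topology: a 7×7 stride-2 stem,
2×2 max pooling, then four stages of two basic blocks at widths 64 / 128 /
256 / 512 with projected shortcuts at stage transitions. The decoder — for
which no reference design exists in this setting — mirrors the encoder:
four stages of nearest-neighbour 2× upsampling, concatenation with the
corresponding encoder skip, and one 3×3 convolution + batchnorm + ReLU, with
a final upsample and a small head ending in a 1×1 convolution to 4 channels.
Output channels (femur, fibula, tibia, background) pass through independent
sigmoids — a multi-label formulation with per-channel binary cross-entropy,
not softmax — and the predicted label is the argmax with ties resolved to
the lowest class index. An optional `dilated` switch replaces the deepest
stage's convolutions with dilation-2 (atrous) ones; it is off by default.
A 50-layer bottleneck variant exists solely to check that the 18-layer
network is the smaller model (13.5M vs 60.8M parameters at width 64).

All layers, including 2-D convolution (realized as kernel-offset slices
feeding BLAS matrix products) and its exact reverse-mode gradients, are
implemented in numpy inside the package; training is single-threaded CPU,
float32, and bitwise reproducible for a fixed seed.

Training uses Adam (lr 0.001, β = (0.9, 0.999), weight decay 1e-5 folded
into the gradient), per-epoch augmentation (rotation uniform in ±5°, shifts
uniform in ±10% of the side, horizontal flip with probability 1/2, and ±10%
multiplicative contrast/gain jitter — the jitter amplitude is a package
default, as is batch size 4 and the 300-epoch cap), and early stopping when
validation loss has not strictly decreased for 10 epochs (no minimum delta);
the returned weights are those of the best validation epoch. Binary
cross-entropy is computed in the numerically stable logit form during
training; the public `bce_loss` clips probabilities to [1e-7, 1−1e-7].

The training sanity check memorizes 5 phantom pairs at 128×128 to mean IoU
≥ 0.95; at this problem size one epoch (full batch of 5) takes roughly 2–3 s
on one CPU core and the target is typically reached within 30 epochs. This
scale was chosen so the whole check completes in about a minute; it
exercises every layer's forward and backward pass at realistic depth.

## Contours and the plateau frame

On a label mask, the articular margins are the per-column extremal
boundaries: the lowest femur pixel edge and the highest tibia pixel edge,
restricted to the largest contiguous run of columns where both bones exist.
On a binary raster this coincides with what an edge filter would trace but
is deterministic and parameter-free. The plateau frame maps the first/last
margin columns to x = 0/1; laterality metadata (or an explicit
`medial_side` override) mirrors the axis so the medial compartment is
always at high x — masks alone cannot disambiguate the two sides, so
unknown laterality without an override is an error.

## JSW measurement

Per-site width is the **vertical** (row-direction) inter-margin distance at
the pixel column nearest to the site, in mm via row spacing. The sampling
convention is half-open: {a + k·spacing, k = 0 … n/2−1} per compartment on
equal-width ranges [0.10, 0.30) and [0.70, 0.90). This is the unique
convention under which spacings 0.05 / 0.025 / 0.0125 / 0.00625 yield
exactly 8 / 16 / 32 / 64 sites and dyadic grids nest with exact width
agreement at shared sites. Sites whose column falls outside the margin
overlap (possible when a frame fixed at baseline is applied to a degraded
segmentation) copy the nearest valid site's width and are flagged; a
profile with more than 25% missing sites is rejected. Crossing margins
(bone-on-bone contact) clamp the width at 0 with a warning.

Minimum JSW is the exhaustive all-pairs Euclidean minimum
√((Δrow·row_mm)² + (Δcol·col_mm)²) between margin points with x in
[0.7, 0.9]. Brute force over the window (≲200×200 pairs) is exact and fast;
it is the reference semantics, and the test suite holds the implementation
to bit-for-bit equality with an independent double-loop oracle. The
Euclidean minimum is bounded above by every vertical width in the window.

Calibration is a required scalar (DICOM pixel spacing or explicit
configuration); detecting calibration beams in the image is out of scope.

## Agreement statistics

Differences are first argument minus second. Bias is the mean difference;
limits of agreement are bias ± 1.96·SD (denominator n−1). The interobserver
"error" is summarized both ways: signed (bias, SD) and absolute
(mean and SD of |d|), since a folded summary is what inter-observer error
tables usually report. ICC is the two-way random-effects,
absolute-agreement, single-measurement form ICC(2,1), computed directly
from the ANOVA mean squares
(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)); the test suite checks
it against an independently coded ANOVA oracle and against pingouin's
ICC(A,1) to 1e-9. Zero-variance input leaves Pearson r undefined (NaN with
a warning) while the Bland–Altman and ICC quantities are still returned.

## Severity and progression prediction

Progression is the transition from baseline KL 0–1 to KL 2–4 at 48 months;
knees already at KL ≥ 2 or missing follow-up are excluded. Features are
either the medial minimum width alone or an n-point profile (subsampled
from the stored 64-point grid; dyadic nesting makes the subsampling exact).
The classifier is XGBoost (60 trees, histogram method, single thread,
seeded); max_depth / L1 α / L2 λ are grid-searched by mean macro F1 over
stratified 5-fold CV, with default grids that include depth 30, α 1, λ 1
(severity) and depth 25, α 0.5, λ 1 (progression). The 8:2 train/test split
is stratified by label at the subject level so bilateral knees never
straddle the split. Evaluation bootstraps the test set 100 times with a
fixed model (resamples missing a class are redrawn, at most 1000 attempts);
multiclass AUC is macro-averaged one-vs-rest; confidence half-widths are
1.96·SD over bootstrap samples. AUC distributions of two experiments are
compared with Welch's unpaired two-sided t-test; if both sample vectors are
degenerate (zero variance) the p-value is defined as 1 for equal means and
0 otherwise.

Test problem sizes — cohorts of 150–1000 knees, 20–100 bootstrap rounds,
small hyperparameter grids — were chosen to exercise every code path in
seconds. The profile-vs-minimum comparison uses a cohort whose narrowing is
placed in the lateral compartment, which the medial minimum cannot see by
construction; it demonstrates the mechanism by which whole-profile features
carry more information, not the effect size expected on clinical data.

## Known limitations

- Inputs must be pre-cropped single-knee images with known laterality (or an
  explicit medial-side override); bilateral-film splitting is not provided.
- Widths are vertical in image coordinates; perpendicular-to-midline or
  medial-axis width definitions are not implemented.
- The contour module requires masks; extracting margins from raw images
  (double-edge disambiguation under 3-D projection) is out of scope.
- Synthetic cohorts have idealized monotone JSW–KL structure; absolute
  classification scores on them say nothing about clinical performance.
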