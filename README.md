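# kneejsw

Automated measurement of tibiofemoral **joint space width (JSW)** from knee
radiographs, and JSW-based prediction of **Kellgren–Lawrence (KL)** severity
and knee-osteoarthritis progression.

Radiographic JSW — the distance between the inferior femoral condyle margin
and the superior tibial plateau margin — is the standard imaging proxy for
articular cartilage thickness. Clinical practice usually records only the
*minimum* JSW in the medial compartment, a single number that ignores the
shape of the rest of the joint. This package implements the full pipeline
needed to do better, automatically:

1. **phantom** — synthetic radiograph/mask pairs with analytically known
   gap profiles g(x), synthetic observer pairs, and synthetic cohorts, so
   every stage can be validated offline against exact ground truth;
2. **imaging** — DICOM/PNG reading, histogram truncation at the 5th/99th
   percentiles with global contrast normalization to [0, 1], and square
   resizing (default 1024×1024) with per-axis mm calibration;
3. **segmentation** — a residual U-Net (18-layer residual encoder, skip
   connections, 4 independent sigmoid output channels for femur / fibula /
   tibia / background) trained with per-channel binary cross-entropy, Adam
   (lr 0.001, weight decay 1e-5), rotation/shift/flip/contrast augmentation
   and early stopping (patience 10), all on CPU;
4. **contour** — per-column extremal articular margins from label masks and
   a normalized plateau frame x∈[0,1] with the medial compartment at high x;
5. **jsw** — multi-point JSW: vertical widths at n/2 fixed sites per
   compartment in [0.10, 0.30) and [0.70, 0.90) (n = 8/16/32/64 at spacings
   0.05/0.025/0.0125/0.00625), and minimum JSW: the exhaustive all-pairs
   Euclidean minimum between the margins for x∈[0.7, 0.9], in mm;
6. **agreement** — Pearson r, R², Bland–Altman bias d̄ ± 1.96·SD limits of
   agreement, and ICC(2,1) from two-way ANOVA mean squares;
7. **prediction** — XGBoost classifiers for 5-class KL severity and binary
   48-month progression (KL 0–1 → 2–4), grid-searched with stratified
   5-fold CV, evaluated on a subject-grouped 8:2 split with 100 bootstrap
   resamples (mean macro F1 and AUC ± 1.96·SD), and Welch t-tests for
   comparing AUC distributions.

## Worked example

Generate a phantom knee whose medial gap narrows parabolically, then measure
it (the phantom's truth is known analytically, so you can check the output):

```sh
$ kneejsw simulate --out phantom --seed 3
phantom written to phantom (min medial gap 3.00 mm at x=0.802)

$ kneejsw measure --mask phantom/mask.png --laterality right \
      --mm-per-pixel 0.2 --points 16 --out jsw.csv
16-point profile + minimum JSW (2.81 mm) written to jsw.csv
```

`jsw.csv` lists the 16 sites (x, width in mm, imputation flag) followed by
the minimum-JSW row. The vertical width at the minimizing site is 3.00 mm —
the all-pairs Euclidean minimum (2.81 mm) is slightly smaller because the
margins are not parallel, and it is always ≤ every vertical width in the
search window.

Severity prediction on a synthetic cohort (KL grade drives joint narrowing;
features are the per-knee JSW profile):

```sh
$ kneejsw predict --features phantom/cohort.csv --task severity \
      --points 16 --seed 1 --out severity.json
severity/profile: macro F1 0.807 (+/-0.151), AUC 0.959 (+/-0.041)
```

The ± values are 95% confidence half-widths over 100 bootstrap resamples of
the held-out test knees. Comparing `--feature profile` against
`--feature min` on a cohort whose narrowing includes the lateral compartment
shows the central point of the package: multi-point profiles out-predict the
single minimum-JSW, which is blind to everything outside the medial window.

The same operations are available as a library:

```python
from kneejsw import (PhantomSpec, make_phantom, extract_margins,
                     build_frame, multi_jsw, min_jsw, SamplingGrid)

radiograph, mask, truth = make_phantom(PhantomSpec(seed=3))
femur, tibia = extract_margins(mask)
frame = build_frame(tibia, "right", row_mm=0.2, col_mm=0.2)
profile = multi_jsw(femur, tibia, frame, SamplingGrid(n_points=64))
minimum = min_jsw(femur, tibia, frame)
```

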