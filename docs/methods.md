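# Methods

## The screening problem

Type II diabetes alters tongue thermal physiology: reduced salivary
secretion (xerostomia) weakens evaporative cooling, so the diabetic tongue
surface runs warmer — reported group means are 35.23 ± 0.61 °C versus
34.62 ± 0.77 °C at a fixed centre region of interest — and the heat
concentrates at the tongue centre while the discrete cold spots visible on
healthy tongues disappear. A thermogram rendered under a rainbow palette
makes these differences visible as colour components: hot spots render red,
midrange tissue green/yellow, cold regions blue. The pipeline quantifies
them (temperature at a fixed ROI, texture of the hot-spot component) and
feeds them to standard classifiers.

The clinical recordings behind those numbers are not distributable, so the
package includes a synthetic generator that reproduces the published
statistical and morphological structure. Everything downstream of the
generator treats its output exactly as it would treat real data.

## Synthetic cohort model

**Tabular records.** Each group's 15 variables (age, height, weight, BMI,
SpO2, core temperature, waist, hip, SBP, DBP, HbA1c, FBS, PPBS, EAG, tongue
surface temperature) are Gaussian with the published group mean/SD. Joint
structure is a Gaussian copula: the published diabetic-group correlation
matrix over nine variables (the only dependence information available) is
repaired to the nearest positive-definite matrix by eigenvalue clipping
(floor 1e-8, rescaled to unit diagonal), Cholesky-factored, and applied to
both groups; variables outside that subset are independent. Draws are
clipped to physical ranges (SpO2 ≤ 100%, temperatures within 20–42 °C,
everything else non-negative); at the published parameters clipping is at
least 2.5 SDs out and shifts no mean by more than ~0.002 SD.

Only a correlation matrix for the *diabetic* group was published; applying
the same copula to the normal group is an assumption, made because no
information supports a different one.

**Diagnostic-label consistency.** The published diabetic HbA1c margin
(8.58 ± 2.30%) places ≈18% of its mass below the 6.5% diagnostic cut, so
marginal fidelity and label consistency are mutually exclusive. The
default samples the margins as published; `consistent_labels=True`
truncates the HbA1c margin at the cut (diabetic ≥ 6.5, normal ≤ 6.4) via
the truncated-normal quantile of the same copula uniform, which preserves
the dependence but raises the diabetic HbA1c mean to ≈9.3.

**Pooled HbA1c–temperature association.** The published pooled-cohort
r² = 0.5688 (r ≈ 0.754) is unreachable from the published group margins:
with equal group sizes the between-group mean offsets plus any within-group
correlation ≤ 1 cap the pooled r² near 0.51, and it is also inconsistent
with the published diabetic-only r = 0.662 (0.662² = 0.438). The package
therefore exposes both configurations: the copula cohort reproduces the
within-group correlation, and a separate pooled mode
(`sample_pooled_hba1c_tst`) draws HbA1c from the two-group mixture and
models temperature as a linear response, t = μ_t + β(h − μ_h) + ε, with
β = r·σ_t/σ_h and Var(ε) = (1−r²)σ_t² computed from the mixture moments, so
the population correlation equals the configured target exactly while the
pooled temperature mean and SD match the mixture.

**Temperature fields.** A field is an elliptical tongue (default semi-axes
0.76/0.60 of the half-frame) over an ambient background of 22.5 °C with
pixel noise (SD 0.08 °C). Inside the tongue the base profile is
T(r) = TST − d·r², where r is the normalized elliptical radius and d the
centre-to-margin cooling. The presets encode the group morphology:

| parameter          | diabetic | normal | unit | rationale                      |
|--------------------|---------:|-------:|------|--------------------------------|
| hot spots          | 1 (centre) | 3 (scattered) | — | centre-concentrated vs diffuse |
| hot-spot amplitude | +1.5 | +1.5 | °C | moderate local hyperthermia    |
| hot-spot σ         | 0.12 | 0.08 | frame fraction | broad centre plume vs spots |
| cold spots         | 0 | 2 | — | cold spots absent in diabetics |
| cold-spot amplitude| — | −1.5 | °C | relative to local base         |
| margin cooling d   | 1.5 | 6.0 | °C | dry tongue stays warm; moist margins cool toward ambient |

The margin-cooling term is what makes normal tongues show blue components
under the fixed palette scale: a −1.5 °C spot on an otherwise warm tongue
stays in the green band, so the cold/blue morphology requires genuinely
cool peripheral tissue, which is physically what a moist extended tongue
does. After assembly the whole in-tongue field is shifted by a constant so
the centre-ROI mean equals the record's tongue temperature exactly —
measurement at the ROI is then consistent with the tabular record by
construction.

**What the generator does not emulate**: camera optics and noise spectra,
anatomically realistic tongue contours, coating artefacts, longitudinal
physiology. Tests passing on synthetic data show the *pipeline* is correct
and that the published group structure is recoverable; they do not show
real-data accuracy. In particular the published classifier accuracies
(92.85/89.28/94.28%) were measured on the restricted clinical images and
are not claimable here; the pipeline property asserted on synthetic data is
a weaker ≥85% cross-validated linear-SVM accuracy bound.

## Palette and scale

The default palette is a 256-entry HSV sweep from blue (hue 240°) to red
(hue 0°) at full saturation — a documented stand-in for the camera vendor's
proprietary rainbow — with two calibrated choices:

* **peak channel value 252**, because the calibrated red-component
  threshold interval is R ∈ [222, 252]: a palette peaking at 255 could
  never produce a red-component pixel;
* **scale 30–36 °C**, because under a wider scale (e.g. 28–38 °C) tongue
  temperatures of 33–37 °C render entirely green-to-orange: no pixel would
  reach the red band (top ≈17% of the scale) or the blue band (bottom
  ≈16%), and the red-hot-spot / blue-cold-spot morphology the segmentation
  is built on would vanish.

Both are configurable; inversion maps each pixel to the bin midpoint of the
nearest entry in RGB Euclidean distance (round-trip error ≤ half a
quantization step, (t_max−t_min)/512 ≈ 0.012 °C). The 10×12 mm physical
ROI corresponds to 40×48 px at the 256×256 working size (0.25 mm/px); the
true pixel pitch of the 0.3 m acquisition is unpublished, so this is an
explicit configuration value.

## Segmentation conventions

A pixel belongs to a colour component when each channel lies inside that
component's inclusive [min, max] interval. Components are non-exclusive
(the calibrated green row overlaps the red row for some pixels); for
visualization the precedence is red > green > blue. An optional white rule
(all channels ≥ 240), seen in published figures but absent from the
threshold table, is off by default. Grayscale conversion uses Rec. 601
luma (0.2989, 0.5870, 0.1140) rounded to nearest integer, with non-red
pixels zeroed; if the red component is empty the conversion falls back to
the whole image with a warning. The tongue is localized for ROI placement
as the above-background region of the inverted field (> t_min + 0.5 °C) —
more stable than a colour-component centroid, which scattered warm spots
drag off-centre. ROI placement rounds ties toward the top-left and clamps
to the frame.

## Texture features

GLCM defaults: 8 gray levels (uniform binning of [0, 255]), offset (0, 1),
symmetric, normalized — the common co-occurrence convention; all exposed in
`GLCMConfig`. Features follow the standard forms; two conventions need
stating:

* **Entropy** defaults to Shannon −Σ P ln P over nonzero cells. The
  unweighted form Σ −ln P (available as `literal=True`) diverges on zero
  cells and is computed over nonzero cells only.
* **Skewness/kurtosis** are population moment ratios of the ROI pixel
  intensities (divide by n; kurtosis of a Gaussian is 3, no excess
  subtraction).

The reference study's printed feature scales (entropy ≈ 41–46, kurtosis ≈
0.01–0.02) cannot be reconciled with these formulas under any standard
normalization and are not targeted. Likewise its GLCM standard deviation is
higher in diabetics (79.91 vs 47.75 on its own gray scale), whereas the
synthetic morphology induces the opposite direction (the red-masked
diabetic ROI is nearly uniform; the normal ROI mixes zeros and warm spots).
Texture differences here are induced by morphology, not injected, so only
their stability — not their clinical direction or magnitude — is asserted.
Degenerate ROIs (zero variance) yield NaN with an explicit flag set
(`TextureFeatures.degenerate`), never silent zeros; the classifier feature
assembly maps flagged values to 0.

## Statistics

"Student's t-test" is the equal-variance pooled test (the common
statistical-package default reading), Welch behind a flag. Kruskal–Wallis
is implemented for k ≥ 2 groups (with two groups it reduces to the
rank-sum comparison actually applied). Raw p-values are reported with no
multiplicity correction, matching the source convention; Bonferroni/BH are
available but off by default. All tests delegate to `scipy.stats`.

## Classification

SVM: soft-margin linear kernel, C = 1.0, z-score standardization fitted
inside each training fold. NB: Gaussian class-conditionals with variance
smoothing 1e-9 × the largest feature variance; an all-constant feature
matrix degrades to the prior distribution with a logged warning.
Cross-validation is stratified 10-fold with a seeded shuffle; held-out
predictions are pooled into a single confusion matrix (hold-out evaluation
is available but pooled-CV is the default, as the single published
confusion matrix per classifier is most consistent with pooling).
Percentages are truncated (not rounded) to two decimals — this is what
reproduces the published 92.85 = ⌊130/140 × 10⁴⌋/100 — with rounding mode
exposed. ROC is a threshold sweep over distinct scores with trapezoidal
AUC (equal to the tie-averaged Mann–Whitney statistic).

The CNN is a from-scratch NumPy implementation of the VGG topology:
blocks of 3×3 same-padding convolutions + ReLU ending in 2×2 max pooling,
a dense ReLU layer and a softmax head, trained by plain SGD at learning
rate 0.01 on cross-entropy with shear/zoom/rotation/flip/translation
augmentation of training batches. The default is a down-scaled two-block
variant for CPU-scale experiments; `CNNConfig.vgg16()` builds the full
five-block, thirteen-convolution topology. Inputs are z-scored with
training-set statistics (required for plain SGD at this rate to move the
zero-initialized head). The head's zero weights and prior-matched bias
make an untrained network predict the empirical priors. No pretrained
weights are bundled; the `pretrained` flag raises an informative error.

## Numerical choices and problem sizes

Metric percentages are computed with exact rational arithmetic before
truncation, so printed-precision comparisons are float-safe. Nearest-PD
repair uses eigenvalue clipping at 1e-8. Seeds: every sampling function
takes one integer seed; multi-subject operations spawn per-subject child
seeds from a `SeedSequence`, so outputs are bitwise reproducible and
insensitive to subject order. The test suite and the acceptance script use
desk-scale problem sizes chosen to estimate each quantity well inside its
tolerance: 100–200 seeds for generator-recovery means, 5,000 replicates
for type-I-error calibration, 140-subject cohorts at 256×256 for the
pipeline property, and 96×96 fields for the bulk ROI-temperature
measurement (the ROI mean is exact by construction at any frame size).

## Known limitations

* The published correlation table's header and row labels disagree; row
  labels were taken as authoritative, and the matrix (as printed) is not
  positive definite, hence the repair step.
* The published pooled r², diabetic-only r, percentage temperature
  difference (2.35%), SVM PPV cell, and texture-feature scales are mutually
  or internally inconsistent; each is either reproduced from the printed
  inputs, configurable, or explicitly flagged — none is silently adjusted.
* Palette inversion assumes the rendering palette is known; foreign images
  under unknown palettes invert only approximately.
* The synthetic morphology is a two-preset caricature; real tongue
  thermograms vary continuously and include coating and motion artefacts.
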