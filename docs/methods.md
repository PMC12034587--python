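# Methods

## Problem and data model

The package predicts a binary one-year outcome (stroke, myocardial
infarction, or DWI-hyperintense lesion) after carotid endarterectomy from
two modalities: whole-slide images of the resected, H&E-stained plaque, and
an 18-variable clinical record. The design assumption throughout is that
event-associated histology (plaque hemorrhage, mural thrombus, lymphocytic
infiltration, hemosiderin deposition) is *rare in event-free patients*, so a
generative model trained only on event-free tissue will reconstruct it
poorly, and reconstruction error is a usable risk signal without any lesion
annotation.

Slides are treated as single-level RGB images; pyramid handling is an I/O
concern outside the method, so the segmentation stage takes an explicit
downsample factor instead of a pyramid level.

## Preprocessing

`segment_tissue` runs a fixed pipeline: block-average downsample (default
factor 32) → HSV conversion → saturation channel → median filter → Otsu
binarization → binary closing → contour extraction. Saturation is used
because eosin/hematoxylin staining saturates tissue while the scanner
background and section holes are near-white and unsaturated. Otsu's
threshold is computed on the 256-bin saturation histogram as the split
maximizing between-class variance, taking the smallest maximizing index on
ties (flat plateaus occur in bimodal histograms with empty mid-bins).

Defaults that the pipeline exposes but that are choices, not constraints:
median kernel 7 px and closing kernel 5 px at the downsampled level; minimum
tissue-component area 512 px and minimum hole area 256 px at downsample 32
(holes below the minimum are absorbed into tissue). A hole is an enclosed
background region inside a tissue component; nested islands of tissue inside
holes are not modelled (they do not occur in plaque sections at this scale).

`extract_patch_grid` tiles the slide from (0, 0) at stride = patch size
(256 px defaults). A window is kept when its area-weighted tissue fraction
on the coarse mask is at least `min_tissue_fraction` (default 0.5 — an
exposed inclusion rule). Edge windows are discarded rather than padded so
every patch has full pixel content; the fraction is computed with exact
integer cell overlaps, so it equals the fraction on a full-resolution
upsampled mask.

## Anomaly models

Inputs are scaled to [0, 1]; the decoder/generator ends in a sigmoid, which
both fixes the output range and bounds the autoencoder score of any
in-range input by 1.

**Autoencoder (primary).** Encoder: three 3×3 stride-1 conv layers, each
with ReLU and 2×2 max pooling, with doubling channel widths ending at 128
(default 32→64→128); the final feature map is flattened and projected to a
512-dimensional latent code. Decoder: a dense layer back to the feature-map
size, then three transposed convolutions (kernel 2, stride 2 — chosen so
upsampling blocks do not overlap and checkerboard artifacts cannot arise),
the first two with ReLU and the last with a sigmoid. Training minimizes
reconstruction MSE with Adam at learning rate 1e-3, batch size 64, up to 300
epochs with early stopping (patience 30); all of these are the default
training profile and are configurable. Patches labelled anomalous are
rejected from training sets outright — a leakage guard, since the score is
only meaningful when the model has seen normal tissue only.

The per-patch score is the MSE over every pixel-channel entry, and the
per-patient pathological risk score is the plain mean over all of the
patient's patches, pooled across slides before averaging (a patient can
contribute several slides; the score is defined per patient, and pooling
weights every patch equally rather than every slide).

**f-AnoGAN (optional izif variant).** Phase 1 trains a Wasserstein GAN
(RMSprop, learning rate 5e-5, 5 critic steps per generator step, latent
dimension 1024 by default). The critic's Lipschitz constraint is enforced by
weight clipping; the engine below is a minimal reverse-mode implementation
without the double backpropagation that an exact gradient-penalty term
requires, and at desk scale clipping trains comparably. Generator
checkpoints are taken periodically and the one with the lowest Fréchet
distance between embeddings of real and generated training images is kept
(argmin, first on ties). The embedding behind that distance is a fixed
seeded projection of 8×8 block-averaged images — a lightweight extractor
behind an interface; the selection logic is the tested component, and the
extractor can be swapped. Phase 2 trains an encoder into the frozen
generator's latent space with the izif objective (image residual plus
critic-feature residual, feature weight 1.0 and exposed in config),
stopping after 30 epochs without improvement. Training the encoder before
the GAN is an error.

**Engine.** Both models run on a small numpy NN engine written for this
package (conv / transposed-conv / pool / dense, Adam and RMSprop), float32,
fully deterministic under a seed; every backward pass is verified against
central finite differences in the test suite.

## Classification and evaluation protocol

Missing clinical cells are imputed with the column mean of observed values
(indicator columns included — their imputed value is the observed
prevalence). The feature matrix is the 18 clinical variables plus the risk
score; gradient-boosting backends (XGBoost, LightGBM) sit behind one
interface.

Each evaluation repetition, seeded as base_seed + i:

1. class-stratified patient-level split with train size round-half-up(0.7 N)
   (71 patients → 50 train / 21 test); per-class counts are rounded the same
   way and reconciled on the larger class;
2. grid search over a small default grid (depth {2,4} × learning rate
   {0.1,0.3} × 50 trees) by mean log loss over 5 stratified CV folds, argmin
   with first-wins ties, refit on the full training set;
3. Youden-index threshold on *out-of-fold* training predictions — in-sample
   boosted-tree probabilities are nearly 0/1 and would push the threshold to
   a degenerate corner; candidate thresholds are midpoints of consecutive
   distinct scores plus ±∞ sentinels, ties broken toward the higher
   threshold (higher specificity);
4. test-set ROC-AUC (rank concordance, ties 0.5), accuracy, sensitivity,
   specificity, F1 at that threshold.

Aggregation over 100 repetitions reports mean ± 1.96·sd/√n per metric as the
95% CI. A repetition whose split fails class-presence preconditions is
redrawn from a disjoint seed stream and the substitution recorded.
Train/test disjointness is asserted in every repetition. The anomaly model
is trained once, outside the repetition loop, on patients never used in
classification — retraining it per split would multiply cost without
changing what the protocol measures.

## Synthetic data: what it emulates and what it does not

`generate_slide` renders pink tissue discs (RGB ≈ (230, 160, 190) ± Gaussian
noise, sd 6 by default) on a near-white background (245, 245, 245), with
background-colored holes and textured lesions, returning exact tissue and
lesion masks (lesions are always inside tissue). Three parametric lesion
textures stand in for the pathologies of interest: `hemorrhage_like` (solid
dark-red fill), `infiltrate_like` (fields of small dark dots at ~40% cover),
`deposit_like` (brown granules at ~45% cover). Contrasts are free
parameters, not calibrated to any cohort — the real visual contrast of
plaque pathology is unquantified — so passing benchmarks show the pipeline
is *correct and sensitive to localized texture change*, not that it reaches
any particular accuracy on clinical material. Real-slide properties that are
deliberately absent: stain variation, pen marks and scanner artifacts,
tissue folds, pyramid levels, photorealistic texture.

`generate_clinical_table` draws the 18 variables class-conditionally from
the cohort's published summary statistics (normal vs abnormal means/
proportions), with optional extra per-feature effect shifts and MCAR
missingness (default cohort sizes 50/21, the classification set). Tables
use the cohort's variable names verbatim as column headers so the synthetic
path and a real-data CSV are interchangeable.

## Desk-scale profiles and problem sizes

Full-profile defaults (256-px patches, 512-dim latent, 300 epochs) match
the intended application scale. Tests and the acceptance script use a desk
profile chosen as the package's own benchmark configuration: 64-px patches,
8→16→32 channels, 128-dim latent, 30 epochs on 500 normal patches, which
trains in about a minute on one CPU and separates held-out lesion patches
from normal ones at ranking AUC ≥ 0.90 (in practice ≈ 1.0). The f-AnoGAN
desk profile uses 32-px patches and a 32-dim latent. Patient-level
benchmarks use 20 patches per patient with 6 lesion patches per abnormal
patient — roughly a 30% lesion burden, a plausible fraction of abnormal
tissue in an unstable plaque.

## Numerical choices

- Otsu ties → smallest index; degenerate single-bin histogram → that bin.
- Patch tissue fractions are exact rationals (integer overlaps / patch
  area); the ≥ comparison with the inclusion threshold is therefore stable.
- Scores are accumulated in float64 even though model weights are float32.
- Grid-search and checkpoint argmins take the first minimizer; the Youden
  threshold takes the *largest* maximizing threshold.
- Heat maps take the max when two patch footprints overlap a mask cell
  (possible when patch size is not a multiple of the downsample factor),
  and normalize by a cohort-wide range when one is provided, per-slide
  otherwise; degenerate ranges (all scores equal) render scored tissue at
  full brightness.

## Known limitations

- Headline clinical metrics of the motivating study are not reproducible
  here: the cohort is private, and synthetic benchmarks are easier than
  clinical material (results on the synthetic cohort are near-ceiling).
- The WGAN critic uses weight clipping rather than an exact gradient
  penalty (see above); the izif encoder-loss weighting is exposed rather
  than fixed, as reference formulations differ.
- Contour hierarchy handles tissue-with-holes, not deeper nesting.
- Single-level images only; gigapixel pyramidal I/O is out of scope.
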