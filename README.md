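# plaqrisk

Prediction of cardiovascular events within one year after carotid
endarterectomy (CEA) from whole-slide pathology images of the resected
plaque combined with clinical data.

After CEA, a minority of patients go on to have a stroke, a myocardial
infarction, or an asymptomatic DWI-hyperintense lesion within a year, and no
single clinical variable predicts who. This package implements a two-step
method for that problem, aimed at researchers working with digitized H&E
plaque sections and tabular clinical records:

1. **Pathological risk score.** Tissue is segmented from each slide
   (32× downsample → HSV saturation → median filter → Otsu threshold →
   morphological closing → tissue/hole contours), tiled into 256×256
   patches, and scored by a reconstruction-based anomaly detector trained
   **only on patches from event-free patients**. The primary detector is a
   convolutional autoencoder (3 conv+ReLU+max-pool stages → 512-dim latent →
   3 transposed-conv stages, sigmoid output) with per-patch score

   A(x) = ‖x − D(E(x))‖² / n,

   the mean squared reconstruction error over all n pixel-channel entries.
   An izif-style f-AnoGAN is available as an alternative, scoring

   A(x) = ‖x − G(E(x))‖²/n + ‖f(x) − f(G(E(x)))‖²/n_d,

   where f(·) is the critic's penultimate feature map. The per-patient
   **pathological risk score** pools every patch of every slide of patient p:

   A_p = Σ_{x∈X} A(x) / |X|.

2. **Multimodal classification.** A_p is appended to 18 clinical variables
   (age, sex, stenosis rate, NIHSS, MPRAGE grade, smoking, comorbidities,
   medications; missing cells mean-imputed) and a gradient-boosted tree
   classifier (XGBoost or LightGBM) predicts the binary outcome from the 19
   features. Evaluation follows a strict repeated protocol: 100 stratified
   patient-level 7:3 splits, 5-fold cross-validated grid search minimizing
   log loss on each training set, an operating threshold chosen by the
   Youden index (J = sensitivity + specificity − 1) on out-of-fold training
   predictions, and test-set ROC-AUC / accuracy / sensitivity / specificity /
   F1 aggregated as mean with normal-approximation 95% CIs.

Per-patch scores can also be rendered as anomaly heat maps (brightness
increases with score, non-tissue black) to show *where* in the plaque the
model sees abnormality — hemorrhage, infiltrates, deposits.

No patient data ships with the package. A first-class synthetic module
generates H&E-like slides with exact tissue/hole/lesion ground truth, patch
banks, and clinical tables with the cohort's class-conditional statistics,
so the whole pipeline is testable end to end.

## Worked example

```bash
# one synthetic slide (2 lesions) plus a clinical table
plaqrisk simulate --out-dir demo --seed 5 --n-slides 1 --lesions 2 --clinical

# segment tissue, extract the patch grid
plaqrisk segment demo/slide_000.png --out-prefix demo/seg --downsample 8 \
    --min-tissue-area 64 --min-hole-area 16
# -> otsu threshold 40; 1 tissue / 0 hole contours

# train a desk-scale autoencoder on synthetic normal patches, then score
plaqrisk train-ae --out demo/ae --seed 2 --n-patches 500 --epochs 30
plaqrisk score demo/slide_000.png demo/ae --out-csv demo/scores.csv --patient-id P1
# -> 88 patches scored -> demo/scores.csv
plaqrisk risk demo/scores.csv --out-csv demo/risk.csv
plaqrisk heatmap demo/slide_000.png demo/ae --out-png demo/heat.png
```

`demo/risk.csv` then holds one row per patient, e.g.
`P1,88,0.0936...`: patient P1 had 88 tissue patches with mean anomaly score
(pathological risk score A_p) ≈ 0.094 — high for this model, whose normal
patches reconstruct to ≈ 0.012, because the slide contains lesions. The heat
map brightens exactly over the lesion footprints.

The same objects are available as a library:

```python
from plaqrisk import (SlideGenConfig, generate_patch_bank, AutoencoderSpec,
                      TrainConfig, train_autoencoder, score_patches)

bank = generate_patch_bank(SlideGenConfig(seed=7), 500, 0, patch_px=64)
spec = AutoencoderSpec(input_px=64, channels=(8, 16, 32), latent_dim=128)
model, losses = train_autoencoder(bank, spec, TrainConfig(epochs=30, seed=1))
```

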