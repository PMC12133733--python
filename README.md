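# dualcmnet

Lightweight dual-branch fusion of hyperspectral reflectance and RGB kernel
images for maize seed variety classification.

Maize varieties are hard to tell apart from either modality alone: kernel
images capture morphology (length, width, coat colour) but confuse
similar-looking varieties, while full-range reflectance spectra
(350–2500 nm, 2151 points) capture composition (protein, fat, starch) but
overlap for compositionally similar varieties. This package implements a
dual-branch classifier that fuses both:

- **Spectral branch** — a 1-D CNN (three conv blocks of 16/32/64 channels,
  each conv → batch norm → ReLU → max-pool) over Savitzky–Golay-smoothed
  spectra; ≈0.28 M parameters.
- **Spatial branch** — MobileNetV3-Small over 224×224 single-kernel images
  with a 1024-d feature tap; ≈1.53 M parameters, ≈0.06 GMACs.
- **Fusion core** — each branch feature `X ∈ ℝ^d` is mapped to a common
  384-d space by a two-stage *HShuffleBlock*: grouped affine maps
  (`g = 8` groups, a g-fold parameter reduction) followed by channel
  shuffling (reshape to `(g, d/g)`, transpose, flatten), batch norm, and
  ReLU: `ℝ^d → ℝ^512 → ℝ^384`. Both 384-d features pass through CBAM
  (channel-then-spatial sigmoid attention) and are merged by a scalar
  learned gate `g ∈ [0,1]`:

  ```
  fused = g · (F_s ⊙ F_r) + (1 − g) · (F_s + F_r)
  ```

  The assembled model stays ≤ 2.53 M parameters.
- **Protocol** — category-matched pairing (each image paired with a random
  same-variety spectrum), stratified 5-fold cross-validation, and staged
  training: pretrained branches frozen for 14 epochs while fusion layers
  train at Adam LR 1e-3; from epoch 15 everything is unfrozen at 0.05×
  (branches) and 0.1× (fusion) of the base rate.

Everything runs on NumPy with hand-written backpropagation — no deep
learning framework needed. A synthetic data generator emulates the study
conditions (11 varieties with published morphology/composition, spectral
differences confined to 1400–1600 and 2000–2300 nm) so the whole pipeline
is testable end to end, including a watershed segmentation stage that
splits multi-kernel board images into single-kernel crops.

## Worked example

```python
from dualcmnet.pipeline import run_synthetic_study

result = run_synthetic_study(seed=1)
print(f"spectral branch accuracy: {result['spectral_accuracy']:.3f}")
print(f"spatial branch accuracy:  {result['spatial_accuracy']:.3f}")
print(f"fused model accuracy:     {result['fused_accuracy']:.3f}")
```

prints (a few minutes on one CPU core):

```
spectral branch accuracy: 0.909
spatial branch accuracy:  0.255
fused model accuracy:     1.000
```

This is the desk-scale study: 11 varieties × 50 image/spectrum pairs, 96-px
kernel crops, short pretraining budgets. The spectral branch separates most
varieties through their composition signatures; the spatial branch is
limited by genuinely overlapping morphology (several varieties share nearly
identical size and colour); the fused model combines both and classifies
the validation fold perfectly. `result["history"]` records per-epoch loss,
validation accuracy, the per-group learning rates, and a digest of the
branch weights (constant during the frozen phase).

The CLI mirrors the library:

```
dualcmnet gen-data --out-dir data --images-per-class 50 --scene-kernels 100
dualcmnet smooth --input data/spectra.csv --output data/smoothed.csv
dualcmnet segment --image data/scene.png --out-dir data/crops
dualcmnet make-folds --spectra-csv data/spectra.csv --images-dir data/images --out folds.csv
dualcmnet count --model spatial
```

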