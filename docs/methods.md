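# Methods

## Model

The classifier fuses two modalities of a maize kernel sample:

**Spectral branch.** Reflectance spectra live on a fixed 350–2500 nm grid
(1 nm steps, 2151 points). After Savitzky–Golay smoothing (window 11,
polynomial order 3 — the common chemometrics default, wide enough to
denoise but narrower than the ~50–100 nm absorption features), spectra pass
through a 1-D CNN: three blocks of conv(k=3, length-preserving padding) →
batch norm → ReLU → max-pool, with channels 16/32/64, pool factors 2/2/4
(lengths 2151 → 1075 → 537 → 134, floor semantics), and dropout 0.2 after
the first pool. The flattened 64×134 = 8576-d map is the branch's feature
tap; a head of FC(8576→32) → ReLU → dropout 0.5 → FC(32→11) is used only
for pretraining. Kernel size, pool factors, FC width and dropout rates are
free design parameters; this combination puts the full branch at 282,779
trainable parameters (0.28 M at two decimals) and the spatial ladder above
keeps the fused assembly within its budget.

**Spatial branch.** MobileNetV3-Small in its canonical small configuration:
3×3 stem at stride 2 (16 ch, hard-swish), eleven inverted-residual
bottlenecks (kernel 3 or 5; expansion 16–576; squeeze-excitation on all but
bottlenecks 2–3; ReLU in the first three, hard-swish after; strides
reproducing 224 → 112 → 56 → 28 → 28 → 14 → … → 7), a 1×1 conv to 576,
adaptive average pooling, and FC(576→1024) with hard-swish as the feature
tap, plus an FC(1024→11) pretraining head. With the 11-class head this is
1,529,131 parameters (1.53 M) and ≈0.0555 GMACs at 224×224. The network is
fully convolutional up to the pool, so smaller inputs are accepted; the
scaled-down studies below use 96×96.

**HShuffleBlock.** Each branch feature is aligned to a 384-d common space
in two stages: grouped affine map (g = 8 contiguous groups, each with its
own weight matrix and bias; d₁·d₂/g + d₂ parameters instead of d₁·d₂) →
channel shuffle (reshape to (g, d/g), transpose, flatten — a fixed
permutation that redistributes information across groups) → batch norm →
ReLU, mapping d → 512 → 384. The shuffle is applied after the affine map,
the standard ordering in channel-shuffle networks.

**CBAM.** Channel attention pools the feature map globally (average and max
in parallel), passes both statistics through a shared bias-free MLP
(C → C/r → C, ReLU between, r = 16), and gates channels with the sigmoid of
the summed responses. Spatial attention concatenates the channel-wise mean
and max maps and gates positions with a sigmoid-activated 7×7 convolution.
The 384-d transformed features are treated as 384 channels of 1×1 spatial
extent by default, so channel attention is fully active while spatial
attention degenerates to a single sigmoid scalar; it is kept for
architectural fidelity, and a config option (`CBAMConfig.reshape`) can fold
the vector to e.g. 24×4×4 to give spatial attention real extent.

**Gated fusion.** The two attended 384-d features are concatenated and fed
to a 768 → 48 → 1 MLP (ReLU, dropout 0.2 between the layers); the sigmoid
output g weighs a convex combination of the elementwise product (cross-modal
interaction) and the elementwise sum (modality preservation):
fused = g·(F_s⊙F_r) + (1−g)·(F_s+F_r). Every fused coordinate therefore
lies between the two pure strategies. A dropout-0.2 → FC(384→11) head
classifies. The assembled fused model (branch backbones + two
HShuffleBlocks + two CBAMs + gate + head, pretraining heads excluded
because the feature taps bypass them) holds 2,272,994 parameters, within
the 2.53 M budget.

## Training protocol

Images are paired with spectra by category matching: for each image a
spectrum of the same variety is drawn uniformly with replacement (the
modalities are never physically aligned, and the real setting has fewer
spectra than images). Pairing is fixed per run so the stratified 5-fold
splits are well defined; per-epoch re-pairing is available as an option.
Training images get random 224-crop + horizontal flip (p = 0.5), validation
images a centre crop, both followed by standard natural-image channel
normalisation; the constants are recorded with every checkpoint.

The fused model trains with Adam (base LR 1e-3, weight decay 1e-4, batch
32, cross-entropy). Epochs 1–14: branch parameters frozen (gradients off —
a freeze and a non-zero learning rate cannot both hold, so the staged
multipliers apply only after unfreezing), fusion layers (HShuffleBlocks,
CBAM, gate, head) at the base rate. From epoch 15: everything unfrozen,
branches at 0.05×, fusion at 0.1× the base rate. Validation runs after
every epoch and the highest-accuracy state is checkpointed. Epochs are
1-based; the unfreeze happens at the start of epoch 15.

Parameter counts are exact sums over trainable tensors. The MAC counter is
analytic — one multiply-add per conv/affine multiply, elementwise, batch
norm and pooling ops excluded — the convention under which
MobileNetV3-Small at 224×224 costs ≈0.06 G.

## Synthetic data

The generator emulates the acquisition, not the optics:

- **Spectra**: a monotone-safe cubic (PCHIP) base curve through the
  characteristic peak (863/1105/1295/1680/2015 nm) and valley
  (980/1175/1450/1780/1915 nm) anchors, endpoints (350, 0.15) and
  (2500, 0.10), and one shape anchor at 1850 nm so both the 1780 and
  1915 nm valleys are genuine local minima; anchor heights are free
  parameters forming a plausible concave reflectance profile. Per class, up
  to three Gaussian bumps (σ 20–45 nm) are added whose centres are drawn
  once per class inside the discriminative windows 1400–1600 nm (one bump)
  and 2000–2300 nm (two bumps) and whose amplitudes are
  `class_effect_scale` × the z-scored protein/fat/starch content of the
  variety; bumps are zeroed outside their window so class variance is
  strictly confined to the stated bands. I.i.d. Gaussian noise
  (default sd 0.01 reflectance units — on the order of bench-top
  repeatability) is added and values clipped to [0, 1].
- **Kernel images**: one speckled ellipse per image on a black background,
  axes drawn from the variety's published length/width mean ± sd, scaled at
  8 px/mm on a 256-px canvas (configurable), random orientation, fill
  colour near a yellow (225,185,60) or orange (230,130,40) reference with
  per-kernel jitter sd 10 and per-pixel speckle sd 8.
- **Scenes**: n kernels on a jittered square grid (emulating kernels
  arranged in regular groups on the acquisition board) at 6 px/mm on a
  1024-px canvas — grid placement guarantees pairwise-disjoint bounding
  boxes at 100-kernel density, where naive rejection sampling cannot
  terminate; a placement error is raised when the grid cell cannot contain
  a kernel.

What the generator does *not* emulate: radiometric instrument response,
scattering baselines, kernel texture (crown dents, tip caps), shadows,
specular highlights, or background boards other than near-black. Passing
tests therefore demonstrate that the pipeline is mechanically and
statistically sound under controlled conditions, not that the reported
real-data accuracies transfer.

## Desk-scale study sizes

The end-to-end study (`dualcmnet.pipeline.run_synthetic_study`) uses 11
varieties × 50 image/spectrum pairs, kernels on a 128-px canvas at 6 px/mm
cropped to 96×96, full-length spectra, strong class separation
(`class_effect_scale` 0.2, noise sd 0.01), and one stratified fold (440
train / 110 validation pairs). Branch pretraining budgets are deliberately
small — 15 epochs at LR 1e-4 for the spectral branch, 6 epochs at LR 3e-3
without augmentation for the spatial branch — and fusion training runs 15
epochs (14 frozen + 1 fine-tune) with augmentation off, which lets the
frozen-phase branch features be computed once and cached. Under these
conditions the spectral branch typically reaches ≈0.9–1.0, the spatial
branch ≈0.2–0.3 (several varieties share nearly identical published
morphology and colour, so the image-only problem has a low ceiling — the
same complementarity argument that motivates fusion), and the fused model
reaches ≥0.95.

Two numerical/pipeline choices matter here. Spectra are mean-centred with
the training-fold mean before the 1-D CNN (the standard chemometric
centring step); without it the shared reflectance curve dominates the
batch-norm statistics, conditioning is poor, and the branch head is prone
to dead-ReLU collapse under Adam. And while branches are frozen they are
run in inference mode (fixed normalisation statistics, no dropout), the
usual convention for frozen backbones, which is also what makes the
feature cache exact.

## Numerical choices and limitations

- All layers and backpropagation are implemented on NumPy (float32 by
  default, dtype-agnostic); gradients of every layer and of the composed
  fusion stack are verified against central finite differences in float64.
- Argmax ties in prediction break to the lowest class index; macro
  precision/recall/F1 treat empty denominators as 0.
- Batch norm uses eps 1e-5, momentum 0.1, biased batch variance for
  normalisation and unbiased updates for the running estimate.
- Otsu thresholding operates on the 8-bit histogram of the standard-luma
  grayscale; the watershed floods the negated distance transform from
  markers at distance > 0.5 × max, restricted to the opened mask. Regions
  under 50 px are discarded; crops are padded by 5 px and clipped.
- The depthwise/1×1 convolution fast paths avoid im2col materialisation;
  the general path builds patch tensors per tap.
- Single-process, CPU-only; no attempt at GPU or multi-threaded training.
- The comparison-model zoo, alternative attention modules, and the
  hyperparameter-sweep accuracies are out of scope; the config surface
  supports the sweeps but their reported numbers depend on the unreleased
  real dataset.
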