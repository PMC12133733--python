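"""End-to-end synthetic study: generate data, pretrain both branches, run
staged fusion training, and report accuracies.

This is the desk-scale counterpart of the full experimental protocol: 11
varieties, 50 image/spectrum pairs per variety, kernels rendered on a
128 px canvas at 6 px/mm and cropped to 96x96 (the spatial branch is fully
convolutional, so the reference 224 resolution is not required), spectra at
the full 2151 points with strong class separation.  Branch pretraining
budgets are deliberately small; the staged fusion schedule keeps the
published shape (freeze for 14 epochs, unfreeze with 0.05x/0.1x learning
rates at epoch 15).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .fusion import build_dualcmnet
from .pairing import pair_by_category, stratified_kfold_split
from .preprocess import center_spectra, sg_smooth
from .spatial import build_spatial_net
from .spectral import build_spectral_net
from .synthetic import SyntheticConfig, gen_kernel_images, gen_spectra, \
    spectra_to_arrays
from .training import TrainConfig, evaluate, fit_branch, staged_fit

#: scaled-down study conditions (see module docstring)
STUDY = dict(
    n_per_class=50,
    noise_sd=0.01,
    class_effect_scale=0.2,
    canvas_px=128,
    px_per_mm=6.0,
    image_size=96,
    spectral_epochs=15,
    spectral_lr=1e-4,
    spatial_epochs=6,
    spatial_lr=3e-3,
    fusion_epochs=15,
    freeze_until_epoch=14,
)


def make_paired_dataset(seed: int, n_per_class: int = 50, noise_sd: float = 0.01,
                        class_effect_scale: float = 0.2, canvas_px: int = 128,
                        px_per_mm: float = 6.0, k: int = 5, fold: int = 0):
    """Generate spectra + kernel images, pair by category, and return one
    stratified train/val fold as (spectra, images, labels) triples."""
    cfg = SyntheticConfig(
        n_spectra_per_class=n_per_class, n_images_per_class=n_per_class,
        noise_sd=noise_sd, class_effect_scale=class_effect_scale,
        rng_seed=seed, canvas_px=canvas_px, px_per_mm=px_per_mm)
    X, ys = spectra_to_arrays(gen_spectra(cfg))
    X = sg_smooth(X).astype(np.float32)
    images, yi = gen_kernel_images(cfg)
    pairs = pair_by_category(yi, ys, seed)
    folds = stratified_kfold_split(pairs, k, seed)
    split = folds[fold]

    def gather(ids):
        spec = np.stack([X[pairs[i].spectrum_id] for i in ids])
        imgs = [images[pairs[i].image_id] for i in ids]
        labs = np.array([pairs[i].label for i in ids])
        return spec, imgs, labs

    train = gather(split.train_ids)
    val = gather(split.val_ids)
    # mean-centre spectra with the training-fold mean
    spec_tr, mean = center_spectra(train[0])
    spec_va, _ = center_spectra(val[0], mean)
    return ((spec_tr.astype(np.float32), train[1], train[2]),
            (spec_va.astype(np.float32), val[1], val[2]))


def run_synthetic_study(seed: int, **overrides) -> dict:
    """Pretrain both branches, run staged fusion training, and return the
    branch/fused validation accuracies plus the fusion history."""
    p = {**STUDY, **overrides}
    train, val = make_paired_dataset(
        seed, n_per_class=p["n_per_class"], noise_sd=p["noise_sd"],
        class_effect_scale=p["class_effect_scale"], canvas_px=p["canvas_px"],
        px_per_mm=p["px_per_mm"])
    spec_tr, img_tr, y_tr = train
    spec_va, img_va, y_va = val

    nn.seed_all(seed)
    spectral = build_spectral_net()
    out_s = fit_branch(spectral, (spec_tr, y_tr), (spec_va, y_va),
                       epochs=p["spectral_epochs"], lr=p["spectral_lr"],
                       seed=seed)
    spectral.load_state_dict(out_s["best_state"])

    spatial = build_spatial_net()
    out_r = fit_branch(spatial, (img_tr, y_tr), (img_va, y_va),
                       epochs=p["spatial_epochs"], lr=p["spatial_lr"],
                       seed=seed, image_size=p["image_size"],
                       augment_train=False)
    spatial.load_state_dict(out_r["best_state"])

    model = build_dualcmnet(spectral, spatial)
    cfg = TrainConfig(epochs=p["fusion_epochs"],
                      freeze_until_epoch=p["freeze_until_epoch"],
                      seed=seed, image_size=p["image_size"], augment=False)
    out_f = staged_fit(model, train, val, cfg)
    return {
        "spectral_accuracy": out_s["best_val_accuracy"],
        "spatial_accuracy": out_r["best_val_accuracy"],
        "fused_accuracy": out_f["best_val_accuracy"],
        "history": out_f["history"],
        "model": model,
        "best_state": out_f["best_state"],
    }
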