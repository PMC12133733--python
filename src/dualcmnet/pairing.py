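"""Category-matched pairing, stratified 5-fold splitting and image
augmentation.

The two modalities are never physically aligned: each image is paired with
a spectrum drawn uniformly (with replacement) from the same variety's
spectrum pool.  Pairing is fixed per run so the cross-validation folds are
well defined; re-pairing per epoch can be enabled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import PairingError, ValidationError

#: channel normalisation constants (standard natural-image statistics)
IMAGE_MEAN = np.array([0.485, 0.456, 0.406], np.float32)
IMAGE_STD = np.array([0.229, 0.224, 0.225], np.float32)


@dataclass(frozen=True)
class PairedSample:
    image_id: int
    spectrum_id: int
    label: int


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: np.ndarray
    val_ids: np.ndarray


def pair_by_category(image_labels, spectrum_labels, seed: int = 0
                     ) -> list[PairedSample]:
    """One pair per image; the spectrum is drawn uniformly with replacement
    from the same class's pool."""
    image_labels = np.asarray(image_labels, int)
    spectrum_labels = np.asarray(spectrum_labels, int)
    rng = np.random.default_rng(seed)
    pools = {int(c): np.flatnonzero(spectrum_labels == c)
             for c in np.unique(image_labels)}
    for c, pool in pools.items():
        if pool.size == 0:
            raise PairingError(f"class {c} has images but no spectra")
    return [PairedSample(int(i), int(rng.choice(pools[int(lab)])), int(lab))
            for i, lab in enumerate(image_labels)]


def stratified_kfold_split(pairs: list[PairedSample], k: int = 5,
                           seed: int = 0) -> list[FoldSplit]:
    """k stratified folds over the paired dataset; per-class counts differ
    by at most one across folds."""
    labels = np.array([p.label for p in pairs])
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} pairs; needs >= k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [FoldSplit(i, train_idx, val_idx)
            for i, (train_idx, val_idx)
            in enumerate(skf.split(np.zeros(len(pairs)), labels))]


def _resize_min_side(image: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    h, w = image.shape[:2]
    scale = size / min(h, w)
    out = resize(image, (max(int(round(h * scale)), size),
                         max(int(round(w * scale)), size)),
                 preserve_range=True, anti_aliasing=True)
    return out.astype(image.dtype)


def augment(image: np.ndarray, split: str, seed=None, rng=None,
            size: int = 224, mean=IMAGE_MEAN, std=IMAGE_STD) -> np.ndarray:
    """Crop, optionally flip, and normalise one HxWx3 uint8 image.

    train: random crop to ``size`` plus horizontal flip with p=0.5;
    val: centre crop.  Undersized images are resized up first.  Returns a
    float32 (3, size, size) tensor.
    """
    if split not in ("train", "val"):
        raise ValidationError("split must be 'train' or 'val'")
    if rng is None:
        rng = np.random.default_rng(seed)
    if min(image.shape[:2]) < size:
        image = _resize_min_side(image, size)
    h, w = image.shape[:2]
    if split == "train":
        top = rng.integers(0, h - size + 1)
        left = rng.integers(0, w - size + 1)
    else:
        top, left = (h - size) // 2, (w - size) // 2
    crop = image[top:top + size, left:left + size]
    if split == "train" and rng.random() < 0.5:
        crop = crop[:, ::-1]
    x = crop.astype(np.float32) / 255.0
    x = (x - mean) / std
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def denormalize(x: np.ndarray, mean=IMAGE_MEAN, std=IMAGE_STD) -> np.ndarray:
    """Invert ``augment``'s normalisation; returns float HxWx3 in [0, 1]."""
    return x.transpose(1, 2, 0) * std + mean


def augment_batch(images, split: str, rng, size: int = 224) -> np.ndarray:
    return np.stack([augment(img, split, rng=rng, size=size) for img in images])


def pairs_to_csv(pairs, folds, path) -> None:
    """(image_id, spectrum_id, label, fold) rows, fold = validation fold."""
    import pandas as pd

    fold_of = {}
    for f in folds:
        for i in f.val_ids:
            fold_of[int(i)] = f.fold_index
    pd.DataFrame(
        [(p.image_id, p.spectrum_id, p.label, fold_of.get(i, -1))
         for i, p in enumerate(pairs)],
        columns=["image_id", "spectrum_id", "label", "fold"],
    ).to_csv(path, index=False)
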