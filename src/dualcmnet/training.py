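"""Staged fusion training, evaluation metrics, and parameter/MAC accounting.

The fused model trains in two phases with Adam (base LR 1e-3, weight decay
1e-4, batch 32, cross-entropy): the pretrained branches stay frozen while
the fusion layers (HShuffleBlocks, CBAM, gate, classifier head) train at
the base rate; from epoch ``freeze_until_epoch + 1`` everything is
unfrozen, the branches at 0.05x and the fusion layers at 0.1x the base
rate.  Validation runs after every epoch and the highest-accuracy
parameters are kept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, UnsupportedLayerError, ValidationError
from .fusion import CBAM, GroupedLinear
from .pairing import augment_batch


@dataclass
class TrainConfig:
    batch_size: int = 32
    base_lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 50
    freeze_until_epoch: int = 14  # 1-based; unfreeze at the start of the next
    pretrained_lr_mult_phase2: float = 0.05
    fusion_lr_mult_phase2: float = 0.1
    seed: int = 0
    image_size: int = 224
    augment: bool = True

    def __post_init__(self):
        for m in (self.pretrained_lr_mult_phase2, self.fusion_lr_mult_phase2):
            if not (0 < m <= 1):
                raise ConfigurationError("LR multipliers must be in (0, 1]")
        if self.freeze_until_epoch >= self.epochs:
            raise ConfigurationError("freeze_until_epoch must be < epochs")


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    params: int | None = None
    macs: int | None = None


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """M[i, j] = number of class-i samples predicted as class j."""
    m = np.zeros((n_classes, n_classes), int)
    np.add.at(m, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return m


def metrics_from_predictions(y_true, y_pred, n_classes: int) -> MetricsReport:
    """Accuracy plus one-vs-rest macro precision/recall/F1 from the
    confusion matrix; undefined ratios (empty denominators) count as 0."""
    m = confusion_matrix(y_true, y_pred, n_classes)
    tp = np.diag(m).astype(float)
    fp = m.sum(0) - tp
    fn = m.sum(1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / m.sum()),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion=m,
    )


def _predict(model, spectra, images, batch_size=64):
    """Eval-mode class predictions for a fused model or a single branch."""
    model.eval()
    preds = []
    n = len(spectra) if spectra is not None else len(images)
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        if spectra is not None and images is not None:
            logits = model(spectra[lo:hi], images[lo:hi])
        elif spectra is not None:
            logits = model(spectra[lo:hi], "logits")
        else:
            logits = model(images[lo:hi], "logits")
        preds.append(logits.argmax(1))  # argmax ties break to lowest index
    return np.concatenate(preds)


def evaluate(model, spectra, images, labels, n_classes: int = 11,
             batch_size: int = 64) -> MetricsReport:
    """Eval-mode metrics on a validation set of (spectra, images, labels);
    pass ``spectra=None`` or ``images=None`` to evaluate a single branch."""
    labels = np.asarray(labels, int)
    if labels.size == 0:
        raise ValidationError("empty validation set")
    preds = _predict(model, spectra, images, batch_size)
    return metrics_from_predictions(labels, preds, n_classes)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo:lo + batch_size]


def _params_hash(params) -> str:
    import hashlib

    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()


def _branch_feats(model, spectra, images_t, batch_size=64):
    fs, fr = [], []
    for lo in range(0, len(spectra), batch_size):
        a, b = model.branch_features(spectra[lo:lo + batch_size],
                                     images_t[lo:lo + batch_size])
        fs.append(a)
        fr.append(b)
    return np.concatenate(fs), np.concatenate(fr)


def staged_fit(model, train_data, val_data, config: TrainConfig,
               branches_pretrained: bool = True) -> dict:
    """Two-phase fit of the fused model.

    ``train_data``/``val_data`` are (spectra, raw uint8 images, labels)
    triples; images are augmented per epoch (train policy) and centre
    cropped for validation.  Returns history, the best checkpoint state
    and its validation accuracy.
    """
    if config.freeze_until_epoch > 0 and not branches_pretrained:
        raise ConfigurationError(
            "phase-1 freezing requires pretrained branch weights")
    spectra_tr, images_tr, y_tr = train_data
    spectra_va, images_va, y_va = val_data
    y_tr = np.asarray(y_tr, int)

    nn.seed_all(config.seed)
    rng = np.random.default_rng(config.seed + 1)
    aug_rng = np.random.default_rng(config.seed + 2)

    branch_params = model.branch_parameters()
    fusion_params = model.fusion_parameters()
    for p in branch_params:
        p.trainable = False
    opt = nn.Adam([
        {"name": "branches", "params": branch_params, "lr": 0.0},
        {"name": "fusion", "params": fusion_params, "lr": config.base_lr},
    ], weight_decay=config.weight_decay)

    images_va_t = augment_batch(images_va, "val", aug_rng, config.image_size)
    # while the branches are frozen (and inputs are deterministic) their
    # feature taps are constant, so they are computed once per phase
    cache = None
    if not config.augment:
        images_tr_t = augment_batch(images_tr, "val", aug_rng, config.image_size)
        model.eval()
        cache = (_branch_feats(model, spectra_tr, images_tr_t),
                 _branch_feats(model, spectra_va, images_va_t))
    history = []
    best_acc, best_state = -1.0, None
    for epoch in range(1, config.epochs + 1):
        if epoch == config.freeze_until_epoch + 1:
            for p in branch_params:
                p.trainable = True
            opt.groups[0]["lr"] = config.base_lr * config.pretrained_lr_mult_phase2
            opt.groups[1]["lr"] = config.base_lr * config.fusion_lr_mult_phase2
        frozen = epoch <= config.freeze_until_epoch
        model.train()
        losses = []
        if frozen and cache is not None:
            (fs_tr, fr_tr), _ = cache
            for idx in _batches(len(y_tr), config.batch_size, rng):
                logits = model.fuse_features(fs_tr[idx], fr_tr[idx])
                loss, grad = nn.softmax_cross_entropy(logits, y_tr[idx])
                model.zero_grad()
                model.backward(grad, through_branches=False)
                opt.step()
                losses.append(loss)
        else:
            for idx in _batches(len(y_tr), config.batch_size, rng):
                imgs = augment_batch([images_tr[i] for i in idx],
                                     "train" if config.augment else "val",
                                     aug_rng, config.image_size)
                logits = model(spectra_tr[idx], imgs)
                loss, grad = nn.softmax_cross_entropy(logits, y_tr[idx])
                model.zero_grad()
                model.backward(grad, through_branches=not frozen)
                opt.step()
                losses.append(loss)
        model.eval()
        if frozen and cache is not None:
            _, (fs_va, fr_va) = cache
            preds = model.fuse_features(fs_va, fr_va).argmax(1)
            rep = metrics_from_predictions(y_va, preds, model.head.out_features)
        else:
            rep = evaluate(model, spectra_va, images_va_t, y_va,
                           n_classes=model.head.out_features)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_accuracy": rep.accuracy,
            "lr_branches": opt.groups[0]["lr"],
            "lr_fusion": opt.groups[1]["lr"],
            # digest of the branch weights: constant across phase-1 epochs
            "branch_hash": _params_hash(branch_params),
        })
        if rep.accuracy > best_acc:
            best_acc = rep.accuracy
            best_state = copy.deepcopy(model.state_dict())
    return {"history": history, "best_val_accuracy": best_acc,
            "best_state": best_state}


def fit_branch(model, train_data, val_data=None, epochs: int = 200,
               lr: float = 1e-3, weight_decay: float = 1e-4,
               batch_size: int = 32, seed: int = 0, image_size: int = 224,
               augment_train: bool = True) -> dict:
    """Plain Adam pretraining loop for a single branch.

    ``train_data`` is (X, labels) where X is a spectra array for the
    spectral branch or a list of raw uint8 images for the spatial branch.
    """
    X_tr, y_tr = train_data
    y_tr = np.asarray(y_tr, int)
    is_image = not isinstance(X_tr, np.ndarray) or np.asarray(X_tr[0]).ndim == 3
    nn.seed_all(seed)
    rng = np.random.default_rng(seed + 1)
    aug_rng = np.random.default_rng(seed + 2)
    opt = nn.Adam([{"name": "all", "params": model.parameters(), "lr": lr}],
                  weight_decay=weight_decay)
    history, best_acc, best_state = [], -1.0, None
    X_va_t = y_va = None
    if val_data is not None:
        X_va, y_va = val_data
        X_va_t = (augment_batch(X_va, "val", aug_rng, image_size)
                  if is_image else X_va)
    for epoch in range(1, epochs + 1):
        model.train()
        losses = []
        for idx in _batches(len(y_tr), batch_size, rng):
            if is_image:
                xb = augment_batch([X_tr[i] for i in idx],
                                   "train" if augment_train else "val",
                                   aug_rng, image_size)
            else:
                xb = X_tr[idx]
            logits = model(xb, "logits")
            loss, grad = nn.softmax_cross_entropy(logits, y_tr[idx])
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_data is not None:
            model.eval()
            rep = evaluate(model, None if is_image else X_va_t,
                           X_va_t if is_image else None, y_va,
                           n_classes=int(y_tr.max()) + 1)
            entry["val_accuracy"] = rep.accuracy
            if rep.accuracy > best_acc:
                best_acc, best_state = rep.accuracy, copy.deepcopy(model.state_dict())
        history.append(entry)
    return {"history": history, "best_val_accuracy": best_acc,
            "best_state": best_state}


# ---------------------------------------------------------------------------
# Parameter and MAC accounting
# ---------------------------------------------------------------------------


def count_params(model: nn.Module) -> int:
    """Exact count of trainable parameters."""
    return int(sum(p.size for p in model.parameters() if p.trainable))


#: layers with parameters that contribute no multiply-accumulates under the
#: one-MAC-per-multiply-add convention (BN folds at inference)
_NO_MAC_PARAMETRIC = (nn.BatchNorm,)


def count_macs(model: nn.Module, forward) -> int:
    """Analytic multiply-accumulate count for one forward pass.

    ``forward`` is a zero-argument callable running the model once in eval
    mode on a representative input (it fixes the conv output sizes).  One
    multiply-add counts as 1; elementwise, normalisation and pooling ops
    are excluded, matching the convention under which MobileNetV3-Small at
    224x224 costs ~0.06 G.
    """
    model.eval()
    forward()
    total = 0
    for m in model.modules():
        if isinstance(m, nn.Conv2d):
            ho, wo = m.last_out_hw
            total += ho * wo * m.out_ch * (m.in_ch // m.groups) * m.k * m.k
        elif isinstance(m, nn.Conv1d):
            total += m.last_out_len * m.out_ch * m.in_ch * m.k
        elif isinstance(m, nn.Linear):
            total += m.in_features * m.out_features
        elif isinstance(m, GroupedLinear):
            total += m.in_features * m.out_features // m.groups
        elif isinstance(m, CBAM):
            C, r = m.config.channels, m.config.reduction
            total += 2 * 2 * (C * (C // r))  # shared MLP on avg and max paths
            # (the 7x7 conv is a Conv2d child, counted above)
        elif isinstance(m, _NO_MAC_PARAMETRIC):
            continue
        elif m._params:
            raise UnsupportedLayerError(
                f"no MAC rule for parametric layer {type(m).__name__}")
    return int(total)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: nn.Module, meta: dict | None = None) -> None:
    """Weights (npz) plus a JSON-encoded metadata blob."""
    import json

    state = model.state_dict()
    state["_meta"] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, model: nn.Module) -> dict:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode()) if "_meta" in data else {}
        model.load_state_dict({k: data[k] for k in data.files if k != "_meta"})
    return meta
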