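"""Metrics arithmetic, parameter/MAC accounting, and the staged-training
schedule on a miniature fused model."""

import numpy as np
import pytest

from dualcmnet import (GroupedLinear, TrainConfig, build_dualcmnet,
                       build_spatial_net, build_spectral_net, nn)
from dualcmnet.errors import (ConfigurationError, UnsupportedLayerError,
                              ValidationError)
from dualcmnet.training import (count_macs, count_params, evaluate,
                                metrics_from_predictions, staged_fit)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_perfect_predictions_give_unit_metrics_and_diagonal_confusion():
    y = np.repeat(np.arange(4), 3)
    rep = metrics_from_predictions(y, y, 4)
    assert rep.accuracy == rep.macro_f1 == rep.macro_precision == 1.0
    assert np.all(rep.confusion == np.diag([3, 3, 3, 3]))


def test_two_class_toy_matches_precision_recall_formulas():
    """Class 0 with TP=1, FP=1, FN=0: precision 1/2, recall 1, F1 2/3."""
    rep = metrics_from_predictions([0, 1], [0, 0], 2)
    tp0 = rep.confusion[0, 0]
    fp0 = rep.confusion[:, 0].sum() - tp0
    fn0 = rep.confusion[0, :].sum() - tp0
    assert (tp0, fp0, fn0) == (1, 1, 0)
    prec0 = tp0 / (tp0 + fp0)
    rec0 = tp0 / (tp0 + fn0)
    assert prec0 == 0.5 and rec0 == 1.0
    assert 2 * prec0 * rec0 / (prec0 + rec0) == pytest.approx(2 / 3)


def test_accuracy_equals_confusion_trace_over_total(rng):
    y = rng.integers(0, 5, 200)
    p = rng.integers(0, 5, 200)
    rep = metrics_from_predictions(y, p, 5)
    assert rep.accuracy == np.trace(rep.confusion) / rep.confusion.sum()
    assert np.all(rep.confusion.sum(1) == np.bincount(y, minlength=5))


def test_evaluate_rejects_empty_validation_set():
    with pytest.raises(ValidationError):
        evaluate(build_spectral_net(), np.zeros((0, 2151)), None, [])


def test_argmax_ties_break_to_lowest_class_index():
    assert np.argmax(np.zeros(11)) == 0


# ---------------------------------------------------------------------------
# parameter / MAC accounting
# ---------------------------------------------------------------------------


def test_count_params_closed_forms():
    assert count_params(nn.Linear(7, 5)) == 7 * 5 + 5
    gl = GroupedLinear(8, 4, 2)
    assert count_params(gl) == 8 * 4 // 2 + 4
    assert count_params(gl) == sum(p.value.size for p in gl.parameters())


def test_count_params_skips_frozen_tensors():
    lin = nn.Linear(7, 5)
    lin.weight.trainable = False
    assert count_params(lin) == 5  # bias only


def test_count_macs_affine_and_conv1d_against_loop_counter():
    lin = nn.Linear(7, 5)
    assert count_macs(lin, lambda: lin(np.zeros((1, 7), np.float32))) == 35
    conv = nn.Conv1d(2, 3, 3, padding=1)
    x = np.zeros((1, 2, 10), np.float32)
    macs = count_macs(conv, lambda: conv(x))
    # naive loop counter: one MAC per (output position, out ch, in ch, tap)
    naive = 0
    for _pos in range(10):
        for _co in range(3):
            for _ci in range(2):
                for _k in range(3):
                    naive += 1
    assert macs == naive


def test_count_macs_rejects_unknown_parametric_layer():
    class Weird(nn.Module):
        def __init__(self):
            super().__init__()
            self.w = nn.Parameter(np.zeros(3, np.float32))

        def forward(self, x):
            return x

    m = Weird()
    with pytest.raises(UnsupportedLayerError):
        count_macs(m, lambda: m(np.zeros(3)))


# ---------------------------------------------------------------------------
# staged training schedule
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_study():
    """A miniature paired dataset + fused model (small images, 3 classes)."""
    from dualcmnet.pipeline import make_paired_dataset

    train, val = make_paired_dataset(seed=5, n_per_class=8, canvas_px=128,
                                     px_per_mm=6.0, k=4)
    nn.seed_all(5)
    return train, val


def _fresh_model():
    nn.seed_all(5)
    return build_dualcmnet(build_spectral_net(), build_spatial_net())


def test_staged_fit_freezes_then_switches_learning_rates(tiny_study):
    train, val = tiny_study
    model = _fresh_model()
    cfg = TrainConfig(epochs=4, freeze_until_epoch=3, seed=5, image_size=96,
                      augment=False, batch_size=16)
    before = [p.value.copy() for p in model.branch_parameters()]
    out = staged_fit(model, train, val, cfg)
    h = out["history"]
    # phase 1: branch weights bit-identical (hash constant), base LR on fusion
    assert h[0]["branch_hash"] == h[1]["branch_hash"] == h[2]["branch_hash"]
    assert h[0]["lr_branches"] == 0.0 and h[0]["lr_fusion"] == 1e-3
    # phase 2 at epoch freeze_until+1: (0.05x, 0.1x) of the base rate
    assert h[3]["lr_branches"] == pytest.approx(5e-5)
    assert h[3]["lr_fusion"] == pytest.approx(1e-4)
    assert h[3]["branch_hash"] != h[2]["branch_hash"]
    # the frozen phase left the snapshot untouched until epoch 4 ran
    changed = any(not np.array_equal(b, p.value)
                  for b, p in zip(before, model.branch_parameters()))
    assert changed  # after unfreezing the branches do train


def test_staged_fit_loss_decreases_on_easy_data(tiny_study):
    train, val = tiny_study
    model = _fresh_model()
    cfg = TrainConfig(epochs=6, freeze_until_epoch=5, seed=5, image_size=96,
                      augment=False, batch_size=16)
    out = staged_fit(model, train, val, cfg)
    h = out["history"]
    assert h[-1]["train_loss"] < h[0]["train_loss"]
    assert out["best_val_accuracy"] == max(e["val_accuracy"] for e in h)


def test_staged_fit_requires_pretrained_weights_for_freezing(tiny_study):
    train, val = tiny_study
    with pytest.raises(ConfigurationError):
        staged_fit(_fresh_model(), train, val,
                   TrainConfig(epochs=3, freeze_until_epoch=2, seed=0),
                   branches_pretrained=False)


def test_train_config_validation():
    with pytest.raises(ConfigurationError):
        TrainConfig(freeze_until_epoch=50, epochs=50)
    with pytest.raises(ConfigurationError):
        TrainConfig(pretrained_lr_mult_phase2=0.0)
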