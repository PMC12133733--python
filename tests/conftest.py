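import numpy as np
import pytest

from dualcmnet import nn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _seed_framework():
    nn.seed_all(0)


def to_float64(module: nn.Module) -> nn.Module:
    """Cast parameters to float64 for tight finite-difference checks."""
    for p in module.parameters():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    return module


def gradcheck(module, x, forward, backward, eps=1e-6, tol=1e-6):
    """Compare analytic gradients of sum(forward(x) * w) against central
    differences, for the input and every parameter."""
    y = forward(x)
    w = np.random.default_rng(0).standard_normal(y.shape)

    def loss():
        return float((forward(x) * w).sum())

    for p in module.parameters():
        p.grad[...] = 0
    forward(x)
    gin = backward(w)
    num = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x1 = x.copy(); x1[i] += eps
        x2 = x.copy(); x2[i] -= eps
        num[i] = ((forward(x1) * w).sum() - (forward(x2) * w).sum()) / (2 * eps)
    assert np.abs(num - gin).max() < tol, "input gradient mismatch"

    for p in module.parameters():
        for q in module.parameters():
            q.grad[...] = 0
        forward(x)
        backward(w)
        g = p.grad.copy()
        num = np.zeros_like(p.value)
        it = np.nditer(p.value, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = p.value[i]
            p.value[i] = old + eps
            f1 = loss()
            p.value[i] = old - eps
            f2 = loss()
            p.value[i] = old
            num[i] = (f1 - f2) / (2 * eps)
        assert np.abs(num - g).max() < tol, "parameter gradient mismatch"
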