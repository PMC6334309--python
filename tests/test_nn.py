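"""Gradient and contract checks for the numpy NN engine.

Every layer's backward pass is compared against central finite differences
(the independent oracle) on tiny float64 inputs.
"""

import numpy as np
import pytest

from nodulegan import nn


def numeric_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_layer_grads(layer, x, rtol=1e-4, atol=1e-6):
    """Compare backward() against finite differences for input and params."""
    rng = np.random.default_rng(7)

    def loss():
        y = layer.forward(x)
        return float((y * w_out).sum())

    y = layer.forward(x)
    w_out = rng.normal(size=y.shape)  # random linear functional of the output
    gx = layer.backward(w_out)

    np.testing.assert_allclose(gx, numeric_grad(loss, x), rtol=rtol, atol=atol)
    for name, p in layer.params.items():
        np.testing.assert_allclose(
            layer.grads[name], numeric_grad(loss, p), rtol=rtol, atol=atol,
            err_msg=f"param {name}",
        )


@pytest.mark.parametrize(
    "make_layer,shape",
    [
        (lambda rng: nn.Conv2d(2, 3, 3, stride=1, pad=1, rng=rng, dtype=np.float64), (2, 2, 5, 5)),
        (lambda rng: nn.Conv2d(1, 2, 5, stride=2, pad=2, rng=rng, dtype=np.float64), (2, 1, 8, 8)),
        (lambda rng: nn.Conv2d(2, 4, 3, stride=2, pad=0, rng=rng, dtype=np.float64), (1, 2, 7, 7)),
        (lambda rng: nn.ConvTranspose2d(3, 2, 5, stride=2, pad=2, output_padding=1, rng=rng, dtype=np.float64), (2, 3, 4, 4)),
        (lambda rng: nn.ConvTranspose2d(2, 1, 3, stride=1, pad=0, output_padding=0, rng=rng, dtype=np.float64), (1, 2, 3, 3)),
        (lambda rng: nn.BatchNorm2d(3, dtype=np.float64), (4, 3, 3, 3)),
        (lambda rng: nn.Linear(6, 4, rng=rng, dtype=np.float64), (3, 6)),
        (lambda rng: nn.Tanh(), (2, 3, 4, 4)),
        (lambda rng: nn.LeakyReLU(0.2), (2, 3, 4, 4)),
    ],
)
def test_layer_gradients_match_finite_differences(make_layer, shape):
    rng = np.random.default_rng(0)
    layer = make_layer(rng)
    x = rng.normal(size=shape)
    check_layer_grads(layer, x)


def test_maxpool_gradient_matches_finite_differences():
    # Distinct values so the argmax is stable under the FD perturbation.
    rng = np.random.default_rng(3)
    x = rng.permutation(np.linspace(-1, 1, 2 * 2 * 7 * 7)).reshape(2, 2, 7, 7)
    check_layer_grads(nn.MaxPool2d(3, 2), x)


def test_sequential_end_to_end_gradient():
    rng = np.random.default_rng(5)
    model = nn.Sequential(
        nn.Conv2d(1, 3, 3, stride=2, pad=1, rng=rng, dtype=np.float64),
        nn.BatchNorm2d(3, dtype=np.float64),
        nn.ReLU(),
        nn.Flatten(),
        nn.Linear(3 * 4 * 4, 2, rng=rng, dtype=np.float64),
    )
    x = rng.normal(size=(4, 1, 8, 8))
    labels = np.array([0, 1, 1, 0])

    def loss():
        logits = model.forward(x)
        return nn.softmax_cross_entropy(logits, labels)[0]

    logits = model.forward(x)
    _, dlogits = nn.softmax_cross_entropy(logits, labels)
    gx = model.backward(dlogits)
    np.testing.assert_allclose(gx, numeric_grad(loss, x), rtol=1e-4, atol=1e-6)
    for layer, name, p in model.parameters():
        np.testing.assert_allclose(layer.grads[name], numeric_grad(loss, p), rtol=1e-4, atol=1e-6)


def test_conv_shape_arithmetic():
    conv = nn.Conv2d(1, 96, 11, stride=4, pad=0)
    assert conv.out_size(227) == 55
    pool = nn.MaxPool2d(3, 2)
    assert pool.out_size(55) == 27
    ct = nn.ConvTranspose2d(8, 4, 5, stride=2, pad=2, output_padding=1)
    assert ct.out_size(4) == 8 and ct.out_size(32) == 64


def test_batchnorm_inference_uses_running_stats():
    rng = np.random.default_rng(1)
    bn = nn.BatchNorm2d(2, dtype=np.float64)
    x = rng.normal(3.0, 2.0, size=(8, 2, 4, 4))
    for _ in range(50):
        bn.forward(x)
    bn.training = False
    y = bn.forward(x)
    # running stats converge to batch stats, so inference output ~ normalized
    assert abs(y.mean()) < 0.05 and abs(y.std() - 1.0) < 0.05


def test_dropout_inverted_scaling_and_inference_identity():
    rng = np.random.default_rng(2)
    d = nn.Dropout(0.5, rng=rng)
    x = np.ones((1000, 10))
    y = d.forward(x)
    assert set(np.unique(y)) <= {0.0, 2.0}
    assert abs(y.mean() - 1.0) < 0.05
    d.training = False
    np.testing.assert_array_equal(d.forward(x), x)


@pytest.mark.parametrize(
    "opt_cls,kwargs,steps",
    [(nn.SGD, dict(lr=0.05, momentum=0.9), 500), (nn.RMSprop, dict(lr=0.02), 1500)],
)
def test_optimizers_reach_least_squares_optimum(opt_cls, kwargs, steps):
    # minimize ||Wx + b - t||^2; analytic optimum from lstsq is the oracle
    rng = np.random.default_rng(0)
    model = nn.Sequential(nn.Linear(4, 3, rng=rng, dtype=np.float64))
    opt = opt_cls(model, **kwargs)
    x = rng.normal(size=(16, 4))
    t = rng.normal(size=(16, 3))
    xa = np.hstack([x, np.ones((16, 1))])
    coef, *_ = np.linalg.lstsq(xa, t, rcond=None)
    opt_loss = float(((xa @ coef - t) ** 2).mean())
    for _ in range(steps):
        y = model.forward(x)
        r = y - t
        loss = float((r**2).mean())
        model.zero_grad()
        model.backward(2 * r / r.size)
        opt.step()
    assert loss < opt_loss * 1.05 + 1e-6
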