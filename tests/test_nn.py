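"""Numpy neural-network engine: gradients, shapes, determinism."""

import numpy as np
import pytest

from usdespeckle import nn


def numerical_grad(f, param, eps=1e-3):
    grad = np.zeros_like(param, dtype=np.float64)
    it = np.nditer(param, flags=["multi_index"])
    while not it.finished:
        ij = it.multi_index
        old = param[ij]
        param[ij] = old + eps
        lp = f()
        param[ij] = old - eps
        lm = f()
        param[ij] = old
        grad[ij] = (lp - lm) / (2 * eps)
        it.iternext()
    return grad


@pytest.mark.parametrize("layer_factory,in_shape", [
    (lambda: nn.Conv2D(2, 3, kernel=3, activation="linear"), (2, 6, 6, 2)),
    (lambda: nn.Conv2D(1, 2, kernel=3, activation="relu"), (2, 6, 6, 1)),
    (lambda: nn.Dense(5, 3, activation="linear"), (4, 5)),
    (lambda: nn.BatchNorm(3), (4, 4, 4, 3)),
])
def test_parameter_gradients_match_numerical(layer_factory, in_shape):
    rng = np.random.default_rng(1)
    layer = layer_factory()
    layer.init(rng)
    if isinstance(layer, nn.Conv2D):
        layer.W += rng.normal(0, 0.2, layer.W.shape).astype(np.float32)
        layer.b += rng.normal(0, 0.2, layer.b.shape).astype(np.float32)
    x = rng.random(in_shape).astype(np.float32)
    target = rng.random(in_shape[:1] + layer.forward(x, True).shape[1:]).astype(np.float32)

    def loss():
        return nn.mse_loss(layer.forward(x, True), target)[0]

    value, grad = nn.mse_loss(layer.forward(x, True), target)
    layer.backward(grad)
    for param, analytic in zip(layer.params(), layer.grads()):
        numeric = numerical_grad(loss, param)
        np.testing.assert_allclose(analytic, numeric, rtol=0.02, atol=2e-4)


@pytest.mark.parametrize("layer,in_shape", [
    (nn.Conv2D(2, 3, kernel=3), (2, 6, 6, 2)),
    (nn.MaxPool2x2(), (2, 6, 6, 2)),
    (nn.Upsample2x(), (2, 3, 3, 2)),
    (nn.Dense(8, 4), (3, 8)),
])
def test_input_gradients_match_numerical(layer, in_shape):
    rng = np.random.default_rng(2)
    layer.init(rng)
    x = rng.random(in_shape).astype(np.float32)
    out = layer.forward(x, True)
    target = rng.random(out.shape).astype(np.float32)

    def loss():
        return nn.mse_loss(layer.forward(x, True), target)[0]

    _, grad = nn.mse_loss(layer.forward(x, True), target)
    gx = layer.backward(grad)
    numeric = numerical_grad(loss, x)
    np.testing.assert_allclose(gx, numeric, rtol=0.02, atol=2e-4)


def test_maxpool_forward_and_tie_breaking():
    x = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
    pool = nn.MaxPool2x2()
    out = pool.forward(x, True)
    np.testing.assert_array_equal(out[0, :, :, 0], [[5, 7], [13, 15]])
    # ties send the gradient to exactly one entry
    xt = np.ones((1, 2, 2, 1), dtype=np.float32)
    pool.forward(xt, True)
    gx = pool.backward(np.ones((1, 1, 1, 1), dtype=np.float32))
    assert gx.sum() == 1.0


def test_upsample_is_nearest_neighbour():
    x = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32).reshape(1, 2, 2, 1)
    out = nn.Upsample2x().forward(x, False)
    np.testing.assert_array_equal(out[0, :, :, 0],
                                  [[1, 1, 2, 2], [1, 1, 2, 2],
                                   [3, 3, 4, 4], [3, 3, 4, 4]])


def test_glorot_bounds_and_seeding():
    layer_a = nn.Conv2D(4, 8, kernel=3)
    layer_b = nn.Conv2D(4, 8, kernel=3)
    layer_a.init(np.random.default_rng(7))
    layer_b.init(np.random.default_rng(7))
    np.testing.assert_array_equal(layer_a.W, layer_b.W)
    limit = np.sqrt(6.0 / (9 * 4 + 9 * 8))
    assert np.all(np.abs(layer_a.W) <= limit)
    assert np.all(layer_a.b == 0)


def test_dropout_scales_and_is_identity_at_inference():
    layer = nn.Dropout(0.5)
    layer.reseed(3)
    x = np.ones((64, 64), dtype=np.float32)
    out = layer.forward(x, training=True)
    assert set(np.unique(out)) == {0.0, 2.0}  # inverted dropout
    np.testing.assert_array_equal(layer.forward(x, training=False), x)


def test_fit_aborts_on_nonfinite_loss():
    model = nn.Sequential([nn.Dense(2, 1)], seed=0)
    model.layers[0].W[:] = 1e30
    x = np.full((4, 2), 1e30, dtype=np.float32)
    y = np.zeros((4, 1), dtype=np.float32)
    with pytest.raises(RuntimeError, match="non-finite"):
        nn.fit(model, x, y, epochs=1, batch_size=2, optimizer=nn.Adam(model))


def test_adam_converges_on_least_squares():
    rng = np.random.default_rng(0)
    x = rng.random((64, 3)).astype(np.float32)
    true_w = np.array([[1.0], [-2.0], [0.5]], dtype=np.float32)
    y = x @ true_w
    model = nn.Sequential([nn.Dense(3, 1)], seed=1)
    history = nn.fit(model, x, y, epochs=600, batch_size=16,
                     optimizer=nn.Adam(model, lr=0.01))
    assert history[-1] < 1e-4
    np.testing.assert_allclose(model.layers[0].W, true_w, atol=0.05)


def test_weight_roundtrip():
    model = nn.Sequential([nn.Dense(4, 2), nn.ReLU(), nn.Dense(2, 1)], seed=3)
    weights = model.get_weights()
    clone = nn.Sequential([nn.Dense(4, 2), nn.ReLU(), nn.Dense(2, 1)], seed=9)
    clone.set_weights(weights)
    x = np.random.default_rng(0).random((5, 4)).astype(np.float32)
    np.testing.assert_array_equal(model.forward(x), clone.forward(x))
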