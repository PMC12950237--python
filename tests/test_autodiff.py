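"""Gradient checks (central differences, float64) and optimiser sanity for
the numpy autodiff stack every model component is built from."""

import numpy as np
import pytest

from eegart import nn
from eegart.nn import tensor as T
from eegart.nn.tensor import Tensor


def _num_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f w.r.t. array x (float64)."""
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def _scalarize(out, w):
    """Deterministic random projection of an op output to a scalar tensor."""
    prod = T.mul(out, Tensor(w))
    return T.mean(T.reshape(prod, (1, -1)), axis=1)


def _check(op, shapes, rng, wrt=None, atol=1e-6):
    """Run op on float64 leaf tensors and compare grads to finite differences."""
    arrays = [rng.standard_normal(s) for s in shapes]
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    w = rng.standard_normal(op(*tensors).shape)

    loss = _scalarize(op(*tensors), w)
    loss.backward()
    wrt = range(len(tensors)) if wrt is None else wrt
    for i in wrt:
        num = _num_grad(lambda: _scalarize(op(*[Tensor(a) for a in arrays]), w).item(),
                        arrays[i])
        assert tensors[i].grad is not None, f"no gradient for argument {i}"
        np.testing.assert_allclose(tensors[i].grad, num, atol=atol, rtol=1e-5,
                                   err_msg=f"argument {i} of {op}")


@pytest.mark.parametrize("name,op,shapes", [
    ("add_broadcast", lambda a, b: T.add(a, b), [(3, 4), (4,)]),
    ("mul", lambda a, b: T.mul(a, b), [(3, 4), (3, 4)]),
    ("matmul_batched", lambda a, b: T.matmul(a, b), [(2, 3, 4), (2, 4, 5)]),
    ("linear", lambda x, w, b: T.linear(x, w, b), [(5, 3), (3, 4), (4,)]),
    ("reshape_transpose", lambda a: T.transpose(T.reshape(a, (2, 6)), (1, 0)), [(3, 4)]),
    ("concat", lambda a, b: T.concat([a, b], axis=1), [(2, 3), (2, 5)]),
    ("mean_axis", lambda a: T.mean(a, axis=1), [(4, 6)]),
    ("elu", lambda a: T.elu(a), [(5, 7)]),
    ("softmax", lambda a: T.softmax(a, axis=-1), [(4, 6)]),
    ("layer_norm", lambda x, g, b: T.layer_norm(x, g, b), [(6, 5), (5,), (5,)]),
    ("conv1d_s2", lambda x, w, b: T.conv1d(x, w, b, stride=2), [(2, 3, 17), (4, 3, 5), (4,)]),
    ("conv2d", lambda x, w, b: T.conv2d(x, w, b), [(2, 3, 7, 6), (4, 3, 3, 3), (4,)]),
    ("conv2d_padw", lambda x, w, b: T.conv2d(x, w, b, pad_w=1), [(2, 2, 6, 4), (3, 2, 1, 3), (3,)]),
    ("maxpool1d", lambda x: T.max_pool1d(x, 3, 2), [(2, 3, 11)]),
    ("maxpool2d", lambda x: T.max_pool2d(x, (2, 2)), [(2, 3, 5, 6)]),
])
def test_gradients_match_finite_differences(name, op, shapes):
    _check(op, shapes, np.random.default_rng(hash(name) % 2**31))


def test_attention_gradients_match_finite_differences():
    rng = np.random.default_rng(42)
    d, h = 8, 2

    def op(x, wqkv, bqkv, wo, bo):
        return T.multi_head_self_attention(x, wqkv, bqkv, wo, bo, h)

    _check(op, [(2, 5, d), (d, 3 * d), (3 * d,), (d, d), (d,)], rng, atol=5e-6)


def test_attention_gradients_without_weight_cache(monkeypatch):
    """The recompute-in-backward path (large sequences) gives the same
    gradients as the cached path."""
    monkeypatch.setattr(T, "ATTENTION_CACHE_BYTES", 0)
    rng = np.random.default_rng(43)
    d, h = 8, 2

    def op(x, wqkv, bqkv, wo, bo):
        return T.multi_head_self_attention(x, wqkv, bqkv, wo, bo, h)

    _check(op, [(2, 5, d), (d, 3 * d), (3 * d,), (d, d), (d,)], rng, atol=5e-6)


def test_no_grad_suppresses_tape():
    x = Tensor(np.ones(3), requires_grad=True)
    with T.no_grad():
        y = T.mul(x, x)
    assert not y.requires_grad and y._backward_fn is None


def test_batchnorm_gradients_train_and_eval():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((4, 3, 6))
    g = rng.standard_normal(3)
    b = rng.standard_normal(3)
    for training in (True, False):
        rm, rv = np.zeros(3), np.ones(3)
        arrays = [x.copy(), g.copy(), b.copy()]
        tensors = [Tensor(a, requires_grad=True) for a in arrays]
        w = rng.standard_normal((4, 3, 6))

        def run(ts):
            return T.batch_norm(ts[0], ts[1], ts[2], rm.copy(), rv.copy(), training)

        loss = _scalarize(run(tensors), w)
        loss.backward()
        for i in range(3):
            num = _num_grad(
                lambda: _scalarize(run([Tensor(a) for a in arrays]), w).item(), arrays[i]
            )
            np.testing.assert_allclose(tensors[i].grad, num, atol=1e-6, rtol=1e-5)


def test_softmax_cross_entropy_gradient_and_value():
    rng = np.random.default_rng(9)
    z = rng.standard_normal((6, 4))
    y = rng.integers(0, 4, size=6)
    t = Tensor(z.copy(), requires_grad=True)
    loss = T.softmax_cross_entropy(t, y)
    # value equals the plain formula
    p = T.stable_softmax(z)
    expect = -np.mean(np.log(p[np.arange(6), y]))
    assert np.isclose(loss.item(), expect, atol=1e-10)
    loss.backward()
    num = _num_grad(lambda: T.softmax_cross_entropy(Tensor(z), y).item(), z)
    np.testing.assert_allclose(t.grad, num, atol=1e-6, rtol=1e-5)


def test_dropout_scales_and_masks(rng):
    x = Tensor(np.ones((200, 50)), requires_grad=True)
    out = T.dropout(x, 0.5, np.random.default_rng(0), training=True)
    vals = np.unique(out.data)
    assert set(vals).issubset({0.0, 2.0})  # inverted dropout
    assert abs(out.data.mean() - 1.0) < 0.05
    # eval mode: identity
    assert T.dropout(x, 0.5, np.random.default_rng(0), training=False) is x


def test_gradient_accumulates_over_shared_parent():
    x = Tensor(np.array([1.0, 2.0]), requires_grad=True)
    y = T.add(T.mul(x, x), x)  # x^2 + x -> grad 2x + 1
    loss = T.mean(T.reshape(y, (1, -1)), axis=1)
    loss.backward()
    np.testing.assert_allclose(x.grad, (2 * x.data + 1) / 2)


def test_adam_matches_reference_update():
    p = Tensor(np.array([1.0, -2.0], dtype=np.float32), requires_grad=True)
    opt = nn.Adam([p], lr=0.1, beta1=0.9, beta2=0.999)
    g = np.array([0.5, -1.0], dtype=np.float32)
    p.grad = g.copy()
    opt.step()
    m = 0.1 * g
    v = 0.001 * g * g
    expect = np.array([1.0, -2.0]) - 0.1 * (m / 0.1) / (np.sqrt(v / 0.001) + 1e-8)
    np.testing.assert_allclose(p.data, expect, rtol=1e-6)
    with pytest.raises(ValueError):
        nn.Adam([p], lr=-1.0)


def test_state_dict_round_trip_restores_weights():
    rng = np.random.default_rng(0)
    layer = nn.TransformerEncoder(2, 8, 2, 16, rng)
    state = layer.state_dict()
    for p in layer.parameters():
        p.data = p.data + 1.0
    layer.load_state_dict(state)
    for k, v in layer.state_dict().items():
        np.testing.assert_array_equal(v, state[k])
    with pytest.raises(ValueError):
        layer.load_state_dict({"bogus": np.zeros(1)})
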