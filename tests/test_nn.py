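"""Neural-network core: gradients against finite differences, module
mechanics, optimizer behavior."""

import numpy as np
import pytest

from skelseq.nn import AdamW, RngRef, Tensor, TransformerEncoder, concat, no_grad
from skelseq.nn.autograd import (
    bce_with_logits,
    cross_entropy_logits,
    embedding_lookup,
    layer_norm,
    softmax_cross_entropy_probs,
)


def numeric_grad(fn, params, eps=1e-6):
    """Central finite differences of a scalar fn w.r.t. each parameter."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p.data[i]
            p.data[i] = orig + eps
            lp = fn().item()
            p.data[i] = orig - eps
            lm = fn().item()
            p.data[i] = orig
            g[i] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads


def check_grads(fn, params, atol=1e-7):
    loss = fn()
    for p in params:
        p.grad = None
    loss.backward()
    for p, num in zip(params, numeric_grad(fn, params)):
        np.testing.assert_allclose(p.grad, num, atol=atol, rtol=1e-5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestAutogradGradients:
    """Every op family is validated against central finite differences
    (float64 so truncation error dominates round-off)."""

    def test_arithmetic_and_broadcast(self, rng):
        a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4,)), requires_grad=True)

        def fn():
            return (((a + b) * b - a * 0.5 + 2.0) ** 2).mean()

        check_grads(fn, [a, b])

    def test_matmul_batched(self, rng):
        a = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
        w = Tensor(rng.normal(size=(4, 5)), requires_grad=True)

        def fn():
            return ((a @ w).tanh()).sum() * 0.1

        check_grads(fn, [a, w])

    def test_reshape_transpose_slice(self, rng):
        a = Tensor(rng.normal(size=(2, 6)), requires_grad=True)

        def fn():
            b = a.reshape(2, 3, 2).transpose(1, 0, 2)
            return (b[:, 0, :] ** 2).sum()

        check_grads(fn, [a])

    def test_activations(self, rng):
        a = Tensor(rng.normal(size=(4, 5)), requires_grad=True)

        def fn():
            return (a.gelu() + a.relu() * 0.3 + a.leaky_relu(0.2) * 0.1).sum()

        check_grads(fn, [a], atol=1e-6)

    def test_softmax_and_reductions(self, rng):
        a = Tensor(rng.normal(size=(3, 6)), requires_grad=True)

        def fn():
            return (a.softmax(axis=-1) ** 2).sum(axis=-1).mean()

        check_grads(fn, [a])

    def test_layer_norm(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 8)), requires_grad=True)
        g = Tensor(rng.uniform(0.5, 1.5, size=8), requires_grad=True)
        b = Tensor(rng.normal(size=8), requires_grad=True)

        def fn():
            return (layer_norm(x, g, b) ** 2).mean()

        check_grads(fn, [x, g, b], atol=1e-6)

    def test_embedding_lookup_accumulates_repeats(self, rng):
        E = Tensor(rng.normal(size=(7, 4)), requires_grad=True)
        ids = np.array([[0, 3, 3], [6, 0, 1]])  # repeated ids must sum grads

        def fn():
            return (embedding_lookup(E, ids) ** 2).sum()

        check_grads(fn, [E])

    def test_cross_entropy_logits(self, rng):
        z = Tensor(rng.normal(size=(5, 4)), requires_grad=True)
        labels = np.array([0, 1, 2, 3, 1])

        def fn():
            return cross_entropy_logits(z, labels)

        check_grads(fn, [z])

    def test_cross_entropy_probs(self, rng):
        z = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        t = rng.dirichlet(np.ones(3), size=4)

        def fn():
            return softmax_cross_entropy_probs(z, t)

        check_grads(fn, [z])

    def test_bce_with_logits(self, rng):
        z = Tensor(rng.normal(size=(6, 1)), requires_grad=True)
        t = rng.integers(0, 2, size=(6, 1)).astype(float)

        def fn():
            return bce_with_logits(z, t)

        check_grads(fn, [z])

    def test_concat(self, rng):
        a = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        b = Tensor(rng.normal(size=(3, 4)), requires_grad=True)

        def fn():
            return (concat([a, b], axis=-1) ** 2).sum()

        check_grads(fn, [a, b])

    def test_diamond_graph_accumulates(self, rng):
        a = Tensor(rng.normal(size=(3,)), requires_grad=True)

        def fn():
            b = a * 2.0
            return (b * a + b).sum()  # a reached through two paths

        check_grads(fn, [a])


class TestLossValues:
    def test_cross_entropy_uniform_logits_is_log_c(self):
        z = Tensor(np.zeros((8, 12)))
        z.requires_grad = True
        loss = cross_entropy_logits(z, np.zeros(8, dtype=int))
        assert loss.item() == pytest.approx(np.log(12), abs=1e-9)

    def test_bce_matches_closed_form(self):
        z = Tensor(np.array([[0.0], [2.0]]), requires_grad=True)
        t = np.array([[1.0], [0.0]])
        expected = (np.log(2.0) + (np.log1p(np.exp(-2.0)) + 2.0)) / 2
        assert bce_with_logits(z, t).item() == pytest.approx(expected)


class TestModules:
    def test_no_grad_builds_no_graph(self, rng):
        a = Tensor(rng.normal(size=(2, 2)), requires_grad=True)
        with no_grad():
            out = (a * 3.0).sum()
        assert out.requires_grad is False

    def test_state_dict_roundtrip(self, rng):
        enc = TransformerEncoder(20, 10, 8, 1, 2, 16, 0.0, rng, RngRef(0))
        state = enc.state_dict()
        enc2 = TransformerEncoder(20, 10, 8, 1, 2, 16, 0.0, np.random.default_rng(99), RngRef(0))
        enc2.load_state_dict(state)
        ids = np.array([[1, 2, 3]])
        with no_grad():
            np.testing.assert_array_equal(enc(ids).data, enc2(ids).data)

    def test_dropout_identity_in_eval(self, rng):
        from skelseq.nn import Dropout

        drop = Dropout(0.5, RngRef(0))
        drop.eval()
        x = Tensor(rng.normal(size=(4, 4)))
        np.testing.assert_array_equal(drop(x).data, x.data)


class TestAdamW:
    def test_first_step_matches_hand_computation(self):
        from skelseq.nn.layers import Parameter

        p = Parameter(np.array([1.0]))
        p.grad = np.array([0.5], dtype=np.float32)
        opt = AdamW([("weight", p)], lr=0.1, weight_decay=0.0)
        opt.step()
        # first Adam step moves by ~lr * sign(grad) (bias-corrected)
        expected = 1.0 - 0.1 * 0.5 / (np.abs(0.5) + 1e-8)
        assert p.data[0] == pytest.approx(expected, rel=1e-5)

    def test_decay_skipped_for_excluded_names(self):
        from skelseq.nn.layers import Parameter

        w = Parameter(np.array([1.0]))
        b = Parameter(np.array([1.0]))
        opt = AdamW([("weight", w), ("head.bias", b)], lr=0.0, weight_decay=0.5)
        w.grad = np.zeros(1, dtype=np.float32)
        b.grad = np.zeros(1, dtype=np.float32)
        opt.step()
        assert w.data[0] == 1.0 and b.data[0] == 1.0  # lr 0: no movement at all
        opt2 = AdamW([("weight", w), ("head.bias", b)], lr=1.0, weight_decay=0.5)
        w.grad = np.zeros(1, dtype=np.float32)
        b.grad = np.zeros(1, dtype=np.float32)
        opt2.step()
        assert w.data[0] == pytest.approx(0.5)  # decoupled decay applied
        assert b.data[0] == 1.0  # bias exempt
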