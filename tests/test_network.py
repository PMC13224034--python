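"""Network construction, forward passes, losses, and gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dauplift.network import (
    ConfigError,
    NetworkConfig,
    build_network,
    fairness_penalty,
    grl_backward,
    grl_forward,
    total_loss,
    uplift_loss,
)
from dauplift.align import (
    cdan_penalty,
    coral_penalty,
    domain_adversarial_penalty,
    mmd_penalty,
)


def small_net(seed=0, d=5, widths=(7, 4), K=3, extra=0):
    return build_network(NetworkConfig(
        input_dim=d, hidden_widths=widths, dropout=0.0,
        num_domains=K, seed=seed, disc_extra_inputs=extra))


class TestBuildNetwork:
    def test_architecture_dimensions(self):
        net = build_network(NetworkConfig(input_dim=40, hidden_widths=(128, 64),
                                          dropout=0.30, num_domains=3, seed=0))
        assert net.config.embedding_dim == 64
        assert net.params["disc_W1"].shape == (64, 3)
        assert net.params["enc_W0"].shape == (40, 128)

    def test_same_seed_identical_parameters(self):
        a, b = small_net(seed=3), small_net(seed=3)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    @pytest.mark.parametrize("kwargs", [
        {"input_dim": 0},
        {"input_dim": 4, "hidden_widths": ()},
        {"input_dim": 4, "dropout": 1.0},
        {"input_dim": 4, "num_domains": 1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            NetworkConfig(**kwargs)

    def test_checkpoint_round_trip_exact(self, tmp_path):
        net = small_net(seed=9)
        net.save(tmp_path / "model.npz")
        loaded = net.load(tmp_path / "model.npz")
        assert all(np.array_equal(net.params[k], loaded.params[k]) for k in net.params)
        assert loaded.config == net.config


class TestForward:
    def test_eval_mode_deterministic(self):
        net = build_network(NetworkConfig(input_dim=5, dropout=0.5, num_domains=2, seed=0))
        X = np.random.default_rng(1).normal(size=(8, 5))
        a = net.forward_potential_outcomes(X)
        b = net.forward_potential_outcomes(X)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_hand_set_single_unit_network(self):
        """1-d encoder with identity weights; heads checked against a
        pencil-and-paper sigmoid."""
        net = small_net(d=1, widths=(1,), K=2)
        net.params["enc_W0"][:] = [[1.0]]
        net.params["enc_b0"][:] = [0.0]
        net.params["h1_w"][:] = [2.0]
        net.params["h1_b"][:] = [0.5]
        net.params["h0_w"][:] = [-1.0]
        net.params["h0_b"][:] = [0.0]
        X = np.array([[1.5]])
        y1, y0, emb = net.forward_potential_outcomes(X)
        sig = lambda z: 1 / (1 + np.exp(-z))
        assert emb[0, 0] == 1.5  # relu(1*1.5)
        assert np.isclose(y1[0], sig(2.0 * 1.5 + 0.5))
        assert np.isclose(y0[0], sig(-1.5))
        assert np.isclose(net.predict_uplift(X)[0], sig(3.5) - sig(-1.5))

    def test_identical_heads_give_zero_uplift(self):
        net = small_net()
        net.params["h0_w"] = net.params["h1_w"].copy()
        net.params["h0_b"] = net.params["h1_b"].copy()
        X = np.random.default_rng(0).normal(size=(20, 5))
        assert np.allclose(net.predict_uplift(X), 0.0)

    def test_empty_batch(self):
        net = small_net()
        y1, y0, emb = net.forward_potential_outcomes(np.zeros((0, 5)))
        assert y1.shape == (0,) and emb.shape == (0, 4)

    def test_uplift_strictly_inside_unit_interval(self):
        net = small_net(seed=4)
        X = np.random.default_rng(2).normal(scale=10, size=(50, 5))
        u = net.predict_uplift(X)
        assert np.all(u > -1) and np.all(u < 1)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="columns"):
            small_net().forward_potential_outcomes(np.zeros((3, 9)))


class TestUpliftLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        t = np.array([1.0, 0.0, 1.0])
        assert uplift_loss(y, y, t, y) < 1e-5

    def test_coin_flip_is_ln2(self):
        half = np.full(6, 0.5)
        t = np.array([0, 1, 0, 1, 0, 1.0])
        y = np.array([1, 0, 1, 1, 0, 0.0])
        assert np.isclose(uplift_loss(half, half, t, y), np.log(2))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        y1, y0 = rng.random(6), rng.random(6)
        t = rng.integers(0, 2, 6).astype(float)
        y = rng.integers(0, 2, 6).astype(float)
        expected = 0.0
        for i in range(6):
            p = y1[i] if t[i] == 1 else y0[i]
            expected -= (y[i] * np.log(p) + (1 - y[i]) * np.log(1 - p)) / 6
        assert np.isclose(uplift_loss(y1, y0, t, y), expected)

    def test_saturated_probabilities_clamped(self):
        ones = np.ones(3)
        t = np.ones(3)
        y = np.ones(3)
        assert np.isfinite(uplift_loss(ones, ones, t, y))


class TestFairnessPenalty:
    def test_constant_uplift_zero(self):
        u = np.full(10, 0.3)
        G = np.arange(10) % 2
        assert fairness_penalty(u, G, G) == 0.0

    def test_hand_computed_case(self):
        u = np.array([0.2, 0.2, 0.4, 0.4])
        G = np.array([0, 0, 1, 1])
        E = np.zeros(4, dtype=int)
        assert np.isclose(fairness_penalty(u, G, E), 0.04)

    def test_single_cell_attribute_contributes_nothing(self):
        u = np.array([0.1, 0.5, 0.9, 0.2])
        G = np.ones(4, dtype=int)  # no G=0 cell
        E = np.array([0, 0, 1, 1])
        expected = (u[:2].mean() - u[2:].mean()) ** 2
        assert np.isclose(fairness_penalty(u, G, E), expected)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        u = rng.normal(size=n)
        G = rng.integers(0, 2, n)
        E = rng.integers(0, 2, n)
        perm = rng.permutation(n)
        assert np.isclose(fairness_penalty(u, G, E),
                          fairness_penalty(u[perm], G[perm], E[perm]))


class TestGRL:
    def test_forward_is_identity(self):
        z = np.random.default_rng(0).normal(size=(4, 3))
        assert np.array_equal(grl_forward(z), z)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigError):
            grl_backward(np.ones((2, 2)), -0.1)

    def test_reversed_gradient_sign_and_scale_by_finite_differences(self):
        """On a relu-transparent scalar network, the encoder-side gradient of
        the domain loss equals -lambda * d(loss)/d(weight) measured by central
        finite differences."""
        net = small_net(d=1, widths=(1,), K=2)
        # positive weights and inputs keep every relu active
        for k in net.params:
            net.params[k] = np.abs(net.params[k]) + 0.1
        X = np.array([[0.7], [1.3], [0.4]])
        labels = np.array([0, 1, 0])
        lam = 0.5

        def domain_loss():
            emb, _ = net.encoder_forward(X)
            return domain_adversarial_penalty(emb, labels, net)

        emb, cache = net.encoder_forward(X)
        _, _, dZ = domain_adversarial_penalty(emb, labels, net, return_grads=True)
        enc_grads = net.encoder_backward(cache, grl_backward(dZ, lam))

        h = 1e-6
        orig = net.params["enc_W0"][0, 0]
        net.params["enc_W0"][0, 0] = orig + h
        lp = domain_loss()
        net.params["enc_W0"][0, 0] = orig - h
        lm = domain_loss()
        net.params["enc_W0"][0, 0] = orig
        fd = (lp - lm) / (2 * h)
        assert np.isclose(enc_grads["enc_W0"][0, 0], -lam * fd, rtol=1e-4)
        assert np.sign(enc_grads["enc_W0"][0, 0]) == -np.sign(fd)


class TestTotalLoss:
    def test_weighted_sum(self):
        lb = total_loss(1.0, 0.5, 0.2, lambda_d=0.4, lambda_f=5.0)
        assert np.isclose(lb.total, 1.0 + 0.4 * 0.5 + 5.0 * 0.2)

    def test_zero_weights_reduce_to_uplift(self):
        assert total_loss(0.7, 9.0, 9.0, 0.0, 0.0).total == 0.7

    def test_breakdown_additivity_random(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            parts = rng.random(3)
            lams = rng.random(2) * 5
            lb = total_loss(*parts, *lams)
            assert np.isclose(lb.total,
                              parts[0] + lams[0] * parts[1] + lams[1] * parts[2],
                              rtol=1e-12)

    def test_non_finite_component_aborts(self):
        with pytest.raises(FloatingPointError):
            total_loss(np.nan, 0.0, 0.0, 0.1, 0.1)


class TestGradients:
    """Central finite differences verify every hand-written backward pass."""

    @staticmethod
    def _fd_check(net, loss_fn, analytic_grads, keys, h=1e-6, rtol=2e-4):
        for k in keys:
            g = analytic_grads[k]
            flat_idx = [tuple(i) for i in np.argwhere(np.ones_like(g, dtype=bool))][:6]
            for i in flat_idx:
                orig = net.params[k][i]
                net.params[k][i] = orig + h
                lp = loss_fn()
                net.params[k][i] = orig - h
                lm = loss_fn()
                net.params[k][i] = orig
                fd = (lp - lm) / (2 * h)
                assert np.isclose(g[i], fd, rtol=rtol, atol=1e-8), (k, i, g[i], fd)

    def test_uplift_path_gradients(self):
        net = small_net(seed=1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(9, 5))
        t = rng.integers(0, 2, 9).astype(float)
        y = rng.integers(0, 2, 9).astype(float)

        def loss_fn():
            emb, _ = net.encoder_forward(X)
            y1, y0 = net.heads_forward(emb)
            return uplift_loss(y1, y0, t, y)

        emb, cache = net.encoder_forward(X)
        y1, y0 = net.heads_forward(emb)
        _, dy1, dy0 = uplift_loss(y1, y0, t, y, return_grads=True)
        grads, d_emb = net.heads_backward(emb, y1, y0, dy1, dy0)
        grads.update(net.encoder_backward(cache, d_emb))
        self._fd_check(net, loss_fn, grads,
                       ["enc_W0", "enc_b0", "enc_W1", "h1_w", "h0_w", "h1_b"])

    def test_fairness_gradients(self):
        net = small_net(seed=2)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        G = rng.integers(0, 2, 8)
        E = rng.integers(0, 2, 8)

        def loss_fn():
            emb, _ = net.encoder_forward(X)
            y1, y0 = net.heads_forward(emb)
            return fairness_penalty(y1 - y0, G, E)

        emb, cache = net.encoder_forward(X)
        y1, y0 = net.heads_forward(emb)
        _, du = fairness_penalty(y1 - y0, G, E, return_grads=True)
        grads, d_emb = net.heads_backward(emb, y1, y0, du, -du)
        grads.update(net.encoder_backward(cache, d_emb))
        self._fd_check(net, loss_fn, grads, ["enc_W0", "h1_w", "h0_w"])

    def test_alignment_penalty_gradients(self):
        net = small_net(seed=3)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        labels = rng.integers(0, 3, 10)

        # adversarial: discriminator + embedding grads
        def dom_fn():
            emb, _ = net.encoder_forward(X)
            return domain_adversarial_penalty(emb, labels, net)

        emb, cache = net.encoder_forward(X)
        _, disc_grads, dZ = domain_adversarial_penalty(emb, labels, net, return_grads=True)
        grads = dict(disc_grads)
        grads.update(net.encoder_backward(cache, dZ))
        self._fd_check(net, dom_fn, grads, ["disc_W0", "disc_W1", "enc_W0"])

        # coral and mmd (fixed bandwidth keeps the objective differentiable)
        for pen, kwargs in ((coral_penalty, {}), (mmd_penalty, {"bandwidth": 1.3})):
            def mom_fn():
                e, _ = net.encoder_forward(X)
                return pen(e[:5], e[5:], **kwargs)

            emb, cache = net.encoder_forward(X)
            _, dZs, dZt = pen(emb[:5], emb[5:], return_grads=True, **kwargs)
            grads = net.encoder_backward(cache, np.vstack([dZs, dZt]))
            self._fd_check(net, mom_fn, grads, ["enc_W0", "enc_W1"])

    def test_cdan_gradients_reach_heads_and_encoder(self):
        net = small_net(seed=4, extra=2)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 5))
        labels = rng.integers(0, 3, 9)

        def loss_fn():
            emb, _ = net.encoder_forward(X)
            y1, y0 = net.heads_forward(emb)
            return cdan_penalty(emb, y0, y1, labels, net)

        emb, cache = net.encoder_forward(X)
        y1, y0 = net.heads_forward(emb)
        _, disc_grads, dZdir, dy0, dy1 = cdan_penalty(
            emb, y0, y1, labels, net, return_grads=True)
        head_grads, d_emb_h = net.heads_backward(emb, y1, y0, dy1, dy0)
        grads = dict(disc_grads)
        grads.update(head_grads)
        grads.update(net.encoder_backward(cache, dZdir + d_emb_h))
        self._fd_check(net, loss_fn, grads,
                       ["disc_W0", "h1_w", "h0_w", "enc_W0"], rtol=1e-3)
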