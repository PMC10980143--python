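import numpy as np
import pytest

from wristgait.nn import (
    Adam,
    LinearHead,
    MLPHead,
    ResNetEncoder1d,
    Tensor,
    mtl_loss,
    ntxent_loss,
    simclr_pairing,
)
from wristgait.ssl_core import EncoderConfig, build_encoder


def brute_force_ntxent(E, pairing, tau):
    """Textbook double-loop NT-Xent, independent of the tape implementation."""
    U = E / np.linalg.norm(E, axis=1, keepdims=True)
    S = U @ U.T / tau
    n = len(E)
    total = 0.0
    for i in range(n):
        denom = sum(np.exp(S[i, k]) for k in range(n) if k != i)
        total += -np.log(np.exp(S[i, pairing[i]]) / denom)
    return total / n


class TestMTLLoss:
    def test_uniform_prediction_gives_ln2(self, rng):
        logits = np.zeros((8, 4))
        flags = rng.integers(0, 2, size=(8, 4)).astype(float)
        assert float(mtl_loss(logits, flags).data) == pytest.approx(np.log(2), abs=1e-12)

    def test_equals_mean_of_four_bce_terms(self, rng):
        logits = rng.normal(size=(16, 4))
        flags = rng.integers(0, 2, size=(16, 4)).astype(float)
        # independent per-task BCE with explicit probabilities
        p = 1 / (1 + np.exp(-logits))
        per_task = [
            -np.mean(flags[:, j] * np.log(p[:, j]) + (1 - flags[:, j]) * np.log(1 - p[:, j]))
            for j in range(4)
        ]
        assert float(mtl_loss(logits, flags).data) == pytest.approx(
            np.mean(per_task), abs=1e-7
        )

    def test_saturated_correct_logits_near_zero(self):
        flags = np.array([[1.0, 0, 1, 0]])
        logits = np.array([[20.0, -20, 20, -20]])
        assert float(mtl_loss(logits, flags).data) < 1e-3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            mtl_loss(np.zeros((4, 4)), np.zeros((3, 4)))

    def test_batch_permutation_equivariance(self, rng):
        logits = rng.normal(size=(12, 4))
        flags = rng.integers(0, 2, size=(12, 4)).astype(float)
        perm = rng.permutation(12)
        a = float(mtl_loss(logits, flags).data)
        b = float(mtl_loss(logits[perm], flags[perm]).data)
        assert a == pytest.approx(b, abs=1e-7)


class TestNTXentLoss:
    def test_identical_embeddings_give_log3(self):
        E = np.ones((4, 8))
        for tau in (0.05, 0.1, 1.0):
            loss = float(ntxent_loss(E, simclr_pairing(2), tau).data)
            assert loss == pytest.approx(np.log(3), abs=1e-9)

    def test_matches_brute_force_double_loop(self, rng):
        E = rng.normal(size=(8, 16))
        pairing = simclr_pairing(4)
        tau = 0.37
        ours = float(ntxent_loss(E, pairing, tau).data)
        assert ours == pytest.approx(brute_force_ntxent(E, pairing, tau), abs=1e-6)

    def test_orthogonal_negatives_small_tau_drives_loss_to_zero(self):
        E = np.zeros((8, 8))
        for i in range(4):                      # collinear positives, orthogonal pairs
            E[i, i] = 1.0
            E[i + 4, i] = 1.0
        loss = float(ntxent_loss(E, simclr_pairing(4), temperature=0.01).data)
        assert loss < 1e-3

    def test_zero_norm_embedding_rejected(self):
        E = np.ones((4, 8))
        E[2] = 0.0
        with pytest.raises(ValueError, match="zero-norm"):
            ntxent_loss(E, simclr_pairing(2))

    def test_scale_invariance_from_cosine(self, rng):
        E = rng.normal(size=(8, 16))
        pairing = simclr_pairing(4)
        a = float(ntxent_loss(E, pairing, 0.2).data)
        b = float(ntxent_loss(3.7 * E, pairing, 0.2).data)
        assert a == pytest.approx(b, abs=1e-6)

    def test_view_permutation_equivariance(self, rng):
        E = rng.normal(size=(8, 16))
        pairing = simclr_pairing(4)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        a = float(ntxent_loss(E, pairing, 0.2).data)
        b = float(ntxent_loss(E[perm], inv[pairing[perm]], 0.2).data)
        assert a == pytest.approx(b, abs=1e-7)

    def test_every_view_has_one_positive(self):
        pairing = simclr_pairing(5)
        assert len(pairing) == 10
        np.testing.assert_array_equal(pairing[pairing], np.arange(10))
        assert (pairing != np.arange(10)).all()


class TestGradients:
    def test_network_loss_gradient_matches_finite_difference(self, rng):
        enc = ResNetEncoder1d(3, [8, 8], [1, 2], feature_dim=6, input_length=30,
                              rng=np.random.default_rng(1))
        head = LinearHead(6, 4, rng=np.random.default_rng(2))
        X = rng.normal(size=(5, 3, 30))
        flags = rng.integers(0, 2, size=(5, 4)).astype(float)
        bufs0 = {n: b.copy() for n, b in enc.named_buffers()}

        def f():
            for n, b in enc.named_buffers():
                b[...] = bufs0[n]
            return mtl_loss(head(enc(Tensor(X))), flags)

        loss = f()
        enc.zero_grad()
        head.zero_grad()
        loss.backward()
        eps = 1e-6
        for name, p in enc.named_parameters() + head.named_parameters():
            g = p.grad
            idx = np.unravel_index(np.argmax(np.abs(g)), p.data.shape)
            old = p.data[idx]
            p.data[idx] = old + eps
            lp = float(f().data)
            p.data[idx] = old - eps
            lm = float(f().data)
            p.data[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - g[idx]) <= 1e-4 * max(1.0, abs(fd)), name

    def test_ntxent_gradient_matches_finite_difference(self, rng):
        E = Tensor(rng.normal(size=(6, 10)), requires_grad=True)
        pairing = simclr_pairing(3)
        loss = ntxent_loss(E, pairing, 0.2)
        loss.backward()
        g = E.grad.copy()
        eps = 1e-6
        for i, j in [(0, 0), (2, 5), (5, 9)]:
            old = E.data[i, j]
            E.data[i, j] = old + eps
            lp = float(ntxent_loss(E, pairing, 0.2).data)
            E.data[i, j] = old - eps
            lm = float(ntxent_loss(E, pairing, 0.2).data)
            E.data[i, j] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - g[i, j]) <= 1e-4 * max(1.0, abs(fd))


class TestEncoder:
    def test_reference_geometry_emits_1024d(self):
        enc = build_encoder(EncoderConfig.full(input_length=300), seed=0)
        out = enc(Tensor(np.random.default_rng(0).normal(size=(2, 3, 300))))
        assert out.data.shape == (2, 1024)

    def test_desk_geometry_emits_64d(self):
        enc = build_encoder(EncoderConfig.desk(), seed=0)
        out = enc(Tensor(np.random.default_rng(0).normal(size=(4, 3, 300))))
        assert out.data.shape == (4, 64)

    def test_same_seed_same_initial_weights(self):
        a = build_encoder(EncoderConfig.desk(), seed=7)
        b = build_encoder(EncoderConfig.desk(), seed=7)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_incompatible_input_length_rejected(self):
        with pytest.raises(ValueError, match="downsampling"):
            ResNetEncoder1d(3, [8, 8, 8, 8, 8], [2, 2, 2, 2, 2], feature_dim=8,
                            input_length=8)

    def test_feature_dim_floor_enforced(self):
        with pytest.raises(ValueError, match="at least 8"):
            EncoderConfig(feature_dim=4)


class TestOptimizer:
    def test_adam_skips_frozen_parameters(self, rng):
        head = MLPHead(8, 4, rng=np.random.default_rng(0))
        frozen = head.fc1.weight
        frozen.requires_grad = False
        before_frozen = frozen.data.copy()
        before_trainable = head.fc3.weight.data.copy()
        opt = Adam(head.parameters(), lr=0.1)
        out = head(Tensor(rng.normal(size=(4, 8))))
        loss = (out * out).mean()
        loss.backward()
        opt.step()
        np.testing.assert_array_equal(frozen.data, before_frozen)
        assert not np.array_equal(head.fc3.weight.data, before_trainable)
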