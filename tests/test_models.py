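"""LSNN assembly, forward pass, loss, and the ablation variants."""

import numpy as np
import pytest

from ldntsc import models
from ldntsc.exceptions import ConfigurationError, DataError
from ldntsc.models import LSNNConfig


class TestAssembly:
    @pytest.mark.parametrize("d,total", [(10, 50), (24, 120), (1, 5)])
    def test_spiking_neuron_count_is_5d(self, d, total):
        model = models.build_lsnn(LSNNConfig(d=d))
        assert model.n_spiking == total
        assert model.config.n_enc == 2 * d and model.config.n_hdn == 3 * d

    def test_layer_and_weight_shapes(self):
        m = models.build_lsnn(LSNNConfig(d=10, n_classes=2))
        assert m.weights["W1"].shape == (20, 30)
        assert m.weights["W2"].shape == (30, 2)

    def test_nhdn_has_single_matrix_and_enc_only(self):
        m = models.build_lsnn_nhdn(LSNNConfig(d=10, n_classes=2))
        assert m.n_spiking == 20
        assert list(m.weights) == ["W"]
        assert m.weights["W"].shape == (20, 2)
        assert m.weights["W"].size == 2 * 10 * 2

    def test_nspk_widths(self):
        m = models.build_lsnn_nspk(LSNNConfig(d=10, n_classes=2))
        assert m.weights["W1"].shape == (10, 30)
        assert m.n_spiking == 0

    @pytest.mark.parametrize("kw", [{"d": 0}, {"n_classes": 1}])
    def test_invalid_sizes(self, kw):
        with pytest.raises(ConfigurationError):
            models.build_lsnn(LSNNConfig(**kw))


class TestForward:
    def test_zero_signal_zero_trace(self):
        m = models.build_lsnn(LSNNConfig(d=4, iota=0.0))
        V, pred = models.forward(m, np.zeros(120))
        assert np.array_equal(V, np.zeros_like(V))
        assert pred == 0  # tie broken to the lowest class index

    def test_deterministic(self, rng):
        u = rng.standard_normal(140)
        m1 = models.build_lsnn(LSNNConfig(d=6, seed=3))
        m2 = models.build_lsnn(LSNNConfig(d=6, seed=3))
        V1, p1 = models.forward(m1, u)
        V2, p2 = models.forward(m2, u)
        assert np.array_equal(V1, V2) and p1 == p2

    def test_rejects_nonfinite(self):
        m = models.build_lsnn(LSNNConfig(d=2))
        with pytest.raises(DataError):
            models.forward(m, np.array([1.0, np.inf, 0.0]))

    def test_matches_manual_enumeration(self):
        """A d=1, T=3 instance with hand-set weights, checked against a
        scalar step-by-step re-evaluation of the layer equations."""
        cfg = LSNNConfig(d=1, theta=0.1, rho=2.0, iota=0.1, tau_cur=10e-3,
                         tau_vol=20e-3, v_thr=0.05, seed=0)
        m = models.build_lsnn(cfg)
        W1 = np.array([[0.3, -0.2, 0.5], [0.1, 0.4, -0.3]])
        W2 = np.array([[0.2, -0.1], [0.3, 0.2], [-0.4, 0.5]])
        m.weights["W1"] = W1.copy()
        m.weights["W2"] = W2.copy()
        u = [5.0, -3.0, 8.0]

        # --- independent scalar enumeration ---
        a_d = float(m.spec.A_d[0, 0])
        b_d = float(m.spec.B_d[0])
        alpha = np.exp(-1e-3 / cfg.tau_cur)
        beta = np.exp(-1e-3 / cfg.tau_vol)
        x_prev = 0.0
        Venc = [0.0, 0.0]
        Ih = [0.0, 0.0, 0.0]
        Vh = [0.0, 0.0, 0.0]
        Io = [0.0, 0.0]
        Vo = [0.0, 0.0]
        Vo_trace = []
        for t in range(3):
            x = a_d * x_prev + b_d * u[t]
            x_prev = x
            Senc = [0.0, 0.0]
            for i, eps in enumerate((1.0, -1.0)):
                I = cfg.rho * eps * x + cfg.iota
                V = max(Venc[i] + I, 0.0)          # lower clamp at 0
                if V >= cfg.v_thr:
                    Senc[i], V = 1.0, 0.0          # spike, hard reset
                Venc[i] = V
            Sh = [0.0, 0.0, 0.0]
            for j in range(3):
                Ih[j] = alpha * Ih[j] + Senc[0] * W1[0, j] + Senc[1] * W1[1, j]
                V = Vh[j] + Ih[j]
                if V >= cfg.v_thr:
                    Sh[j], V = 1.0, 0.0
                Vh[j] = V
            for c in range(2):
                Io[c] = alpha * Io[c] + sum(Sh[j] * W2[j, c]
                                            for j in range(3))
                Vo[c] = beta * Vo[c] + Io[c]
            Vo_trace.append(list(Vo))
        expected = np.array(Vo_trace)

        V, pred = models.forward(m, np.array(u))
        assert np.allclose(V, expected, atol=1e-12)
        assert V.any()  # the toy instance actually produces spikes
        assert pred == int(np.argmax(expected.max(axis=0)))


class TestLoss:
    def test_equal_scores_give_ln2(self):
        V = np.zeros((4, 10, 2))
        y = np.array([0, 1, 0, 1])
        assert np.isclose(models.classification_loss(V, y), np.log(2))

    def test_shift_invariance(self, rng):
        V = rng.standard_normal((5, 20, 3))
        y = np.array([0, 1, 2, 1, 0])
        l1 = models.classification_loss(V, y)
        l2 = models.classification_loss(V + 7.3, y)
        assert np.isclose(l1, l2)

    def test_confident_correct_prediction_drives_loss_to_zero(self):
        V = np.zeros((1, 5, 2))
        V[0, 2, 0] = 50.0
        assert models.classification_loss(V, np.array([0])) < 1e-20

    def test_permutation_equivariance(self, rng):
        V = rng.standard_normal((6, 15, 3))
        y = np.array([0, 1, 2, 0, 1, 2])
        perm = np.array([2, 0, 1])
        l1 = models.classification_loss(V, y)
        l2 = models.classification_loss(V[:, :, perm],
                                        np.argsort(perm)[y])
        assert np.isclose(l1, l2)

    def test_rejects_out_of_range_labels(self):
        with pytest.raises(DataError):
            models.classification_loss(np.zeros((2, 5, 2)),
                                       np.array([0, 2]))


class TestNspk:
    def test_zero_input_zero_scores(self):
        m = models.build_lsnn_nspk(LSNNConfig(d=5))
        V, pred = models.forward(m, np.zeros(60))
        assert np.allclose(V, 0) and pred == 0

    def test_gradient_matches_finite_differences(self, tiny_fixture):
        train, _ = tiny_fixture
        m = models.build_lsnn_nspk(LSNNConfig(d=2, seed=1))
        Z = models.encode_dataset(m, train.signals[:6])
        y = train.labels[:6]
        _, grads = models.loss_and_grad(m, Z, y)
        eps = 1e-6
        for k, W in m.weights.items():
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = W[idx]
                W[idx] = old + eps
                lp, _ = models.loss_and_grad(m, Z, y)
                W[idx] = old - eps
                lm, _ = models.loss_and_grad(m, Z, y)
                W[idx] = old
                fd = (lp - lm) / (2 * eps)
                if abs(fd) > 1e-8:
                    assert abs(fd - grads[k][idx]) / abs(fd) < 1e-4


class TestSaveLoad:
    @pytest.mark.parametrize("builder", [models.build_lsnn,
                                         models.build_lsnn_nhdn,
                                         models.build_lsnn_nspk])
    def test_roundtrip_preserves_predictions(self, builder, tmp_path, rng):
        m = builder(LSNNConfig(d=3, seed=5))
        u = rng.standard_normal(100)
        V, _ = models.forward(m, u)
        models.save_model(m, tmp_path / "m")
        m2 = models.load_model(tmp_path / "m")
        V2, _ = models.forward(m2, u)
        assert m2.variant == m.variant
        assert np.array_equal(V, V2)
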